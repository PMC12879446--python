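"""Raw reflectance -> hemoglobin contrast preprocessing chain.

The chain transforms interleaved multi-wavelength reflectance frames into
masked, filtered oxy-/deoxyhemoglobin contrast time series. The step order
is fixed and recorded in the provenance of every :class:`HemoStack`:

    downsample -> mask -> detrend -> log-mean -> spectroscopy ->
    smooth -> hemisphere regression -> bandpass -> censor

Within detrending, the temporal (per-pixel quadratic in time) fit is
removed before the spatial (per-frame quadratic surface) fit; both orders
are second-order polynomials, the minimal reading of "second-order spatial
and temporal detrending". The censoring statistic is the spatial mean of
squared HbO2 contrast per frame, which is comparable across masks of
different sizes (the per-animal masks of real recordings differ in area).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import ndimage, signal

from .exceptions import LayoutError, PreprocessError
from .masks import MaskSet
from .spectroscopy import SpectroscopyModel, default_spectroscopy_model, invert_spectroscopy

__all__ = [
    "RawStack",
    "HemoStack",
    "downsample",
    "detrend",
    "log_mean_transform",
    "smooth",
    "regress_hemispheric_signal",
    "bandpass",
    "censor_timepoints",
    "concatenate_runs",
    "preprocess_stack",
    "gaussian_kernel",
]


@dataclass
class RawStack:
    """Per-wavelength reflectance frame series with acquisition metadata.

    ``frames`` has shape (n_wavelengths, n_frames, rows, cols); all
    wavelengths share time and spatial dimensions (one frame per wavelength
    per post-separation time point).
    """

    frames: np.ndarray
    wavelengths_nm: tuple[float, ...]
    frame_rate_hz: float
    bit_depth: int | None = 16
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4:
            raise LayoutError(
                f"frames must be 4-D (wavelength, time, rows, cols), got {self.frames.ndim}-D"
            )
        if self.frames.shape[0] != len(self.wavelengths_nm):
            raise LayoutError(
                f"{self.frames.shape[0]} channels but {len(self.wavelengths_nm)} wavelengths"
            )
        if self.frame_rate_hz <= 0:
            raise PreprocessError("frame_rate_hz must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[1]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[2], self.frames.shape[3]


@dataclass
class HemoStack:
    """Hemoglobin contrast time series over a masked field of view.

    ``hbo2``/``hbr`` are (n_frames, rows*cols) matrices in relative
    concentration units (uM with the default spectroscopy model); values
    outside the analysis mask are zero and carry no meaning.
    ``censored_frames`` holds original (pre-censoring, post-concatenation)
    time indices of dropped frames; ``frame_index`` maps surviving rows to
    those original indices.
    """

    hbo2: np.ndarray
    hbr: np.ndarray
    mask: MaskSet
    frame_rate_hz: float
    censored_frames: list[int] = field(default_factory=list)
    provenance: list[dict[str, Any]] = field(default_factory=list)
    frame_index: np.ndarray | None = None
    n_frames_original: int | None = None

    def __post_init__(self) -> None:
        self.hbo2 = np.asarray(self.hbo2, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo2.shape != self.hbr.shape:
            raise PreprocessError("hbo2 and hbr must share a shape")
        npix = int(np.prod(self.mask.shape))
        if self.hbo2.ndim != 2 or self.hbo2.shape[1] != npix:
            raise PreprocessError(
                f"contrast matrices must be (n_frames, {npix}) for mask shape {self.mask.shape}"
            )
        if self.frame_index is None:
            self.frame_index = np.arange(self.hbo2.shape[0])
        if self.n_frames_original is None:
            self.n_frames_original = self.hbo2.shape[0]
        if list(self.censored_frames) != sorted(set(int(i) for i in self.censored_frames)):
            raise PreprocessError("censored_frames must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.hbo2.shape[0]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.mask.shape

    def record(self, step: str, **params: Any) -> None:
        self.provenance.append({"step": step, **params})

    def copy_with(self, hbo2: np.ndarray, hbr: np.ndarray, **overrides: Any) -> "HemoStack":
        kwargs = dict(
            mask=self.mask,
            frame_rate_hz=self.frame_rate_hz,
            censored_frames=list(self.censored_frames),
            provenance=[dict(p) for p in self.provenance],
            frame_index=self.frame_index.copy(),
            n_frames_original=self.n_frames_original,
        )
        kwargs.update(overrides)
        return HemoStack(hbo2, hbr, **kwargs)

    def analysis_traces(self, contrast: str = "hbo2") -> np.ndarray:
        """(n_frames, n_analysis_pixels) view restricted to the analysis mask."""
        flat = self.mask.analysis.ravel()
        return getattr(self, contrast)[:, flat]


# ---------------------------------------------------------------------------
# individual operations


def _block_mean_spatial(frames: np.ndarray, target_shape: tuple[int, int]) -> np.ndarray:
    t, rows, cols = frames.shape
    tr, tc = target_shape
    if rows % tr or cols % tc:
        raise PreprocessError(
            f"spatial shape {(rows, cols)} is not an integer multiple of target {target_shape}"
        )
    fr, fc = rows // tr, cols // tc
    return frames.reshape(t, tr, fr, tc, fc).mean(axis=(2, 4))


def downsample(
    stack: RawStack, target_shape: tuple[int, int], target_rate_hz: float
) -> RawStack:
    """Spatial block-mean and temporal k-wise frame averaging.

    Decimation factors must be integers (no resampling interpolation);
    trailing frames that do not fill a full temporal bin are dropped.
    """
    rows, cols = stack.spatial_shape
    if target_shape[0] > rows or target_shape[1] > cols:
        raise PreprocessError("target shape exceeds source shape")
    ratio = stack.frame_rate_hz / target_rate_hz
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise PreprocessError(
            f"target rate {target_rate_hz} Hz must integer-divide source rate "
            f"{stack.frame_rate_hz} Hz"
        )
    out_wl = []
    n_keep = (stack.n_frames // k) * k
    if n_keep == 0:
        raise PreprocessError("too few frames for the requested temporal decimation")
    for w in range(stack.frames.shape[0]):
        f = np.asarray(stack.frames[w, :n_keep], dtype=float)
        f = f.reshape(-1, k, rows, cols).mean(axis=1)
        out_wl.append(_block_mean_spatial(f, target_shape))
    meta = dict(stack.meta)
    meta["downsample"] = {
        "spatial_factor": (rows // target_shape[0], cols // target_shape[1]),
        "temporal_factor": k,
        "frames_dropped": stack.n_frames - n_keep,
    }
    return RawStack(
        np.stack(out_wl), stack.wavelengths_nm, target_rate_hz, stack.bit_depth, meta
    )


def _polynomial_design(coords: Sequence[np.ndarray], order2: bool = True) -> np.ndarray:
    x, y = coords
    cols = [np.ones_like(x), x, y]
    if order2:
        cols += [x * x, x * y, y * y]
    return np.stack(cols, axis=1)


def detrend(
    series: np.ndarray,
    spatial_shape: tuple[int, int],
    mask: np.ndarray | None = None,
    spatial_mode: str = "drift",
) -> np.ndarray:
    """Second-order temporal and spatial detrending.

    Removes, from each pixel's deviation about its temporal mean, a
    quadratic-in-time least-squares fit, then removes a quadratic 2-D
    surface (terms 1, x, y, x^2, xy, y^2) fitted over in-mask pixels.

    ``spatial_mode`` controls the surface's time course. The default
    ``"drift"`` constrains per-frame surface coefficients to a quadratic
    temporal trend, so only spatially smooth *drift* (second order in both
    space and time) is removed. ``"per_frame"`` fits every frame
    independently; that also removes the quadratic spatial moments of the
    functional signal itself in each frame, which measurably distorts
    large-scale correlation structure (the same mechanism by which
    global-signal removal induces anticorrelation), so it is not the
    default. The temporal mean is re-added so the subsequent log-mean step
    stays well defined; out-of-mask pixels keep their temporal-fit-only
    residual.
    """
    if spatial_mode not in ("drift", "per_frame"):
        raise PreprocessError(f"unknown spatial_mode {spatial_mode!r}")
    series = np.asarray(series, dtype=float)
    n_t, n_pix = series.shape
    rows, cols = spatial_shape
    if n_pix != rows * cols:
        raise PreprocessError("series width does not match spatial shape")
    if n_t < 3:
        raise PreprocessError("detrend requires at least 3 time points")
    mean = series.mean(axis=0, keepdims=True)
    dev = series - mean

    t = np.linspace(-1.0, 1.0, n_t)
    G_t = np.stack([np.ones_like(t), t, t * t], axis=1)  # (T, 3)
    pinv_t = np.linalg.pinv(G_t)
    dev = dev - G_t @ (pinv_t @ dev)

    if mask is None:
        mask = np.ones(spatial_shape, dtype=bool)
    flat = np.asarray(mask, bool).ravel()
    n_in = int(flat.sum())
    yy, xx = np.mgrid[0:rows, 0:cols]
    x = (xx.ravel()[flat] / max(cols - 1, 1)) * 2.0 - 1.0
    y = (yy.ravel()[flat] / max(rows - 1, 1)) * 2.0 - 1.0
    G_s = _polynomial_design((x, y), order2=True)
    if n_in < G_s.shape[1] or np.linalg.matrix_rank(G_s) < G_s.shape[1]:
        warnings.warn(
            "spatial detrend design singular; falling back to planar basis", stacklevel=2
        )
        G_s = _polynomial_design((x, y), order2=False)
        if n_in < G_s.shape[1] or np.linalg.matrix_rank(G_s) < G_s.shape[1]:
            G_s = np.ones((n_in, 1))
    pinv_s = np.linalg.pinv(G_s)  # (6, n_in)
    sub = dev[:, flat]
    coef_s = sub @ pinv_s.T  # (T, 6) per-frame surface coefficients
    if spatial_mode == "drift":
        coef_s = G_t @ (pinv_t @ coef_s)  # quadratic-in-time trend of each coefficient
    dev[:, flat] = sub - coef_s @ G_s.T
    return dev + mean


def log_mean_transform(series: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """log of the ratio of each pixel trace to its temporal mean.

    The result is the negative differential absorption up to sign; a
    constant pixel maps to all zeros and exp(output) has per-pixel temporal
    mean exactly 1.
    """
    series = np.asarray(series, dtype=float)
    check = series if mask is None else series[:, np.asarray(mask, bool).ravel()]
    n_bad = int(np.count_nonzero(check <= 0))
    if n_bad:
        raise PreprocessError(
            f"log-mean transform requires strictly positive values; "
            f"{n_bad} non-positive entries found"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.log(series / series.mean(axis=0, keepdims=True))
    out[~np.isfinite(out)] = 0.0
    return out


def gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    """Truncated 2-D Gaussian kernel of the given side length, summing to 1."""
    half = (size - 1) / 2.0
    ax = np.arange(size) - half
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def smooth(hemo: HemoStack, kernel_size: int | None = None, sigma_px: float | None = None) -> HemoStack:
    """Masked-normalized Gaussian smoothing of every frame.

    The kernel is renormalized over in-mask support so values outside the
    brain mask never bleed into in-mask pixels (a constant in-mask image is
    left exactly unchanged). Defaults: 5x5 kernel, sigma 1.3 px.
    """
    kernel_size = 5 if kernel_size is None else int(kernel_size)
    sigma_px = 1.3 if sigma_px is None else float(sigma_px)
    rows, cols = hemo.spatial_shape
    if kernel_size > min(rows, cols):
        raise PreprocessError("smoothing kernel larger than the image")
    k2d = gaussian_kernel(kernel_size, sigma_px)
    m = hemo.mask.analysis.astype(float)
    den = ndimage.convolve(m, k2d, mode="constant", cval=0.0)
    flat = hemo.mask.analysis.ravel()

    def _one(contrast: np.ndarray) -> np.ndarray:
        frames = (contrast * flat[None, :]).reshape(-1, rows, cols)
        num = ndimage.convolve(frames, k2d[None, :, :], mode="constant", cval=0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sm = num / den[None, :, :]
        sm = sm.reshape(contrast.shape)
        out = contrast.copy()
        out[:, flat] = sm[:, flat]
        return out

    new = hemo.copy_with(_one(hemo.hbo2), _one(hemo.hbr))
    new.record("smooth", kernel_size=kernel_size, sigma_px=sigma_px)
    return new


def regress_hemispheric_signal(hemo: HemoStack) -> HemoStack:
    """Regress each hemisphere's mean trace out of its own pixels.

    Each pixel trace x is replaced by the residual of a least-squares
    regression of x on [1, g], where g is the in-mask average trace of the
    pixel's hemisphere; residuals are mean-free and exactly orthogonal to g.
    Applied independently per contrast.
    """
    new_h = {c: getattr(hemo, c).copy() for c in ("hbo2", "hbr")}
    for side in ("left", "right"):
        flat = hemo.mask.hemi_mask(side).ravel()
        if not flat.any():
            raise PreprocessError(f"{side} hemisphere mask is empty")
        for contrast, arr in new_h.items():
            sub = arr[:, flat]
            g = sub.mean(axis=1)
            gc = g - g.mean()
            denom = float(gc @ gc)
            sub_c = sub - sub.mean(axis=0, keepdims=True)
            if denom <= 0.0:
                warnings.warn(
                    f"{side} hemispheric signal has zero variance; removing mean only",
                    stacklevel=2,
                )
                arr[:, flat] = sub_c
                continue
            beta = (gc @ sub_c) / denom  # (n_pix,)
            arr[:, flat] = sub_c - np.outer(gc, beta)
    new = hemo.copy_with(new_h["hbo2"], new_h["hbr"])
    new.record("hemisphere_regression", regressors=["intercept", "hemispheric_mean"])
    return new


def _design_sos(band_hz: tuple[float, float], rate_hz: float, order: int) -> np.ndarray:
    low, high = band_hz
    nyq = rate_hz / 2.0
    if not (0.0 < low < high < nyq):
        raise PreprocessError(f"band {band_hz} invalid for rate {rate_hz} Hz")
    return signal.butter(order, [low / nyq, high / nyq], btype="bandpass", output="sos")


def bandpass(hemo: HemoStack, band_hz: tuple[float, float] = (0.02, 0.167), order: int = 5) -> HemoStack:
    """Zero-phase Butterworth bandpass of every pixel trace.

    An order-``order`` Butterworth bandpass is applied forward-backward
    (``sosfiltfilt``), doubling the effective attenuation and removing
    phase lag that would distort correlations.
    """
    sos = _design_sos(band_hz, hemo.frame_rate_hz, order)
    padlen = 3 * (2 * len(sos) + 1)
    if hemo.n_frames <= padlen:
        raise PreprocessError(
            f"series of {hemo.n_frames} frames too short for zero-phase filtering; "
            f"need more than {padlen} frames"
        )
    out = {
        c: signal.sosfiltfilt(sos, getattr(hemo, c), axis=0).copy()
        for c in ("hbo2", "hbr")
    }
    new = hemo.copy_with(out["hbo2"], out["hbr"])
    new.record("bandpass", band_hz=list(band_hz), design="butterworth", order=order,
               zero_phase=True)
    return new


def censor_timepoints(hemo: HemoStack, threshold: float = 1.0) -> HemoStack:
    """Drop frames whose spatial mean squared HbO2 contrast exceeds threshold."""
    traces = hemo.analysis_traces("hbo2")
    stat = (traces**2).mean(axis=1)
    keep = stat <= threshold
    if not keep.any():
        raise PreprocessError(
            f"all {hemo.n_frames} frames exceed censor threshold {threshold}"
        )
    dropped = hemo.frame_index[~keep]
    new = hemo.copy_with(
        hemo.hbo2[keep], hemo.hbr[keep],
        censored_frames=sorted(set(hemo.censored_frames) | set(int(i) for i in dropped)),
        frame_index=hemo.frame_index[keep],
    )
    new.record("censor", threshold=threshold, n_censored=int((~keep).sum()))
    return new


def concatenate_runs(runs: Sequence[HemoStack]) -> HemoStack:
    """Concatenate runs along time, re-offsetting censored frame indices."""
    if not runs:
        raise PreprocessError("no runs to concatenate")
    if len(runs) == 1:
        return runs[0]
    first = runs[0]
    offset = 0
    hbo2, hbr, fidx, censored, boundaries = [], [], [], [], []
    for run in runs:
        if run.spatial_shape != first.spatial_shape:
            raise PreprocessError("runs differ in spatial shape")
        if run.frame_rate_hz != first.frame_rate_hz:
            raise PreprocessError("runs differ in frame rate")
        same_mask = (
            np.array_equal(run.mask.brain, first.mask.brain)
            and np.array_equal(run.mask.hemisphere, first.mask.hemisphere)
            and np.array_equal(run.mask.vein, first.mask.vein)
        )
        if not same_mask:
            raise PreprocessError("runs differ in masks")
        hbo2.append(run.hbo2)
        hbr.append(run.hbr)
        fidx.append(run.frame_index + offset)
        censored.extend(int(i) + offset for i in run.censored_frames)
        boundaries.append(offset)
        offset += int(run.n_frames_original)
    out = HemoStack(
        np.concatenate(hbo2), np.concatenate(hbr),
        mask=first.mask, frame_rate_hz=first.frame_rate_hz,
        censored_frames=sorted(censored),
        provenance=[dict(p) for p in first.provenance],
        frame_index=np.concatenate(fidx),
        n_frames_original=offset,
    )
    out.record("concatenate", run_boundaries=boundaries, n_runs=len(runs))
    return out


# ---------------------------------------------------------------------------
# orchestrated chain


def preprocess_stack(
    stack: RawStack,
    mask: MaskSet,
    *,
    target_shape: tuple[int, int] | None = None,
    target_rate_hz: float | None = None,
    band_hz: tuple[float, float] = (0.02, 0.167),
    filter_order: int = 5,
    smoothing: tuple[int, float] = (5, 1.3),
    censor_threshold: float = 1.0,
    model: SpectroscopyModel | None = None,
    do_detrend: bool = True,
    do_smooth: bool = True,
    do_regress: bool = True,
    do_bandpass: bool = True,
    do_censor: bool = True,
) -> HemoStack:
    """Run the full fixed-order preprocessing chain on one raw stack.

    The mask must match the *downsampled* spatial shape. Individual steps
    can be disabled for diagnostic runs; the provenance always reflects
    what actually ran, in order.
    """
    if model is None:
        model = default_spectroscopy_model(stack.wavelengths_nm)
    prov: list[dict[str, Any]] = []
    if target_shape is None:
        target_shape = stack.spatial_shape
    if target_rate_hz is None:
        target_rate_hz = stack.frame_rate_hz
    if target_shape != stack.spatial_shape or target_rate_hz != stack.frame_rate_hz:
        stack = downsample(stack, target_shape, target_rate_hz)
        prov.append({"step": "downsample", **stack.meta["downsample"]})
    if mask.shape != stack.spatial_shape:
        raise PreprocessError(
            f"mask shape {mask.shape} does not match downsampled stack {stack.spatial_shape}"
        )
    prov.append({"step": "mask", "n_brain": int(mask.brain.sum()),
                 "n_vein": int(mask.vein.sum())})

    n_t = stack.n_frames
    rows, cols = stack.spatial_shape
    dabs = np.empty((len(stack.wavelengths_nm), n_t, rows * cols))
    for w in range(len(stack.wavelengths_nm)):
        series = np.asarray(stack.frames[w], dtype=float).reshape(n_t, -1)
        if do_detrend:
            series = detrend(series, (rows, cols), mask.brain)
        dabs[w] = -log_mean_transform(series, mask.brain)
    if do_detrend:
        prov.append({"step": "detrend", "temporal_order": 2, "spatial_order": 2})
    prov.append({"step": "log_mean"})

    hbo2, hbr = invert_spectroscopy(dabs, model)
    prov.append({"step": "spectroscopy",
                 "wavelengths_nm": list(stack.wavelengths_nm),
                 "pathlength_cm": model.pathlength_cm.tolist()})
    flat = mask.brain.ravel()
    hbo2[:, ~flat] = 0.0
    hbr[:, ~flat] = 0.0

    hemo = HemoStack(hbo2, hbr, mask=mask, frame_rate_hz=target_rate_hz, provenance=prov)
    if do_smooth:
        hemo = smooth(hemo, *smoothing)
    if do_regress:
        hemo = regress_hemispheric_signal(hemo)
    if do_bandpass:
        hemo = bandpass(hemo, band_hz, order=filter_order)
    if do_censor:
        hemo = censor_timepoints(hemo, censor_threshold)
    return hemo
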