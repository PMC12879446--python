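"""Synthetic wide-field reflectance generator with known ground truth.

Emulates the structure of resting-state optical recordings of a bilaterally
organized brain surface: mirrored polygonal (Voronoi) region layouts, region
latent time courses with a prescribed correlation matrix (homotopic pairs
strongly positive, within-hemisphere neighbors weakly positive), Beer-Lambert
forward optics per LED wavelength, second-order temporal drift, smooth
vignetting, a midline vein stripe carrying an independent strong signal,
per-hemisphere nuisance components, and white pixel noise, quantized to the
camera bit depth.

Every downstream stage of the pipeline is testable against the returned
:class:`GroundTruth` without any recorded data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace, asdict
from typing import Any

import numpy as np
from scipy import ndimage, signal

from .exceptions import LayoutError, WoifcError
from .masks import MaskSet, HEMI_LEFT, HEMI_RIGHT
from .preprocess import RawStack
from .spectroscopy import SpectroscopyModel, default_spectroscopy_model

__all__ = [
    "GroundTruth",
    "Scenario",
    "default_latent_corr",
    "make_layout",
    "sample_latent_traces",
    "render_reflectance",
    "simulate",
]


@dataclass
class GroundTruth:
    """True region structure behind a synthetic recording.

    ``region_map`` is an integer raster (0 = background, ids 1..n_left are
    left-hemisphere regions, n_left+1..2*n_left their mirrored right-side
    partners). ``latent_traces`` is (n_regions, n_frames).
    """

    region_map: np.ndarray
    region_labels: dict[int, tuple[str, str]]
    homotopic_pairs: list[tuple[int, int]]
    latent_corr: np.ndarray | None = None
    latent_traces: np.ndarray | None = None
    frame_rate_hz: float | None = None
    nuisance: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    margin: int = 2
    vein_halfwidth: int = 1

    @property
    def n_regions(self) -> int:
        return len(self.region_labels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.region_map.shape

    def region_pixels(self, region_id: int) -> np.ndarray:
        """Flat pixel indices of one region."""
        return np.flatnonzero(self.region_map.ravel() == region_id)

    def vein_mask(self) -> np.ndarray:
        return np.asarray(self.nuisance["vein_mask"], bool)

    def mask_set(self, include_vein: bool = True) -> MaskSet:
        """Brain/hemisphere/vein masks consistent with this layout."""
        rows, cols = self.shape
        m = self.margin
        brain = np.zeros((rows, cols), bool)
        brain[m : rows - m, m : cols - m] = True
        cc = np.arange(cols)[None, :] + 0.5
        hemi = np.where(cc <= cols / 2.0, HEMI_LEFT, HEMI_RIGHT).astype(np.uint8)
        hemi = np.broadcast_to(hemi, (rows, cols)).copy()
        hemi[~brain] = 0
        vein = self.vein_mask() if include_vein else None
        return MaskSet(brain, hemi, vein)


def default_latent_corr(
    n_per_hemisphere: int, homotopic_r: float = 0.6, neighbor_r: float = 0.2
) -> np.ndarray:
    """Target region correlation matrix for the default study conditions.

    Homotopic pairs correlate at ``homotopic_r``, consecutive regions within
    a hemisphere (and their mirrored counterparts) at ``neighbor_r``, all
    other pairs at 0 — bracketing the homotopic correlation range observed
    in real recordings so recovery is neither trivial nor impossible.
    """
    n = n_per_hemisphere
    A = np.eye(n)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = neighbor_r
    B = homotopic_r * np.eye(n)
    C = np.block([[A, B], [B, A]])
    eigvals = np.linalg.eigvalsh(C)
    if eigvals.min() < -1e-10:
        raise WoifcError(
            f"default latent correlation not PSD for homotopic_r={homotopic_r}, "
            f"neighbor_r={neighbor_r}"
        )
    return C


def make_layout(
    shape: tuple[int, int],
    n_regions_per_hemisphere: int,
    seed: int = 0,
    *,
    vein_halfwidth: int = 1,
    margin: int = 2,
    min_region_px: int = 4,
) -> GroundTruth:
    """Mirrored polygonal region layout with a midline vein stripe.

    Region seeds are placed on a jittered grid inside the left hemisphere
    (excluding the margin and vein stripe); every left brain pixel joins its
    nearest seed (a Voronoi tessellation), and the right hemisphere mirrors
    the left exactly about the vertical midline.
    """
    rows, cols = shape
    n = int(n_regions_per_hemisphere)
    if n < 1:
        raise LayoutError("need at least one region per hemisphere")
    rng = np.random.default_rng(seed)

    cc = np.arange(cols) + 0.5
    vein_cols = np.abs(cc - cols / 2.0) <= vein_halfwidth
    vein = np.zeros(shape, bool)
    vein[margin : rows - margin, :] = vein_cols[None, :]

    left_col_max = int(np.floor(cols / 2.0 - vein_halfwidth))  # exclusive
    r0, r1 = margin, rows - margin
    c0, c1 = margin, min(left_col_max, cols - margin)
    height, width = r1 - r0, c1 - c0
    if height < 1 or width < 1 or n * min_region_px > height * width:
        raise LayoutError(
            f"{n} regions of >= {min_region_px} px do not fit in a "
            f"{height}x{width} hemisphere area"
        )

    # jittered grid of seed points
    gr = max(1, int(round(np.sqrt(n * height / max(width, 1)))))
    gc = int(np.ceil(n / gr))
    while gr * gc < n:
        gc += 1
    cell_h, cell_w = height / gr, width / gc
    seeds = []
    for idx in range(n):
        gi, gj = divmod(idx, gc)
        cy = r0 + (gi + 0.5) * cell_h + rng.uniform(-0.3, 0.3) * cell_h
        cx = c0 + (gj + 0.5) * cell_w + rng.uniform(-0.3, 0.3) * cell_w
        seeds.append((cy, cx))
    seeds_arr = np.asarray(seeds)

    region_map = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:rows, 0:cols]
    left_area = (
        (yy >= r0) & (yy < r1) & (xx >= c0) & (xx < c1) & ~vein
    )
    ly, lx = yy[left_area], xx[left_area]
    # a few Lloyd relaxation steps give compact regions of comparable area
    for _ in range(3):
        d2 = (ly[:, None] - seeds_arr[None, :, 0]) ** 2 + (
            lx[:, None] - seeds_arr[None, :, 1]
        ) ** 2
        nearest = np.argmin(d2, axis=1)
        for j in range(n):
            sel = nearest == j
            if sel.any():
                seeds_arr[j] = (ly[sel].mean(), lx[sel].mean())
    d2 = (ly[:, None] - seeds_arr[None, :, 0]) ** 2 + (lx[:, None] - seeds_arr[None, :, 1]) ** 2
    region_map[ly, lx] = np.argmin(d2, axis=1) + 1

    # mirror to the right hemisphere: column c -> cols-1-c, id -> id + n
    mirrored = region_map[:, ::-1]
    right = mirrored > 0
    region_map[right] = mirrored[right] + n

    empty = [i for i in range(1, n + 1) if not np.any(region_map == i)]
    if empty:
        raise LayoutError(f"regions {empty} received no pixels; too many regions for shape")

    labels: dict[int, tuple[str, str]] = {}
    for i in range(1, n + 1):
        name = f"region_{i:02d}"
        labels[i] = (name, "left")
        labels[i + n] = (name, "right")
    pairs = [(i, i + n) for i in range(1, n + 1)]
    return GroundTruth(
        region_map=region_map,
        region_labels=labels,
        homotopic_pairs=pairs,
        nuisance={"vein_mask": vein},
        seed=int(seed),
        margin=margin,
        vein_halfwidth=vein_halfwidth,
    )


def _bandlimited_noise(
    rng: np.random.Generator,
    n_frames: int,
    n_series: int,
    band_hz: tuple[float, float],
    frame_rate_hz: float,
) -> np.ndarray:
    """(n_frames, n_series) zero-phase band-filtered standardized noise."""
    white = rng.standard_normal((n_frames, n_series))
    sos = signal.butter(
        4, [band_hz[0] / (frame_rate_hz / 2), band_hz[1] / (frame_rate_hz / 2)],
        btype="bandpass", output="sos",
    )
    x = signal.sosfiltfilt(sos, white, axis=0)
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return x / sd


def sample_latent_traces(
    latent_corr: np.ndarray,
    n_frames: int,
    band_hz: tuple[float, float] = (0.02, 0.167),
    frame_rate_hz: float = 8.0,
    seed: int = 0,
    repair: bool = False,
) -> np.ndarray:
    """Band-limited latent region traces with the target correlation.

    Filtered Gaussian noise is empirically whitened and colored with the
    symmetric square root of ``latent_corr``, so the returned traces are
    zero-mean, unit-variance, spectrally concentrated in ``band_hz``, and
    their empirical Pearson matrix equals the target up to float precision
    (rank-deficient targets, e.g. perfectly correlated duplicates, yield
    identical traces).

    Returns (n_regions, n_frames).
    """
    C = np.asarray(latent_corr, dtype=float)
    n = C.shape[0]
    if C.shape != (n, n) or not np.allclose(C, C.T, atol=1e-12):
        raise WoifcError("latent_corr must be a symmetric square matrix")
    eigvals, eigvecs = np.linalg.eigh(C)
    if eigvals.min() < -1e-10:
        if not repair:
            raise WoifcError(
                f"latent_corr is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3g}); pass repair=True to project"
            )
        eigvals = np.clip(eigvals, 0.0, None)
        C = (eigvecs * eigvals) @ eigvecs.T
        d = np.sqrt(np.diag(C))
        C = C / np.outer(d, d)
        eigvals, eigvecs = np.linalg.eigh(C)
    eigvals = np.clip(eigvals, 0.0, None)
    if n_frames <= n:
        raise WoifcError(f"need n_frames > n_regions ({n}) to whiten, got {n_frames}")

    rng = np.random.default_rng(seed)
    x = _bandlimited_noise(rng, n_frames, n, band_hz, frame_rate_hz)
    # empirical whitening: columns of u are orthonormal and zero-mean
    u, _, _ = np.linalg.svd(x, full_matrices=False)
    z = u * np.sqrt(n_frames)
    A = (eigvecs * np.sqrt(eigvals)) @ eigvecs.T  # symmetric sqrt of C
    y = z @ A
    return y.T.copy()


def render_reflectance(
    truth: GroundTruth,
    model: SpectroscopyModel | None = None,
    *,
    hbo2_amplitude: float = 0.5,
    pixel_noise: float = 0.8,
    hbr_alpha: float = 0.5,
    hbr_noise: float = 0.1,
    vein_amplitude: float = 1.0,
    hemi_nuisance_amplitude: float = 0.3,
    substructure_amplitude: float = 0.3,
    structured_noise_amplitude: float = 0.15,
    structured_noise_components: int = 20,
    structured_noise_sigma_px: float = 2.5,
    drift_amplitude: float = 0.005,
    vignette_min: float = 0.85,
    baseline_counts: tuple[float, ...] = (24000.0, 20000.0, 26000.0),
    bit_depth: int | None = 16,
    band_hz: tuple[float, float] = (0.02, 0.167),
    seed: int | None = None,
) -> RawStack:
    """Forward-render a raw multi-wavelength reflectance stack.

    Per pixel p and frame t the concentration contrasts are

        dHbO2 = amplitude * latent[region(p)] + vein/hemisphere terms + noise
        dHbR  = -alpha * dHbO2 + noise

    and per wavelength the reflectance is

        R(l,t,p) = baseline(l) * vignette(p) * drift(l,t) * exp(-dA(l,t,p))

    with dA from the modified Beer-Lambert forward model. Output is
    quantized to ``bit_depth`` (None keeps float64, for exact-inversion
    diagnostics). Amplitudes are in the concentration units of the
    spectroscopy model (uM for the default).
    """
    if truth.latent_traces is None or truth.frame_rate_hz is None:
        raise WoifcError("truth must carry latent_traces and frame_rate_hz")
    if model is None:
        model = default_spectroscopy_model()
    if len(baseline_counts) != len(model.wavelengths_nm):
        raise WoifcError("one baseline per wavelength required")
    rng = np.random.default_rng(truth.seed + 7919 if seed is None else seed)
    rows, cols = truth.shape
    npix = rows * cols
    latents = truth.latent_traces  # (R, T)
    n_frames = latents.shape[1]
    rate = truth.frame_rate_hz

    dhbo2 = np.zeros((n_frames, npix))
    if pixel_noise > 0:
        dhbo2 += pixel_noise * rng.standard_normal((n_frames, npix))
    flat_map = truth.region_map.ravel()
    for rid in truth.region_labels:
        idx = np.flatnonzero(flat_map == rid)
        dhbo2[:, idx] += hbo2_amplitude * latents[rid - 1][:, None]

    # within-region functional substructure: two orthogonal spatial gradients
    # per region (zero mean inside the region, so region-average traces are
    # unaffected), each with its own band-limited time course. Emulates the
    # sub-functionalization of anatomical regions that sustains finer-scale
    # parcels in real recordings.
    if substructure_amplitude > 0:
        n_reg = len(truth.region_labels)
        sub_traces = _bandlimited_noise(rng, n_frames, 2 * n_reg, band_hz, rate)
        for k, rid in enumerate(sorted(truth.region_labels)):
            idx = np.flatnonzero(flat_map == rid)
            if idx.size < 3:
                continue
            ry, rx = idx // cols, idx % cols
            theta = rng.uniform(0, np.pi)
            for m, (dy, dx) in enumerate(
                ((np.sin(theta), np.cos(theta)), (np.cos(theta), -np.sin(theta)))
            ):
                g = dy * (ry - ry.mean()) + dx * (rx - rx.mean())
                sd = g.std()
                if sd == 0:
                    continue
                g = g / sd
                dhbo2[:, idx] += substructure_amplitude * np.outer(
                    sub_traces[:, 2 * k + m], g
                )

    vein_flat = truth.vein_mask().ravel()
    vein_trace = _bandlimited_noise(rng, n_frames, 1, band_hz, rate)[:, 0]
    # the vein carries its own signal, uncorrelated with every region latent:
    # project the latent span out of the sampled trace to make that exact
    resid = vein_trace - latents.T @ np.linalg.lstsq(latents.T, vein_trace, rcond=None)[0]
    if resid.std() > 0:
        vein_trace = (resid - resid.mean()) / resid.std()
    if vein_amplitude > 0 and vein_flat.any():
        dhbo2[:, vein_flat] += vein_amplitude * vein_trace[:, None]

    masks = truth.mask_set(include_vein=False)
    hemi_traces = _bandlimited_noise(rng, n_frames, 2, band_hz, rate)
    if hemi_nuisance_amplitude > 0:
        for k, side in enumerate(("left", "right")):
            hflat = (masks.hemisphere == (HEMI_LEFT if side == "left" else HEMI_RIGHT)).ravel()
            dhbo2[:, hflat] += hemi_nuisance_amplitude * hemi_traces[:, k][:, None]

    # structured physiological noise: spatially smooth random weight maps,
    # each carrying its own band-limited time course (rank-k noise). This
    # is what sustains sub-region parcels in real recordings.
    if structured_noise_amplitude > 0 and structured_noise_components > 0:
        k = structured_noise_components
        fields = rng.standard_normal((k, rows, cols))
        fields = ndimage.gaussian_filter(
            fields, (0, structured_noise_sigma_px, structured_noise_sigma_px)
        )
        fields /= fields.std(axis=(1, 2), keepdims=True)
        sn_traces = _bandlimited_noise(rng, n_frames, k, band_hz, rate)
        dhbo2 += (structured_noise_amplitude / np.sqrt(k)) * (
            sn_traces @ fields.reshape(k, npix)
        )

    dhbr = -hbr_alpha * dhbo2
    if hbr_noise > 0:
        dhbr = dhbr + hbr_noise * rng.standard_normal((n_frames, npix))

    yy, xx = np.mgrid[0:rows, 0:cols]
    d2 = ((yy - (rows - 1) / 2.0) / max(rows / 2.0, 1)) ** 2 + (
        (xx - (cols - 1) / 2.0) / max(cols / 2.0, 1)
    ) ** 2
    vignette = 1.0 - (1.0 - vignette_min) * (d2 / max(d2.max(), 1e-12))
    vignette_flat = vignette.ravel()

    E = model.system_matrix
    tau = np.linspace(-1.0, 1.0, n_frames)
    drift_coeffs = rng.uniform(-drift_amplitude, drift_amplitude, size=(E.shape[0], 2))
    max_count = float(2 ** bit_depth - 1) if bit_depth else None
    frames = np.empty(
        (E.shape[0], n_frames, rows, cols),
        dtype=(np.uint16 if bit_depth and bit_depth <= 16 else np.float64)
        if bit_depth
        else np.float64,
    )
    n_clipped = 0
    for w in range(E.shape[0]):
        dA = E[w, 0] * dhbo2 + E[w, 1] * dhbr
        drift = 1.0 + drift_coeffs[w, 0] * tau + drift_coeffs[w, 1] * tau**2
        refl = baseline_counts[w] * vignette_flat[None, :] * np.exp(-dA) * drift[:, None]
        if bit_depth:
            clipped = (refl < 0) | (refl > max_count)
            n_clipped += int(clipped.sum())
            refl = np.clip(np.rint(refl), 0, max_count)
        frames[w] = refl.reshape(n_frames, rows, cols)
    if n_clipped:
        warnings.warn(
            f"{n_clipped} reflectance samples clipped at the {bit_depth}-bit range",
            stacklevel=2,
        )

    truth.nuisance.update(
        drift_coeffs=drift_coeffs,
        vignette=vignette,
        vein_trace=vein_trace,
        hemi_traces=hemi_traces.T,
    )
    return RawStack(
        frames=frames,
        wavelengths_nm=model.wavelengths_nm,
        frame_rate_hz=rate,
        bit_depth=bit_depth,
        meta={"synthetic": True, "seed": int(truth.seed)},
    )


@dataclass
class Scenario:
    """Study conditions for one synthetic recording.

    Defaults match the desk-scale default scenario: 10 mirrored regions
    (5 per hemisphere) on a 48x64 grid, 4800 frames at 8 frames/s (the
    duration scale of two concatenated 5-min runs at the post-downsampling
    rate), homotopic latent correlation 0.6, and moderate noise/artifact
    levels documented in the methods note.
    """

    shape: tuple[int, int] = (48, 64)
    n_regions_per_hemisphere: int = 5
    n_frames: int = 4800
    frame_rate_hz: float = 8.0
    band_hz: tuple[float, float] = (0.02, 0.167)
    homotopic_r: float = 0.6
    neighbor_r: float = 0.2
    hbo2_amplitude: float = 0.5
    pixel_noise: float = 0.8
    hbr_alpha: float = 0.5
    hbr_noise: float = 0.1
    vein_halfwidth: int = 1
    vein_amplitude: float = 1.0
    hemi_nuisance_amplitude: float = 0.3
    substructure_amplitude: float = 0.3
    structured_noise_amplitude: float = 0.15
    structured_noise_components: int = 20
    structured_noise_sigma_px: float = 2.5
    drift_amplitude: float = 0.005
    vignette_min: float = 0.85
    baseline_counts: tuple[float, ...] = (24000.0, 20000.0, 26000.0)
    bit_depth: int | None = 16
    seed: int = 0

    def clean(self) -> "Scenario":
        """Noise- and artifact-free variant for exact inversion checks."""
        return replace(
            self,
            pixel_noise=0.0,
            hbr_noise=0.0,
            vein_amplitude=0.0,
            hemi_nuisance_amplitude=0.0,
            substructure_amplitude=0.0,
            structured_noise_amplitude=0.0,
            drift_amplitude=0.0,
            vignette_min=1.0,
            bit_depth=None,
        )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["shape"] = list(d["shape"])
        d["band_hz"] = list(d["band_hz"])
        d["baseline_counts"] = list(d["baseline_counts"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "Scenario":
        kwargs = dict(data)
        for key in ("shape", "band_hz", "baseline_counts"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def simulate(scenario: Scenario | None = None, seed: int | None = None):
    """Generate one full synthetic recording.

    Returns (raw stack, mask set, ground truth). The returned mask does
    *not* pre-mark the vein — discovering and masking the midline vein is
    the pipeline's job, as with real recordings. Identical seeds give
    bit-identical outputs.
    """
    sc = scenario or Scenario()
    if seed is not None:
        sc = replace(sc, seed=int(seed))
    ss = np.random.SeedSequence(sc.seed)
    s_layout, s_latent, s_render = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    truth = make_layout(
        sc.shape, sc.n_regions_per_hemisphere, seed=s_layout, vein_halfwidth=sc.vein_halfwidth
    )
    truth.seed = sc.seed
    truth.latent_corr = default_latent_corr(
        sc.n_regions_per_hemisphere, sc.homotopic_r, sc.neighbor_r
    )
    truth.latent_traces = sample_latent_traces(
        truth.latent_corr, sc.n_frames, sc.band_hz, sc.frame_rate_hz, seed=s_latent
    )
    truth.frame_rate_hz = sc.frame_rate_hz
    raw = render_reflectance(
        truth,
        hbo2_amplitude=sc.hbo2_amplitude,
        pixel_noise=sc.pixel_noise,
        hbr_alpha=sc.hbr_alpha,
        hbr_noise=sc.hbr_noise,
        vein_amplitude=sc.vein_amplitude,
        hemi_nuisance_amplitude=sc.hemi_nuisance_amplitude,
        substructure_amplitude=sc.substructure_amplitude,
        structured_noise_amplitude=sc.structured_noise_amplitude,
        structured_noise_components=sc.structured_noise_components,
        structured_noise_sigma_px=sc.structured_noise_sigma_px,
        drift_amplitude=sc.drift_amplitude,
        vignette_min=sc.vignette_min,
        baseline_counts=sc.baseline_counts,
        bit_depth=sc.bit_depth,
        band_hz=sc.band_hz,
        seed=s_render,
    )
    return raw, truth.mask_set(include_vein=False), truth
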