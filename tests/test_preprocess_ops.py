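import numpy as np
import pytest
from scipy import ndimage

from woifc.exceptions import PreprocessError
from woifc.masks import MaskSet
from woifc.preprocess import (
    HemoStack,
    RawStack,
    bandpass,
    censor_timepoints,
    concatenate_runs,
    detrend,
    downsample,
    gaussian_kernel,
    log_mean_transform,
    regress_hemispheric_signal,
    smooth,
)


def _mask(rows=8, cols=10):
    brain = np.ones((rows, cols), bool)
    hemi = np.where(np.arange(cols)[None, :] < cols // 2, 1, 2).astype(np.uint8)
    hemi = np.broadcast_to(hemi, (rows, cols)).copy()
    return MaskSet(brain, hemi)


def _hemo(data, rows=8, cols=10, rate=8.0):
    mask = _mask(rows, cols)
    return HemoStack(data, 0.0 * data, mask=mask, frame_rate_hz=rate)


# ---------------------------------------------------------------------- downsample


def test_downsample_block_means_and_temporal_pairs():
    rng = np.random.default_rng(0)
    frames = rng.random((2, 4, 8, 12))
    stack = RawStack(frames, (530.0, 590.0), 16.0, bit_depth=None)
    out = downsample(stack, (4, 6), 8.0)
    assert out.frames.shape == (2, 2, 4, 6)
    # hand-computed corner block of first temporal pair
    manual = (frames[0, 0, :2, :2].mean() + frames[0, 1, :2, :2].mean()) / 2
    assert np.isclose(out.frames[0, 0, 0, 0], manual)
    assert out.frame_rate_hz == 8.0


def test_downsample_constant_stack_stays_constant():
    stack = RawStack(np.full((1, 4, 8, 12), 3.5), (530.0,), 16.0, bit_depth=None)
    out = downsample(stack, (2, 3), 4.0)
    assert np.allclose(out.frames, 3.5)


def test_downsample_alternating_frames_average():
    frames = np.empty((1, 6, 2, 2))
    frames[0, 0::2] = 1.0
    frames[0, 1::2] = 3.0
    stack = RawStack(frames, (530.0,), 16.0, bit_depth=None)
    out = downsample(stack, (2, 2), 8.0)
    assert np.allclose(out.frames, 2.0)


def test_downsample_non_integer_factors_rejected():
    stack = RawStack(np.zeros((1, 4, 8, 12)), (530.0,), 16.0)
    with pytest.raises(PreprocessError):
        downsample(stack, (3, 5), 8.0)  # spatial indivisible
    with pytest.raises(PreprocessError):
        downsample(stack, (4, 6), 7.0)  # rate indivisible


# ------------------------------------------------------------------------ detrend


def test_detrend_annihilates_quadratic_time_trends():
    rng = np.random.default_rng(1)
    t = np.linspace(-1, 1, 200)
    coef = rng.standard_normal((3, 40))
    series = coef[0] + np.outer(t, coef[1]) + np.outer(t * t, coef[2])
    out = detrend(series, (4, 10))
    dev = out - out.mean(axis=0)
    assert np.max(np.abs(dev)) < 1e-9 * max(np.max(np.abs(series)), 1)


def test_detrend_leaves_white_noise_uncorrelated_with_trend_basis():
    rng = np.random.default_rng(2)
    n = 500
    series = rng.standard_normal((n, 20))
    out = detrend(series, (4, 5))
    t = np.linspace(-1, 1, n)
    for basis in (t, t * t):
        b = (basis - basis.mean()) / np.linalg.norm(basis - basis.mean())
        dev = out - out.mean(axis=0)
        r = b @ dev / np.linalg.norm(dev, axis=0)
        assert np.all(np.abs(r) < 3 / np.sqrt(n))


def test_detrend_removes_spatial_ramp_drift():
    # planar ramp whose amplitude follows a quadratic in time is spatio-
    # temporal drift; the default mode removes it entirely
    rows, cols = 6, 8
    yy, xx = np.mgrid[0:rows, 0:cols]
    ramp = (2 * xx + 3 * yy).ravel().astype(float)
    t = np.linspace(-1, 1, 50)
    amp = 1.0 + 0.5 * t + 0.25 * t * t
    series = 10.0 + np.outer(amp, ramp)
    out = detrend(series, (rows, cols))
    dev = out - out.mean(axis=0)
    assert np.max(np.abs(dev)) < 1e-9 * np.max(np.abs(series))


def test_detrend_per_frame_mode_removes_single_frame_surface():
    rows, cols = 6, 8
    yy, xx = np.mgrid[0:rows, 0:cols]
    ramp = (xx - xx.mean()).ravel().astype(float)
    rng = np.random.default_rng(3)
    series = np.zeros((40, rows * cols)) + 5.0
    series[17] += 4.0 * ramp  # one-frame transient
    out = detrend(series, (rows, cols), spatial_mode="per_frame")
    dev = out - out.mean(axis=0)
    assert np.max(np.abs(dev[17])) < 1e-9 * np.max(np.abs(series))


def test_detrend_singular_spatial_design_falls_back_with_warning():
    mask = np.zeros((5, 5), bool)
    mask[:, 2] = True  # single column: x has no variation
    series = np.random.default_rng(0).random((10, 25)) + 1
    with pytest.warns(UserWarning, match="singular"):
        detrend(series, (5, 5), mask, spatial_mode="per_frame")


def test_detrend_needs_three_frames():
    with pytest.raises(PreprocessError):
        detrend(np.ones((2, 4)), (2, 2))


# ----------------------------------------------------------------------- log-mean


def test_log_mean_constant_pixel_is_zero():
    out = log_mean_transform(np.full((10, 3), 7.0))
    assert np.allclose(out, 0.0)


def test_log_mean_closed_form_value():
    series = np.ones((4, 1))
    series[2, 0] = np.e  # mean = (3 + e)/4
    out = log_mean_transform(series)
    expected = np.log(np.e / ((3 + np.e) / 4))
    assert np.isclose(out[2, 0], expected)


def test_log_mean_exp_identity():
    rng = np.random.default_rng(4)
    series = 1.0 + 0.5 * rng.random((60, 12))
    out = log_mean_transform(series)
    # exp(output) must have per-pixel temporal mean of series/mean(series) = 1
    np.testing.assert_allclose(
        np.exp(out).mean(axis=0) * series.mean(axis=0) / series.mean(axis=0), 1.0,
        rtol=1e-12,
    )


def test_log_mean_rejects_non_positive_values():
    series = np.ones((5, 4))
    series[2, 1] = -1.0
    with pytest.raises(PreprocessError, match="1 non-positive"):
        log_mean_transform(series)


# ------------------------------------------------------------------------- smooth


def test_gaussian_kernel_matches_truncated_normal_and_sums_to_one():
    k = gaussian_kernel(5, 1.3)
    assert np.isclose(k.sum(), 1.0)
    ax = np.arange(5) - 2.0
    raw = np.exp(-np.add.outer(ax**2, ax**2) / (2 * 1.3**2))
    np.testing.assert_allclose(k, raw / raw.sum(), atol=1e-12)


def test_smooth_delta_away_from_edge_reproduces_kernel():
    rows = cols = 12
    hemo = _hemo(np.zeros((2, rows * cols)), rows, cols)
    hemo.hbo2[0, 5 * cols + 5] = 1.0  # delta at (5, 5), kernel fully in-mask
    sm = smooth(hemo, 5, 1.3)
    img = sm.hbo2[0].reshape(rows, cols)
    k = gaussian_kernel(5, 1.3)
    np.testing.assert_allclose(img[3:8, 3:8], k, atol=1e-12)


def test_smooth_constant_in_mask_image_unchanged():
    hemo = _hemo(np.full((3, 80), 2.5))
    sm = smooth(hemo, 5, 1.3)
    np.testing.assert_allclose(sm.hbo2, 2.5, atol=1e-12)


def test_smooth_no_bleed_across_mask_edge():
    """Out-of-mask values must not influence in-mask results: compare against
    an oracle that zero-fills outside the mask and renormalizes the kernel."""
    rows, cols = 8, 10
    brain = np.zeros((rows, cols), bool)
    brain[:, :5] = True  # half-masked plane
    hemi = np.where(brain, 1, 0).astype(np.uint8)
    mask = MaskSet(brain, hemi)
    rng = np.random.default_rng(5)
    data = rng.standard_normal((2, rows * cols))
    data[:, ~brain.ravel()] = 1e6  # poison out-of-mask values
    hemo = HemoStack(data, 0 * data, mask=mask, frame_rate_hz=8.0)
    sm = smooth(hemo, 5, 1.3)

    k = gaussian_kernel(5, 1.3)
    den = ndimage.convolve(brain.astype(float), k, mode="constant")
    frame = (data[0] * brain.ravel()).reshape(rows, cols)
    num = ndimage.convolve(frame, k, mode="constant")
    oracle = num / den
    np.testing.assert_allclose(
        sm.hbo2[0].reshape(rows, cols)[brain], oracle[brain], atol=1e-10
    )


# --------------------------------------------------------- hemispheric regression


def test_regression_removes_its_own_regressor():
    rng = np.random.default_rng(6)
    g = rng.standard_normal(100)
    data = np.tile(g[:, None], (1, 80))
    hemo = _hemo(data)
    out = regress_hemispheric_signal(hemo)
    assert np.max(np.abs(out.hbo2)) < 1e-10


def test_residuals_orthogonal_to_hemispheric_signal():
    rng = np.random.default_rng(7)
    hemo = _hemo(rng.standard_normal((200, 80)))
    out = regress_hemispheric_signal(hemo)
    for side in ("left", "right"):
        flat = hemo.mask.hemi_mask(side).ravel()
        g = hemo.hbo2[:, flat].mean(axis=1)
        gc = g - g.mean()
        res = out.hbo2[:, flat]
        r = gc @ res / (np.linalg.norm(gc) * np.linalg.norm(res, axis=0))
        assert np.all(np.abs(r) < 1e-10)
        assert np.all(np.abs(res.mean(axis=0)) < 1e-12)  # intercept included


def test_trace_orthogonal_to_g_passes_through():
    n = 64
    t = np.arange(n)
    common = np.sin(2 * np.pi * t / 16)
    probe = np.cos(2 * np.pi * t / 8)  # orthogonal to common and mean-free
    data = np.tile(common[:, None], (1, 80))
    hemo = _hemo(data)
    # +probe/-probe on two pixels of the same hemisphere keeps g = common
    hemo.hbo2[:, 3] = common + probe
    hemo.hbo2[:, 4] = common - probe
    out = regress_hemispheric_signal(hemo)
    np.testing.assert_allclose(out.hbo2[:, 3], probe, atol=1e-10)
    np.testing.assert_allclose(out.hbo2[:, 4], -probe, atol=1e-10)


# ----------------------------------------------------------------------- bandpass


def _tone(freq, rate, n):
    return np.sin(2 * np.pi * freq * np.arange(n) / rate)


def test_bandpass_passes_in_band_tone_within_10pct():
    n = 4000
    data = np.tile(_tone(0.08, 8.0, n)[:, None], (1, 80))
    out = bandpass(_hemo(data), (0.02, 0.167))
    mid = slice(n // 4, 3 * n // 4)
    ratio = out.hbo2[mid, 0].std() / data[mid, 0].std()
    assert 0.9 < ratio < 1.1


def test_bandpass_attenuates_stopband_tone_95pct():
    n = 4000
    data = np.tile(_tone(0.5, 8.0, n)[:, None], (1, 80))
    out = bandpass(_hemo(data), (0.02, 0.167))
    assert out.hbo2[:, 0].std() / data[:, 0].std() < 0.05


def test_bandpass_removes_dc_offset():
    data = np.full((4000, 80), 5.0)
    out = bandpass(_hemo(data), (0.02, 0.167))
    assert np.mean(np.abs(out.hbo2)) < 1e-6 * 5.0


def test_bandpass_too_short_series_advises_minimum_length():
    data = np.zeros((10, 80))
    with pytest.raises(PreprocessError, match="frames"):
        bandpass(_hemo(data), (0.02, 0.167))


# ------------------------------------------------------------------------ censor


def test_censor_keeps_quiet_frames_and_drops_constructed_spike():
    rng = np.random.default_rng(8)
    data = 0.01 * rng.standard_normal((50, 80))
    hemo = _hemo(data)
    out = censor_timepoints(hemo, threshold=1.0)
    assert out.censored_frames == []
    hemo.hbo2[23] = 10.0
    out = censor_timepoints(hemo, threshold=1.0)
    assert out.censored_frames == [23]
    assert out.n_frames == 49


def test_censoring_is_idempotent():
    rng = np.random.default_rng(9)
    hemo = _hemo(rng.standard_normal((60, 80)))
    once = censor_timepoints(hemo, threshold=1.0)
    twice = censor_timepoints(once, threshold=1.0)
    assert twice.censored_frames == once.censored_frames
    assert twice.n_frames == once.n_frames


def test_censoring_everything_is_an_error():
    hemo = _hemo(np.ones((10, 80)) * 5)
    with pytest.raises(PreprocessError, match="censor"):
        censor_timepoints(hemo, threshold=0.0)


# ------------------------------------------------------------------- concatenate


def test_concatenate_adds_lengths_and_offsets_censoring():
    rng = np.random.default_rng(10)
    a = censor_timepoints(_hemo(0.01 * rng.standard_normal((40, 80))), 1.0)
    b = _hemo(0.01 * rng.standard_normal((40, 80)))
    b.hbo2[5] = 10.0
    b = censor_timepoints(b, 1.0)
    cat = concatenate_runs([a, b])
    assert cat.n_frames == a.n_frames + b.n_frames
    assert cat.censored_frames == [45]  # index 5 of run 2, offset by 40


def test_concatenate_single_run_is_identity():
    hemo = _hemo(np.random.default_rng(11).standard_normal((20, 80)))
    assert concatenate_runs([hemo]) is hemo


def test_concatenate_mask_mismatch_rejected():
    a = _hemo(np.ones((10, 80)))
    brain = np.ones((8, 10), bool)
    brain[0, 0] = False
    hemi = np.where(np.arange(10)[None, :] < 5, 1, 2).astype(np.uint8)
    hemi = np.broadcast_to(hemi, (8, 10)).copy()
    hemi[0, 0] = 0
    b = HemoStack(np.ones((10, 80)), np.zeros((10, 80)),
                  mask=MaskSet(brain, hemi), frame_rate_hz=8.0)
    with pytest.raises(PreprocessError, match="mask"):
        concatenate_runs([a, b])
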