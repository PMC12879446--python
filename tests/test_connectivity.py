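import numpy as np
import pandas as pd
import pytest

from woifc.connectivity import (
    CorrMatrix,
    RegionTable,
    correlation_matrix,
    extract_homotopic,
    reorder_by_hemisphere_cluster,
    seed_correlation_map,
    unit_traces,
)
from woifc.exceptions import WoifcError
from woifc.masks import MaskSet
from woifc.preprocess import HemoStack
from woifc.study import SUBJECT_REGIONS, pooled_pair_counts, subject_region_table


def _hemo(data, rows, cols):
    brain = np.ones((rows, cols), bool)
    hemi = np.where(np.arange(cols)[None, :] < cols // 2, 1, 2).astype(np.uint8)
    hemi = np.broadcast_to(hemi, (rows, cols)).copy()
    return HemoStack(data, 0 * data, mask=MaskSet(brain, hemi), frame_rate_hz=8.0)


# -------------------------------------------------------------------- unit traces


def test_single_pixel_unit_is_that_pixels_trace():
    rng = np.random.default_rng(0)
    hemo = _hemo(rng.standard_normal((30, 12)), 3, 4)
    traces = unit_traces(hemo, {1: np.array([7])})
    np.testing.assert_array_equal(traces[0], hemo.hbo2[:, 7])


def test_opposite_traces_cancel():
    hemo = _hemo(np.zeros((20, 12)), 3, 4)
    t = np.sin(np.arange(20.0))
    hemo.hbo2[:, 2] = t
    hemo.hbo2[:, 5] = -t
    traces = unit_traces(hemo, {1: np.array([2, 5])})
    np.testing.assert_allclose(traces[0], 0.0, atol=1e-15)


def test_unit_mean_matches_naive_loop():
    rng = np.random.default_rng(1)
    hemo = _hemo(rng.standard_normal((25, 12)), 3, 4)
    idx = np.array([0, 3, 7, 11])
    traces = unit_traces(hemo, {1: idx})
    naive = np.zeros(25)
    for i in idx:
        naive += hemo.hbo2[:, i]
    naive /= len(idx)
    np.testing.assert_allclose(traces[0], naive, atol=1e-12)


def test_empty_unit_is_an_error():
    hemo = _hemo(np.zeros((5, 12)), 3, 4)
    with pytest.raises(WoifcError, match="no member pixels"):
        unit_traces(hemo, {1: np.array([], dtype=int)})


# ------------------------------------------------------------- correlation matrix


def test_correlation_matrix_invariants_and_transpose():
    rng = np.random.default_rng(2)
    traces = rng.standard_normal((5, 100))
    corr = correlation_matrix(traces, [1, 2, 3, 4, 5])
    np.testing.assert_array_equal(corr.values, corr.values.T)
    np.testing.assert_allclose(np.diag(corr.values), 1.0)
    assert np.all(np.abs(corr.values) <= 1.0)


def test_zero_variance_unit_named_in_error():
    traces = np.vstack([np.random.default_rng(3).standard_normal((2, 50)),
                        np.full((1, 50), 3.3)])
    with pytest.raises(WoifcError, match=r"\[30\]"):
        correlation_matrix(traces, [10, 20, 30])


def test_two_path_equality_pixel_vs_unit_traces(small_hemo, small_sim):
    """Region correlations computed from pixel traces directly equal the
    correlations of unit_traces outputs to 1e-12."""
    _, _, truth = small_sim
    membership = {rid: truth.region_pixels(rid) for rid in truth.region_labels}
    traces = unit_traces(small_hemo, membership)
    corr = correlation_matrix(traces, sorted(membership))
    # direct path: average pixel traces by hand, then corrcoef
    direct = np.corrcoef(
        np.stack([small_hemo.hbo2[:, membership[r]].mean(axis=1)
                  for r in sorted(membership)])
    )
    np.testing.assert_allclose(corr.values, direct, atol=1e-12)


# ---------------------------------------------------------------------- reorder


def _labeled_corr(seed=4):
    rng = np.random.default_rng(seed)
    traces = rng.standard_normal((6, 80))
    labels = pd.DataFrame(
        {
            "unit_id": [1, 2, 3, 4, 5, 6],
            "hemisphere": ["right", "left", "right", "left", "left", "right"],
            "cluster": [2, 1, 1, 2, 1, 2],
        }
    )
    return correlation_matrix(traces, labels, level="parcel")


def test_reorder_groups_left_first_then_cluster():
    out = reorder_by_hemisphere_cluster(_labeled_corr())
    hemis = out.labels["hemisphere"].tolist()
    assert hemis == sorted(hemis, key=["left", "right"].index)
    left = out.labels[out.labels.hemisphere == "left"]
    assert left["cluster"].tolist() == sorted(left["cluster"].tolist())


def test_reorder_already_ordered_is_identity():
    corr = _labeled_corr()
    once = reorder_by_hemisphere_cluster(corr)
    twice = reorder_by_hemisphere_cluster(once)
    np.testing.assert_array_equal(twice.permutation, np.arange(corr.n))
    np.testing.assert_array_equal(once.values, twice.values)


def test_reorder_preserves_value_multiset_and_eigenvalues():
    corr = _labeled_corr()
    out = reorder_by_hemisphere_cluster(corr)
    assert sorted(out.off_diagonal()) == pytest.approx(sorted(corr.off_diagonal()))
    np.testing.assert_allclose(
        np.sort(np.linalg.eigvalsh(out.values)),
        np.sort(np.linalg.eigvalsh(corr.values)),
        atol=1e-12,
    )


def test_cross_quadrant_diagonal_equals_extract_homotopic():
    rng = np.random.default_rng(5)
    traces = rng.standard_normal((6, 120))
    # regions: three names, each left+right
    table = RegionTable(
        pd.DataFrame(
            {
                "region_id": [1, 2, 3, 4, 5, 6],
                "name": ["a", "b", "c", "a", "b", "c"],
                "hemisphere": ["left"] * 3 + ["right"] * 3,
            }
        )
    )
    labels = table.table.rename(columns={"region_id": "unit_id"}).assign(cluster=1)
    corr = correlation_matrix(traces, labels)
    homo, _ = extract_homotopic(corr, table)
    ordered = reorder_by_hemisphere_cluster(corr)
    cross = ordered.quadrant("left", "right")
    # left block order a,b,c matches right block order a,b,c -> diagonal
    np.testing.assert_allclose(np.sort(np.diag(cross)), np.sort(homo), atol=1e-12)


def test_reorder_requires_labels():
    rng = np.random.default_rng(6)
    corr = correlation_matrix(rng.standard_normal((3, 40)), [1, 2, 3])
    with pytest.raises(WoifcError, match="hemisphere"):
        reorder_by_hemisphere_cluster(corr)


# ----------------------------------------------------------------- homotopic split


def test_homotopic_counts_ten_regions_five_pairs():
    rng = np.random.default_rng(7)
    table = RegionTable(
        pd.DataFrame(
            {
                "region_id": range(1, 11),
                "name": [f"r{i}" for i in range(5)] * 2,
                "hemisphere": ["left"] * 5 + ["right"] * 5,
            }
        )
    )
    corr = correlation_matrix(rng.standard_normal((10, 60)), list(range(1, 11)))
    homo, non = extract_homotopic(corr, table)
    assert len(homo) == 5
    assert len(non) == 40
    assert len(homo) + len(non) == 10 * 9 // 2


def test_no_partners_gives_empty_homotopic_pool():
    rng = np.random.default_rng(8)
    table = RegionTable(
        pd.DataFrame(
            {"region_id": [1, 2, 3], "name": ["x", "y", "z"],
             "hemisphere": ["left", "left", "left"]}
        )
    )
    corr = correlation_matrix(rng.standard_normal((3, 60)), [1, 2, 3])
    homo, non = extract_homotopic(corr, table)
    assert homo.size == 0 and non.size == 3


def test_partner_missing_from_matrix_is_an_error():
    rng = np.random.default_rng(9)
    table = RegionTable(
        pd.DataFrame(
            {"region_id": [1, 2, 3], "name": ["a", "a", "b"],
             "hemisphere": ["left", "right", "left"]}
        )
    )
    corr = correlation_matrix(rng.standard_normal((2, 60)), [1, 3])
    with pytest.raises(WoifcError, match="partner"):
        extract_homotopic(corr, table)


def test_study_cohort_pools_thirty_homotopic_and_84_cross_pairs():
    """Pooling region-level correlations over the eight-subject cohort with
    its per-subject region coverage yields 30 homotopic and 84 cross-
    hemisphere non-homotopic values."""
    assert pooled_pair_counts() == (30, 84)
    rng = np.random.default_rng(10)
    homo_n = non_n = 0
    for subject in SUBJECT_REGIONS:
        table = subject_region_table(subject)
        k = len(table.region_ids)
        corr = correlation_matrix(rng.standard_normal((k, 50)), table.table)
        homo, non = extract_homotopic(corr, table, scope="cross_hemisphere")
        homo_n += len(homo)
        non_n += len(non)
    assert homo_n == 30
    assert non_n == 84
    # per-region homotopic sample sizes across the cohort
    counts = {}
    for regions in SUBJECT_REGIONS.values():
        for r in regions:
            counts[r] = counts.get(r, 0) + 1
    assert counts == {
        "nidopallium": 2,
        "mesopallium": 7,
        "somatosensory_wulst": 8,
        "visual_wulst": 8,
        "hippocampal_formation": 5,
    }


# -------------------------------------------------------------------- seed maps


def test_seed_map_construction_on_single_region(clean_sim):
    """On artifact-free data (no global/hemispheric component), seeding a
    region yields a map of ~1 across that region's interior."""
    from scipy import ndimage

    from woifc.preprocess import preprocess_stack

    raw, mask, truth = clean_sim
    hemo = preprocess_stack(raw, mask, do_regress=False, do_censor=False)
    rid = 1
    interior = ndimage.binary_erosion(
        truth.region_map == rid, structure=np.ones((3, 3)), iterations=2
    )
    seed_px = np.flatnonzero(interior.ravel())
    img = seed_correlation_map(hemo, seed_px)
    assert np.nanmin(img.ravel()[seed_px]) > 0.99


def test_seed_map_pixel_matching_seed_mean_has_r_one():
    rng = np.random.default_rng(11)
    hemo = _hemo(rng.standard_normal((50, 12)), 3, 4)
    hemo.hbo2[:, 5] = hemo.hbo2[:, [2, 5, 9]].mean(axis=1)
    img = seed_correlation_map(hemo, np.array([5]))
    assert np.isclose(img.ravel()[5], 1.0)


def test_seed_map_bounded_and_sentinel_outside_mask(small_hemo):
    flat_idx = np.flatnonzero(small_hemo.mask.analysis.ravel())
    img = seed_correlation_map(small_hemo, flat_idx[:10])
    vals = img.ravel()[flat_idx]
    assert np.all(np.abs(vals) <= 1.0)
    outside = img[~small_hemo.mask.analysis]
    assert np.isnan(outside).all()


def test_out_of_mask_seed_rejected(small_hemo):
    bad = np.flatnonzero(~small_hemo.mask.analysis.ravel())[:1]
    with pytest.raises(WoifcError, match="analysis mask"):
        seed_correlation_map(small_hemo, bad)
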