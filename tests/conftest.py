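"""Shared fixtures: synthetic recordings at several scales.

Everything is generated programmatically; the expensive default-scale
recovery scenario is computed once per session and shared.
"""
from __future__ import annotations

import numpy as np
import pytest

from woifc.connectivity import RegionTable, correlation_matrix, extract_homotopic, unit_traces
from woifc.parcellation import parcellate, pixelwise_hemisphere_clusters
from woifc.preprocess import preprocess_stack
from woifc.synthetic import Scenario, simulate


SMALL = Scenario(
    shape=(24, 32), n_regions_per_hemisphere=3, n_frames=600, seed=7,
)


@pytest.fixture(scope="session")
def small_sim():
    """Small synthetic recording (24x32, 3 regions/hemisphere, 600 frames)."""
    raw, mask, truth = simulate(SMALL)
    return raw, mask, truth


@pytest.fixture(scope="session")
def small_hemo(small_sim):
    raw, mask, truth = small_sim
    return preprocess_stack(raw, mask)


@pytest.fixture(scope="session")
def clean_sim():
    """Noise- and artifact-free variant of the small scenario."""
    sc = SMALL.clean()
    raw, mask, truth = simulate(sc)
    return raw, mask, truth


@pytest.fixture(scope="session")
def default_recovery():
    """Full pipeline run on the default study-condition scenario (seed 1).

    Returns a dict with the ground truth, preprocessed stack, parcellation
    products, and region-level connectivity summaries.
    """
    raw, mask, truth = simulate(Scenario(seed=1))
    hemo = preprocess_stack(raw, mask)
    parcels, clusters, vein = parcellate(hemo)
    table = RegionTable.from_ground_truth(truth)
    corr = correlation_matrix(unit_traces(hemo, table.membership), table.table)
    homo, non = extract_homotopic(corr, table)
    pixel_clusters = pixelwise_hemisphere_clusters(parcels, clusters, hemo.mask)
    return {
        "truth": truth,
        "hemo": hemo,
        "parcels": parcels,
        "clusters": clusters,
        "vein": vein,
        "table": table,
        "corr": corr,
        "homotopic": homo,
        "non_homotopic": non,
        "pixel_clusters": pixel_clusters,
    }
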