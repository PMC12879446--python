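"""Region coverage of the motivating pigeon wide-field imaging cohort.

Eight subjects were imaged through windows at two placements (rostral,
closer to the beak, or caudal, toward the cerebellum), so the set of major
anatomical regions visible bilaterally varies between subjects: the
nidopallium edge appears only in rostral windows, the hippocampal formation
mostly in caudal ones, and the somatosensory and visual Wulst in all.

``SUBJECT_REGIONS`` lists, per subject, the regions visible in *both*
hemispheres. Each such region contributes one homotopic pair, and each
ordered-name cross-hemisphere pairing of distinct regions contributes one
non-homotopic cross-hemisphere pair, which is how region-level correlations
are pooled across the cohort.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import RegionTable

__all__ = ["REGIONS", "SUBJECT_REGIONS", "subject_region_table", "pooled_pair_counts"]

REGIONS = (
    "nidopallium",
    "mesopallium",
    "somatosensory_wulst",
    "visual_wulst",
    "hippocampal_formation",
)

#: per-subject bilaterally visible regions (rostral subjects first)
SUBJECT_REGIONS: dict[str, tuple[str, ...]] = {
    "rostral_1": ("nidopallium", "mesopallium", "somatosensory_wulst", "visual_wulst"),
    "rostral_2": ("nidopallium", "mesopallium", "somatosensory_wulst", "visual_wulst"),
    "caudal_1": ("mesopallium", "somatosensory_wulst", "visual_wulst", "hippocampal_formation"),
    "caudal_2": ("mesopallium", "somatosensory_wulst", "visual_wulst", "hippocampal_formation"),
    "caudal_3": ("mesopallium", "somatosensory_wulst", "visual_wulst", "hippocampal_formation"),
    "caudal_4": ("mesopallium", "somatosensory_wulst", "visual_wulst", "hippocampal_formation"),
    "caudal_5": ("somatosensory_wulst", "visual_wulst", "hippocampal_formation"),
    "caudal_6": ("mesopallium", "somatosensory_wulst", "visual_wulst"),
}


def subject_region_table(subject: str) -> RegionTable:
    """Left/right region table for one subject (no pixel membership)."""
    names = SUBJECT_REGIONS[subject]
    rows = []
    rid = 1
    for hemi in ("left", "right"):
        for name in names:
            rows.append({"region_id": rid, "name": name, "hemisphere": hemi})
            rid += 1
    return RegionTable(pd.DataFrame(rows))


def pooled_pair_counts() -> tuple[int, int]:
    """(homotopic, cross-hemisphere non-homotopic) pair counts pooled over subjects."""
    homo = sum(len(v) for v in SUBJECT_REGIONS.values())
    non = sum(len(v) * (len(v) - 1) for v in SUBJECT_REGIONS.values())
    return homo, non
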