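"""Correlation matrices, homotopic pairings, and seed maps.

Units can be pixels, parcels, clusters, or named regions; in every case the
unit trace is the mean HbO2 contrast over member pixels and the matrix is
the plain Pearson correlation of those traces (average-then-correlate, not
the average of pixel-pair correlations). Homotopic partnership is declared
in a :class:`RegionTable` — two regions sharing a name across hemispheres —
not inferred from geometry.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import WoifcError
from .preprocess import HemoStack

__all__ = [
    "CorrMatrix",
    "RegionTable",
    "unit_traces",
    "correlation_matrix",
    "reorder_by_hemisphere_cluster",
    "extract_homotopic",
    "seed_correlation_map",
]

_HEMI_ORDER = {"left": 0, "right": 1}


@dataclass
class CorrMatrix:
    """Symmetric unit-diagonal Pearson matrix with ordered unit labels.

    ``labels`` is a DataFrame with one row per unit; it always has a
    ``unit_id`` column and may carry ``hemisphere``, ``cluster`` and
    ``name``. ``ordering`` documents the sort key of the current layout;
    ``permutation`` maps current positions to the positions of the matrix
    this one was reordered from (None for an original matrix).
    """

    values: np.ndarray
    labels: pd.DataFrame
    level: str = "region"
    ordering: str = "input"
    permutation: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = v.shape[0]
        if v.shape != (n, n):
            raise WoifcError("correlation matrix must be square")
        if len(self.labels) != n:
            raise WoifcError("one label row per matrix row required")
        if not np.allclose(v, v.T, atol=1e-8):
            raise WoifcError("correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1.0 + 1e-8):
            raise WoifcError("correlation values must lie in [-1, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=1e-8):
            raise WoifcError("correlation matrix must have a unit diagonal")
        v = np.clip((v + v.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(v, 1.0)
        self.values = v
        self.labels = self.labels.reset_index(drop=True)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def off_diagonal(self) -> np.ndarray:
        """Unique off-diagonal values (upper triangle, row-major)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def index_of(self, unit_id: int) -> int:
        pos = np.flatnonzero(self.labels["unit_id"].to_numpy() == unit_id)
        if pos.size != 1:
            raise WoifcError(f"unit {unit_id} not present exactly once")
        return int(pos[0])

    def quadrant(self, hemi_row: str, hemi_col: str) -> np.ndarray:
        if "hemisphere" not in self.labels:
            raise WoifcError("labels carry no hemisphere column")
        h = self.labels["hemisphere"].to_numpy()
        return self.values[np.ix_(h == hemi_row, h == hemi_col)]

    def to_frame(self) -> pd.DataFrame:
        ids = self.labels["unit_id"].tolist()
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass
class RegionTable:
    """Named regions, their member pixels/parcels, and homotopic partners.

    Homotopic partners share a ``name`` and differ in ``hemisphere``; the
    partnership is symmetric and at most one partner exists per region.
    """

    table: pd.DataFrame  # region_id, name, hemisphere
    membership: dict[int, np.ndarray] = field(default_factory=dict)  # region -> flat px

    def __post_init__(self) -> None:
        required = {"region_id", "name", "hemisphere"}
        if not required <= set(self.table.columns):
            raise WoifcError(f"region table needs columns {sorted(required)}")
        if self.table["region_id"].duplicated().any():
            raise WoifcError("duplicate region ids")
        dup = self.table.groupby(["name", "hemisphere"]).size()
        if (dup > 1).any():
            raise WoifcError("a (name, hemisphere) pair appears more than once")
        self.table = self.table.reset_index(drop=True)

    @property
    def region_ids(self) -> list[int]:
        return self.table["region_id"].tolist()

    def partner_map(self) -> dict[int, int]:
        """region_id -> homotopic partner region_id (same name, other side)."""
        out: dict[int, int] = {}
        for name, grp in self.table.groupby("name"):
            if len(grp) == 2:
                a, b = grp["region_id"].tolist()
                out[a] = b
                out[b] = a
        return out

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        pm = self.partner_map()
        return sorted({tuple(sorted((a, b))) for a, b in pm.items()})

    @classmethod
    def from_ground_truth(cls, truth) -> "RegionTable":
        rows = [
            {"region_id": rid, "name": name, "hemisphere": hemi}
            for rid, (name, hemi) in sorted(truth.region_labels.items())
        ]
        membership = {rid: truth.region_pixels(rid) for rid in truth.region_labels}
        return cls(pd.DataFrame(rows), membership)

    @classmethod
    def from_parcels(
        cls,
        parcel_ids: Iterable[int],
        parcel_pixels: Mapping[int, np.ndarray],
        parcel_region: Mapping[int, tuple[str, str]],
    ) -> "RegionTable":
        """Group parcels into regions via a user-supplied (name, hemisphere) label table."""
        groups: dict[tuple[str, str], list[int]] = {}
        for pid in parcel_ids:
            groups.setdefault(parcel_region[pid], []).append(pid)
        rows, membership = [], {}
        for rid, ((name, hemi), pids) in enumerate(sorted(groups.items()), start=1):
            rows.append({"region_id": rid, "name": name, "hemisphere": hemi})
            membership[rid] = np.concatenate([np.asarray(parcel_pixels[p]) for p in pids])
        return cls(pd.DataFrame(rows), membership)


def unit_traces(hemo: HemoStack, membership: Mapping[int, np.ndarray]) -> np.ndarray:
    """(n_units, n_frames) mean HbO2 trace per unit, ordered by sorted unit id."""
    out = []
    for uid in sorted(membership):
        idx = np.asarray(membership[uid])
        if idx.size == 0:
            raise WoifcError(f"unit {uid} has no member pixels")
        out.append(hemo.hbo2[:, idx].mean(axis=1))
    return np.asarray(out)


def correlation_matrix(
    traces: np.ndarray, labels: pd.DataFrame | Iterable[int], level: str = "region"
) -> CorrMatrix:
    """Pearson matrix over unit traces with labels attached."""
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] < 2:
        raise WoifcError("traces must be (n_units, n_frames>=2)")
    sd = traces.std(axis=1)
    tol = 1e-12 * max(float(np.abs(traces).max()), 1.0)
    if np.any(sd <= tol):
        if isinstance(labels, pd.DataFrame):
            ids = labels["unit_id"].to_numpy() if "unit_id" in labels.columns else (
                labels.get("region_id", labels.iloc[:, 0])
            ).to_numpy()
        else:
            ids = np.asarray(list(labels))
        bad = ids[sd <= tol].tolist()
        raise WoifcError(f"zero-variance units: {bad}")
    values = np.corrcoef(traces)
    if not isinstance(labels, pd.DataFrame):
        labels = pd.DataFrame({"unit_id": list(labels)})
    elif "unit_id" not in labels.columns:
        for alias in ("region_id", "parcel_id"):
            if alias in labels.columns:
                labels = labels.rename(columns={alias: "unit_id"})
                break
        else:
            raise WoifcError("labels need a unit_id (or region_id/parcel_id) column")
    return CorrMatrix(values, labels, level=level)


def reorder_by_hemisphere_cluster(corr: CorrMatrix, clusters=None) -> CorrMatrix:
    """Permute a matrix into hemisphere-major, cluster-grouped order.

    Left-hemisphere units first, then right; within a hemisphere units are
    grouped by cluster id and sorted by unit id inside a cluster. The
    permutation is recorded, so the reordering is a pure relabeling: the
    multiset of off-diagonal values (and the eigenvalues) are unchanged.
    """
    labels = corr.labels.copy()
    if clusters is not None:
        split = clusters.hemisphere_split
        ids = labels["unit_id"].to_numpy()
        labels["hemisphere"] = [split[i][0] for i in ids]
        labels["cluster"] = [split[i][1] for i in ids]
    for col in ("hemisphere", "cluster"):
        if col not in labels or labels[col].isna().any():
            raise WoifcError(f"every unit needs a '{col}' label to reorder")
    hemi_rank = labels["hemisphere"].map(_HEMI_ORDER)
    if hemi_rank.isna().any():
        bad = labels.loc[hemi_rank.isna(), "unit_id"].tolist()
        raise WoifcError(f"units with unknown hemisphere: {bad}")
    order = np.lexsort(
        (labels["unit_id"].to_numpy(), labels["cluster"].to_numpy(), hemi_rank.to_numpy())
    )
    return CorrMatrix(
        corr.values[np.ix_(order, order)],
        labels.iloc[order],
        level=corr.level,
        ordering="hemisphere,cluster,unit_id",
        permutation=order,
    )


def extract_homotopic(
    corr: CorrMatrix, table: RegionTable, scope: str = "all"
) -> tuple[np.ndarray, np.ndarray]:
    """Split off-diagonal correlations into homotopic and non-homotopic pools.

    ``scope="all"`` pools every remaining off-diagonal pair once
    (|homotopic| + |non-homotopic| = n(n-1)/2); ``scope="cross_hemisphere"``
    restricts the non-homotopic pool to pairs spanning the two hemispheres,
    the pooling used for cross-subject region comparisons.
    """
    if scope not in ("all", "cross_hemisphere"):
        raise WoifcError(f"unknown scope {scope!r}")
    pm = table.partner_map()
    ids = corr.labels["unit_id"].to_numpy()
    present = set(int(i) for i in ids)
    for a, b in pm.items():
        if a in present and b not in present:
            raise WoifcError(f"region {a} present without its partner {b}")
    hemi = dict(zip(table.table["region_id"], table.table["hemisphere"]))
    homo, non = [], []
    for i in range(corr.n):
        for j in range(i + 1, corr.n):
            a, b = int(ids[i]), int(ids[j])
            if pm.get(a) == b:
                homo.append(corr.values[i, j])
            else:
                if scope == "cross_hemisphere" and hemi.get(a) == hemi.get(b):
                    continue
                non.append(corr.values[i, j])
    return np.asarray(homo), np.asarray(non)


def seed_correlation_map(
    hemo: HemoStack, seed_pixels: np.ndarray, sentinel: float = np.nan
) -> np.ndarray:
    """Image of correlations between a seed-mean trace and every masked pixel.

    ``seed_pixels`` are flat indices inside the analysis mask; out-of-mask
    pixels receive ``sentinel``.
    """
    seed_pixels = np.asarray(seed_pixels)
    flat_mask = hemo.mask.analysis.ravel()
    if seed_pixels.size == 0:
        raise WoifcError("seed is empty")
    if not flat_mask[seed_pixels].all():
        raise WoifcError("seed pixels must lie inside the analysis mask")
    seed = hemo.hbo2[:, seed_pixels].mean(axis=1)
    seed_c = seed - seed.mean()
    denom_seed = float(np.sqrt(seed_c @ seed_c))
    if denom_seed == 0:
        raise WoifcError("seed trace has zero variance")
    traces = hemo.hbo2[:, flat_mask]
    tc = traces - traces.mean(axis=0, keepdims=True)
    denom_px = np.sqrt((tc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (seed_c @ tc) / (denom_seed * denom_px)
    out = np.full(flat_mask.shape, sentinel)
    out[flat_mask] = np.clip(r, -1.0, 1.0)
    return out.reshape(hemo.spatial_shape)
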