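"""SVD-seeded iterative parcellation and hierarchical cluster cutting.

The parcellation partitions masked pixels by functional time course:

1.  The pixel-pixel Pearson correlation matrix is decomposed (SVD of the
    symmetric matrix, i.e. its eigenstructure ordered by magnitude); each
    of the leading ceil(n_parcels/2) singular vectors spawns a positive and
    a negative candidate parcel, and every pixel joins the candidate with
    the largest magnitude-weighted signed loading.
2.  Parcel mean traces are computed, every pixel is correlated against
    every parcel trace and reassigned to its maximum-correlation parcel;
    this repeats until no assignment changes (a fixed point) or an
    iteration cap is reached. Ties keep the current parcel when possible,
    otherwise go to the lowest parcel id; emptied parcels are dropped
    between iterations.
3.  Parcels whose centroid falls on the midline vein stripe are masked out
    and the whole procedure runs a second time without them.
4.  Parcel mean traces are hierarchically clustered (average linkage on
    correlation distance 1 - r) and the dendrogram is cut at the shallowest
    level yielding at least ``min_clusters`` clusters; clusters are then
    split by hemisphere into hemisphere-specific cluster ids.

The two estimators follow scikit-learn conventions (``fit`` on an
(n_samples, n_features) = (n_pixels, n_frames) matrix, trailing-underscore
fitted attributes, ``get_params``/``set_params``) and compose with sklearn
tooling; the module-level functions are thin wrappers operating on pipeline
containers.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array

from .connectivity import CorrMatrix
from .exceptions import ParcellationError
from .masks import MaskSet, HEMI_LEFT, HEMI_RIGHT
from .preprocess import HemoStack

__all__ = [
    "ParcelMap",
    "ClusterAssignment",
    "IterativeParcellation",
    "TraceHierarchy",
    "pixel_correlation_matrix",
    "svd_initial_parcels",
    "iterate_parcels",
    "detect_vein_parcels",
    "cluster_parcels",
    "split_clusters_by_hemisphere",
    "pixelwise_hemisphere_clusters",
    "parcellate",
]


# ---------------------------------------------------------------------------
# containers


@dataclass
class ParcelMap:
    """Pixel -> parcel partition over the analysis mask.

    ``assignment`` is a full raster (0 = unassigned/masked, parcels numbered
    contiguously from 1). ``parcel_traces`` holds the (n_parcels, n_frames)
    mean HbO2 traces of the final assignment.
    """

    assignment: np.ndarray
    n_parcels: int
    iterations_run: int = 0
    converged: bool = False
    parcel_traces: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=np.int32)
        present = np.unique(self.assignment[self.assignment > 0])
        if len(present) != self.n_parcels or (
            len(present) and (present.min() != 1 or present.max() != self.n_parcels)
        ):
            raise ParcellationError(
                f"parcel ids must be contiguous 1..{self.n_parcels}, got {present.tolist()[:10]}"
            )

    def parcel_pixels(self, parcel_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment.ravel() == parcel_id)

    def membership(self) -> dict[int, np.ndarray]:
        return {pid: self.parcel_pixels(pid) for pid in range(1, self.n_parcels + 1)}

    def centroids(self) -> dict[int, tuple[float, float]]:
        """parcel id -> (row, col) pixel centroid."""
        rows, cols = self.assignment.shape
        out = {}
        for pid in range(1, self.n_parcels + 1):
            idx = self.parcel_pixels(pid)
            out[pid] = (float(np.mean(idx // cols)), float(np.mean(idx % cols)))
        return out


@dataclass
class ClusterAssignment:
    """Parcel -> cluster partition from a minimal-depth dendrogram cut."""

    parcel_to_cluster: dict[int, int]
    linkage_tree: np.ndarray
    cut_height: float
    n_clusters: int
    hemisphere_split: dict[int, tuple[str, int]] = field(default_factory=dict)
    ordering: list[int] = field(default_factory=list)  # parcels in display order

    def cluster_members(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for p, c in sorted(self.parcel_to_cluster.items()):
            out.setdefault(c, []).append(p)
        return out


# ---------------------------------------------------------------------------
# core numerics


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Rows scaled to zero mean, unit L2 norm (zero-variance rows -> zero)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.sqrt((Xc**2).sum(axis=1))
    norm[norm == 0] = np.inf
    return Xc / norm[:, None]


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Map present parcel ids onto 1..k preserving order."""
    present = np.unique(labels)
    lut = np.zeros(int(present.max()) + 1, dtype=labels.dtype)
    lut[present] = np.arange(1, len(present) + 1)
    return lut[labels]


def _parcel_means(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    sums = np.zeros((k, X.shape[1]))
    np.add.at(sums, labels - 1, X)
    counts = np.bincount(labels - 1, minlength=k).astype(float)
    return sums / counts[:, None]


def _signed_svd_assignment(corr: np.ndarray, n_parcels: int) -> np.ndarray:
    """Initial assignment from signed loadings of leading singular vectors."""
    n = corr.shape[0]
    m = int(np.ceil(n_parcels / 2))
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(-np.abs(eigvals))[:m]
    sv = np.abs(eigvals[order])  # singular values of the symmetric matrix
    V = eigvecs[:, order]  # (n, m)
    # candidates 2j (positive lobe) and 2j+1 (negative lobe) of vector j
    scores = np.empty((n, 2 * m))
    scores[:, 0::2] = sv[None, :] * np.maximum(V, 0.0)
    scores[:, 1::2] = sv[None, :] * np.maximum(-V, 0.0)
    labels = np.argmax(scores, axis=1) + 1  # ties -> lowest candidate index
    labels = _relabel_contiguous(labels)
    if labels.max() < 2:
        raise ParcellationError(
            "degenerate data: fewer than two non-empty initial parcels"
        )
    return labels.astype(np.int32)


def _iterate_assignments(
    X: np.ndarray, labels: np.ndarray, max_iter: int
) -> tuple[np.ndarray, int, bool]:
    """Fixed-point iteration of the reassign-to-max-correlation rule."""
    Xs = _standardize_rows(X)
    labels = _relabel_contiguous(np.asarray(labels, dtype=np.int32))
    seen: set[bytes] = set()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        k = int(labels.max())
        traces = _parcel_means(X, labels, k)
        R = Xs @ _standardize_rows(traces).T  # (n_pixels, k) Pearson r
        best = R.max(axis=1)
        first_best = np.argmax(R, axis=1) + 1  # lowest parcel id among ties
        keep_current = R[np.arange(len(labels)), labels - 1] == best
        new = np.where(keep_current, labels, first_best).astype(np.int32)
        if np.array_equal(new, labels):
            converged = True
            break
        new = _relabel_contiguous(new)
        state = new.tobytes()
        if state in seen:
            warnings.warn(
                "parcel assignment oscillates without a fixed point; "
                "stopping without convergence",
                stacklevel=2,
            )
            labels = new
            break
        seen.add(state)
        labels = new
    return labels, it, converged


# ---------------------------------------------------------------------------
# estimators


class IterativeParcellation(ClusterMixin, BaseEstimator):
    """SVD-seeded iterative parcellation of pixel time courses.

    Parameters
    ----------
    n_parcels : int, default=30
        Requested number of initial parcels; realized as the non-empty
        candidates among 2*ceil(n_parcels/2) signed singular-vector lobes,
        and possibly reduced further as parcels empty during iteration.
    max_iter : int, default=100
        Iteration cap; the fixed-point iteration has no convergence
        guarantee, so non-convergence is reported, not fatal.

    Attributes
    ----------
    labels_ : (n_samples,) int array, parcel ids 1..n_parcels_.
    initial_labels_ : assignment after the SVD seeding step.
    parcel_traces_ : (n_parcels_, n_features) final parcel mean traces.
    n_iter_ : iterations executed; converged_ : fixed point reached.
    """

    def __init__(self, n_parcels: int = 30, max_iter: int = 100):
        self.n_parcels = n_parcels
        self.max_iter = max_iter

    def fit(self, X: np.ndarray, y: None = None) -> "IterativeParcellation":
        X = check_array(X, dtype=np.float64)
        if self.n_parcels < 2:
            raise ParcellationError("n_parcels must be >= 2")
        if X.shape[1] < 2:
            raise ParcellationError("need at least 2 frames per pixel")
        sd = X.std(axis=1)
        if np.any(sd == 0):
            raise ParcellationError(
                f"zero-variance pixels at rows {np.flatnonzero(sd == 0).tolist()[:20]}"
            )
        Xs = _standardize_rows(X)
        corr = np.clip(Xs @ Xs.T, -1.0, 1.0)
        np.fill_diagonal(corr, 1.0)
        self.initial_labels_ = _signed_svd_assignment(corr, self.n_parcels)
        self.labels_, self.n_iter_, self.converged_ = _iterate_assignments(
            X, self.initial_labels_, self.max_iter
        )
        self.n_parcels_ = int(self.labels_.max())
        self.parcel_traces_ = _parcel_means(X, self.labels_, self.n_parcels_)
        return self

    def audit_fixed_point(self, X: np.ndarray) -> int:
        """Number of pixels whose own parcel is not a maximum-correlation parcel.

        Zero for every converged fit (the defining fixed-point property).
        """
        X = np.asarray(X, dtype=float)
        Xs = _standardize_rows(X)
        R = Xs @ _standardize_rows(self.parcel_traces_).T
        own = R[np.arange(len(self.labels_)), self.labels_ - 1]
        return int(np.sum(own < R.max(axis=1)))


class TraceHierarchy(ClusterMixin, BaseEstimator):
    """Average-linkage hierarchy over traces with a minimal-depth cut.

    Distances are 1 - Pearson correlation. The dendrogram is cut at the
    largest merge height whose induced partition still has at least
    ``min_clusters`` clusters (merges strictly below ``cut_height_`` are
    applied), i.e. the first grouping level, counted from the top, with
    that many clusters.
    """

    def __init__(self, min_clusters: int = 8, linkage: str = "average"):
        self.min_clusters = min_clusters
        self.linkage = linkage

    def fit(self, X: np.ndarray, y: None = None) -> "TraceHierarchy":
        X = check_array(X, dtype=np.float64)
        n = X.shape[0]
        if self.min_clusters > n:
            raise ParcellationError(
                f"min_clusters ({self.min_clusters}) exceeds number of traces ({n})"
            )
        if self.min_clusters < 1:
            raise ParcellationError("min_clusters must be >= 1")
        dist = pdist(X, metric="correlation")  # 1 - r
        Z = hierarchy.linkage(dist, method=self.linkage)
        heights = Z[:, 2]
        if self.min_clusters == n:
            cut = float(heights[0]) if len(heights) else 0.0
        else:
            cut = float(heights[n - self.min_clusters])
        labels = self._cut(Z, n, cut)
        self.linkage_ = Z
        self.cut_height_ = cut
        self.labels_ = labels
        self.n_clusters_ = int(labels.max())
        return self

    @staticmethod
    def _cut(Z: np.ndarray, n: int, cut: float) -> np.ndarray:
        """Apply merges with height strictly below ``cut``; contiguous ids
        ordered by each cluster's first member."""
        parent = list(range(n + len(Z)))

        def find(a: int) -> int:
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for i, (a, b, h, _) in enumerate(Z):
            if h < cut:
                ra, rb = find(int(a)), find(int(b))
                parent[ra] = parent[rb] = n + i
        roots = [find(i) for i in range(n)]
        labels = np.zeros(n, dtype=np.int32)
        next_id = 0
        seen: dict[int, int] = {}
        for i, r in enumerate(roots):
            if r not in seen:
                next_id += 1
                seen[r] = next_id
            labels[i] = seen[r]
        return labels


# ---------------------------------------------------------------------------
# pipeline-facing wrappers


def pixel_correlation_matrix(hemo: HemoStack) -> CorrMatrix:
    """Pearson matrix over analysis-mask pixel traces with pixel lookup."""
    traces = hemo.analysis_traces("hbo2")  # (T, n_pix)
    if traces.shape[0] < 2:
        raise ParcellationError("need at least 2 frames after censoring")
    flat_idx = np.flatnonzero(hemo.mask.analysis.ravel())
    sd = traces.std(axis=0)
    if np.any(sd == 0):
        raise ParcellationError(
            f"zero-variance pixels at flat indices {flat_idx[sd == 0].tolist()[:20]}"
        )
    Xs = _standardize_rows(traces.T)
    corr = np.clip(Xs @ Xs.T, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrMatrix(
        corr, pd.DataFrame({"unit_id": flat_idx}), level="pixel", ordering="flat_index"
    )


def _labels_to_map(
    labels: np.ndarray,
    flat_idx: np.ndarray,
    shape: tuple[int, int],
    iterations: int = 0,
    converged: bool = False,
    traces: np.ndarray | None = None,
) -> ParcelMap:
    raster = np.zeros(shape, dtype=np.int32)
    raster.ravel()[flat_idx] = labels
    return ParcelMap(raster, int(labels.max()), iterations, converged, traces)


def svd_initial_parcels(corr: CorrMatrix, n_parcels: int) -> ParcelMap:
    """Initial parcel map from signed loadings of the leading singular vectors.

    Requesting ``n_parcels`` uses ceil(n_parcels/2) vectors, each spawning a
    positive and a negative candidate parcel; empty candidates are dropped.
    The raster shape is inferred only when the matrix labels carry flat
    pixel indices of a known shape — use :func:`parcellate` for the full
    pipeline. Here the assignment raster is 1-D over the matrix order.
    """
    if n_parcels < 2:
        raise ParcellationError("n_parcels must be >= 2")
    labels = _signed_svd_assignment(corr.values, n_parcels)
    flat_idx = corr.labels["unit_id"].to_numpy()
    shape = (1, int(flat_idx.max()) + 1)
    return _labels_to_map(labels, flat_idx, shape)


def iterate_parcels(hemo: HemoStack, initial: ParcelMap, max_iter: int = 100) -> ParcelMap:
    """Iterate pixel reassignment from an initial parcel map to a fixed point."""
    flat_idx = np.flatnonzero(hemo.mask.analysis.ravel())
    init_labels = initial.assignment.ravel()[flat_idx] if (
        initial.assignment.shape == hemo.spatial_shape
    ) else initial.assignment.ravel()[initial.assignment.ravel() > 0]
    if np.any(init_labels <= 0):
        raise ParcellationError("initial assignment must cover every analysis pixel")
    X = hemo.analysis_traces("hbo2").T  # (n_pix, T)
    labels, n_iter, converged = _iterate_assignments(
        X, init_labels.astype(np.int32), max_iter
    )
    traces = _parcel_means(X, labels, int(labels.max()))
    return _labels_to_map(
        labels, flat_idx, hemo.spatial_shape, n_iter, converged, traces
    )


def detect_vein_parcels(
    parcels: ParcelMap,
    midline_band: tuple[int, int],
    manual_ids: Sequence[int] | None = None,
    min_band_fraction: float = 0.5,
) -> np.ndarray:
    """Flag parcels lying on the midline vein; returns their pixel mask.

    A parcel is flagged when its pixel centroid column falls inside
    ``midline_band`` (inclusive) and at least ``min_band_fraction`` of its
    pixels lie in the band — the fraction guard keeps genuinely homotopic
    parcels that straddle the midline (pixels in both hemispheres but away
    from the vein) from being discarded wholesale. ``manual_ids`` takes
    precedence as an explicit override.
    """
    rows, cols = parcels.assignment.shape
    c0, c1 = midline_band
    if c0 <= 0 and c1 >= cols - 1:
        raise ParcellationError("midline band covers the whole image")
    if manual_ids is not None:
        flagged = set(int(i) for i in manual_ids)
        unknown = flagged - set(range(1, parcels.n_parcels + 1))
        if unknown:
            raise ParcellationError(f"manual vein parcel ids not present: {sorted(unknown)}")
    else:
        centroids = parcels.centroids()
        flagged = set()
        for pid, (_, cc) in centroids.items():
            if not (c0 <= cc <= c1):
                continue
            px_cols = parcels.parcel_pixels(pid) % cols
            frac = float(np.mean((px_cols >= c0) & (px_cols <= c1)))
            if frac >= min_band_fraction:
                flagged.add(pid)
    vein = np.isin(parcels.assignment, sorted(flagged))
    return vein


def cluster_parcels(
    parcel_traces: np.ndarray, min_clusters: int = 8, linkage: str = "average"
) -> ClusterAssignment:
    """Hierarchically cluster parcel mean traces and cut at minimal depth."""
    est = TraceHierarchy(min_clusters=min_clusters, linkage=linkage).fit(parcel_traces)
    mapping = {pid: int(c) for pid, c in enumerate(est.labels_, start=1)}
    return ClusterAssignment(
        parcel_to_cluster=mapping,
        linkage_tree=est.linkage_,
        cut_height=est.cut_height_,
        n_clusters=est.n_clusters_,
    )


def split_clusters_by_hemisphere(
    clusters: ClusterAssignment, parcels: ParcelMap, mask: MaskSet
) -> ClusterAssignment:
    """Split every cluster into hemisphere-specific groups, ordered geometrically.

    Each parcel is assigned the hemisphere holding the majority of its
    pixels (exact ties break to left, with a warning). Final ordering is
    deterministic and geometry-derived: left hemisphere first, hemisphere
    clusters by mean anterior-posterior (row) centroid, parcels by centroid
    within each cluster — so permuting input parcel ids cannot change it.
    """
    hemi_flat = mask.hemisphere.ravel()
    centroids = parcels.centroids()
    parcel_side: dict[int, str] = {}
    for pid in range(1, parcels.n_parcels + 1):
        px = parcels.parcel_pixels(pid)
        n_left = int(np.sum(hemi_flat[px] == HEMI_LEFT))
        n_right = int(np.sum(hemi_flat[px] == HEMI_RIGHT))
        if n_left + n_right < len(px):
            raise ParcellationError(f"parcel {pid} has pixels without hemisphere labels")
        if n_left == n_right:
            warnings.warn(f"parcel {pid} splits 50/50; assigning left", stacklevel=2)
        parcel_side[pid] = "left" if n_left >= n_right else "right"

    # group (cluster, hemisphere) -> member parcels
    groups: dict[tuple[int, str], list[int]] = {}
    for pid, cid in clusters.parcel_to_cluster.items():
        groups.setdefault((cid, parcel_side[pid]), []).append(pid)

    def group_key(item: tuple[tuple[int, str], list[int]]):
        (cid, side), pids = item
        mean_row = float(np.mean([centroids[p][0] for p in pids]))
        mean_col = float(np.mean([centroids[p][1] for p in pids]))
        return (0 if side == "left" else 1, mean_row, mean_col)

    split: dict[int, tuple[str, int]] = {}
    ordering: list[int] = []
    for new_id, ((cid, side), pids) in enumerate(
        sorted(groups.items(), key=group_key), start=1
    ):
        for pid in sorted(pids, key=lambda p: centroids[p]):
            split[pid] = (side, new_id)
            ordering.append(pid)
    return ClusterAssignment(
        parcel_to_cluster=dict(clusters.parcel_to_cluster),
        linkage_tree=clusters.linkage_tree,
        cut_height=clusters.cut_height,
        n_clusters=clusters.n_clusters,
        hemisphere_split=split,
        ordering=ordering,
    )


def pixelwise_hemisphere_clusters(
    parcels: ParcelMap, clusters: ClusterAssignment, mask: MaskSet
) -> np.ndarray:
    """Cluster-id raster after dividing the parcellation map by hemisphere.

    Strong homotopic correlation can produce parcels (and clusters) whose
    pixels span both hemispheres; dividing the *map* by hemisphere assigns
    each pixel the combination (its own hemisphere, its parcel's cluster),
    renumbered contiguously. 0 marks unassigned pixels.
    """
    raster = parcels.assignment
    hemi = mask.hemisphere
    out = np.zeros_like(raster)
    combos: dict[tuple[int, int], int] = {}
    assigned = raster > 0
    for r, c in zip(*np.nonzero(assigned)):
        key = (int(hemi[r, c]), clusters.parcel_to_cluster[int(raster[r, c])])
        if key not in combos:
            combos[key] = len(combos) + 1
        out[r, c] = combos[key]
    return out


def parcellate(
    hemo: HemoStack,
    n_parcels: int = 30,
    min_clusters: int = 8,
    max_iter: int = 100,
    midline_band_halfwidth: int = 3,
    linkage: str = "average",
    manual_vein_ids: Sequence[int] | None = None,
) -> tuple[ParcelMap, ClusterAssignment, np.ndarray]:
    """Full two-pass parcellation: parcellate, mask the vein, re-parcellate,
    cluster, and split clusters by hemisphere.

    Returns (final parcel map, hemisphere-split cluster assignment, vein
    pixel mask). The vein pass is skipped when the first pass flags no
    midline parcels.
    """
    flat_idx = np.flatnonzero(hemo.mask.analysis.ravel())
    X = hemo.analysis_traces("hbo2").T
    est = IterativeParcellation(n_parcels=n_parcels, max_iter=max_iter).fit(X)
    first = _labels_to_map(
        est.labels_, flat_idx, hemo.spatial_shape, est.n_iter_, est.converged_,
        est.parcel_traces_,
    )
    cols = hemo.spatial_shape[1]
    mid = (cols - 1) / 2.0
    band = (
        int(np.floor(mid - midline_band_halfwidth)),
        int(np.ceil(mid + midline_band_halfwidth)),
    )
    vein = detect_vein_parcels(first, band, manual_ids=manual_vein_ids)

    if vein.any():
        hemo = hemo.copy_with(
            hemo.hbo2, hemo.hbr, mask=hemo.mask.with_vein(hemo.mask.vein | vein)
        )
        hemo.record("vein_mask", n_pixels=int(vein.sum()))
        flat_idx = np.flatnonzero(hemo.mask.analysis.ravel())
        X = hemo.analysis_traces("hbo2").T
        est = IterativeParcellation(n_parcels=n_parcels, max_iter=max_iter).fit(X)
    final = _labels_to_map(
        est.labels_, flat_idx, hemo.spatial_shape, est.n_iter_, est.converged_,
        est.parcel_traces_,
    )
    clusters = cluster_parcels(est.parcel_traces_, min_clusters, linkage)
    clusters = split_clusters_by_hemisphere(clusters, final, hemo.mask)
    return final, clusters, vein
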