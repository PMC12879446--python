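"""On-disk artifacts: TIFF stacks and masks, HDF5 contrast series, CSV tables.

Containers and formats: raw frames travel as multi-page TIFF with the LED
interleave declared in metadata (never inferred from content); processed
hemoglobin series as HDF5 with named datasets per contrast; correlation
matrices and cluster tables as CSV; statistics reports as JSON. Writers and
readers round-trip integer data bit-exactly and floats at full precision.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping

import h5py
import numpy as np
import pandas as pd
import tifffile

from .connectivity import CorrMatrix
from .exceptions import LayoutError, MaskError
from .masks import MaskSet
from .parcellation import ClusterAssignment, ParcelMap
from .preprocess import HemoStack, RawStack
from .synthetic import GroundTruth

__all__ = [
    "read_raw_stack",
    "write_raw_stack",
    "read_mask",
    "write_mask",
    "read_hemo",
    "write_hemo",
    "read_corr_matrix",
    "write_corr_matrix",
    "write_parcellation",
    "read_parcel_map",
    "write_ground_truth",
    "read_ground_truth",
    "write_json_report",
]


# ---------------------------------------------------------------------------
# raw stacks (multi-page TIFF, frame-interleaved LED channels)


def write_raw_stack(path: str | Path, stack: RawStack) -> None:
    """Write channels frame-interleaved (t0:l0, t0:l1, ..., t1:l0, ...)."""
    n_wl, n_t = stack.frames.shape[:2]
    pages = np.swapaxes(stack.frames, 0, 1).reshape((-1,) + stack.frames.shape[2:])
    desc = json.dumps(
        {
            "wavelengths_nm": list(stack.wavelengths_nm),
            "frame_rate_hz": stack.frame_rate_hz,
            "bit_depth": stack.bit_depth,
            "interleave": "frame",
        }
    )
    tifffile.imwrite(str(path), pages, description=desc)


def read_raw_stack(path: str | Path, layout: Mapping[str, Any] | None = None) -> RawStack:
    """Read an interleaved multi-wavelength stack.

    ``layout`` declares ``wavelengths_nm`` and ``frame_rate_hz``; when
    omitted, the metadata written by :func:`write_raw_stack` is used. The
    page count must divide evenly by the number of wavelengths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        pages = tf.asarray()
        desc = tf.pages[0].description
    meta: dict[str, Any] = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    if layout is not None:
        meta.update(layout)
    if "wavelengths_nm" not in meta or "frame_rate_hz" not in meta:
        raise LayoutError(
            "no channel layout: declare wavelengths_nm and frame_rate_hz "
            "(the interleave order is never inferred)"
        )
    wavelengths = tuple(float(w) for w in meta["wavelengths_nm"])
    n_wl = len(wavelengths)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] % n_wl:
        raise LayoutError(
            f"{pages.shape[0]} frames not divisible by {n_wl} wavelengths"
        )
    frames = pages.reshape(pages.shape[0] // n_wl, n_wl, *pages.shape[1:])
    frames = np.swapaxes(frames, 0, 1).copy()
    return RawStack(
        frames, wavelengths, float(meta["frame_rate_hz"]),
        meta.get("bit_depth"), {"source": str(path)},
    )


# ---------------------------------------------------------------------------
# masks (label image TIFF: 0 background, 1 left, 2 right, 3 vein)


def write_mask(path: str | Path, mask: MaskSet) -> None:
    tifffile.imwrite(str(path), mask.to_label_image())


def read_mask(path: str | Path, expected_shape: tuple[int, int] | None = None) -> MaskSet:
    labels = tifffile.imread(str(path))
    if expected_shape is not None and labels.shape != tuple(expected_shape):
        raise MaskError(
            f"mask shape {labels.shape} does not match expected {tuple(expected_shape)} "
            "(no resize policy is applied)"
        )
    return MaskSet.from_label_image(labels)


# ---------------------------------------------------------------------------
# hemoglobin series (HDF5)


def write_hemo(path: str | Path, hemo: HemoStack) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("hbo2", data=hemo.hbo2, compression="gzip")
        f.create_dataset("hbr", data=hemo.hbr, compression="gzip")
        f.create_dataset("mask/labels", data=hemo.mask.to_label_image())
        f.create_dataset("censored_frames", data=np.asarray(hemo.censored_frames, dtype=np.int64))
        f.create_dataset("frame_index", data=hemo.frame_index)
        f.attrs["frame_rate_hz"] = hemo.frame_rate_hz
        f.attrs["n_frames_original"] = hemo.n_frames_original
        f.attrs["provenance"] = json.dumps(hemo.provenance)


def read_hemo(path: str | Path) -> HemoStack:
    with h5py.File(str(path), "r") as f:
        mask = MaskSet.from_label_image(f["mask/labels"][()])
        return HemoStack(
            f["hbo2"][()],
            f["hbr"][()],
            mask=mask,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            censored_frames=[int(i) for i in f["censored_frames"][()]],
            provenance=json.loads(f.attrs["provenance"]),
            frame_index=f["frame_index"][()],
            n_frames_original=int(f.attrs["n_frames_original"]),
        )


# ---------------------------------------------------------------------------
# correlation matrices (CSV: label columns then one value column per unit)


def write_corr_matrix(path: str | Path, corr: CorrMatrix) -> None:
    df = corr.labels.copy()
    for j, uid in enumerate(corr.labels["unit_id"]):
        df[f"r_{uid}"] = corr.values[:, j]
    df.attrs["level"] = corr.level
    with open(path, "w") as fh:
        fh.write(f"# level={corr.level} ordering={corr.ordering}\n")
        df.to_csv(fh, index=False)


def read_corr_matrix(path: str | Path) -> CorrMatrix:
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh)
    meta = dict(kv.split("=", 1) for kv in header.lstrip("# ").split())
    value_cols = [c for c in df.columns if c.startswith("r_")]
    labels = df[[c for c in df.columns if not c.startswith("r_")]]
    values = df[value_cols].to_numpy()
    return CorrMatrix(values, labels, level=meta.get("level", "region"),
                      ordering=meta.get("ordering", "input"))


# ---------------------------------------------------------------------------
# parcellation products


def write_parcellation(
    out_dir: str | Path,
    parcels: ParcelMap,
    clusters: ClusterAssignment | None = None,
    frame_rate_hz: float | None = None,
) -> None:
    """Assignment raster (TIFF), parcel traces (HDF5), cluster/linkage tables (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(out / "assignment.tif"), parcels.assignment.astype(np.int32))
    with h5py.File(str(out / "parcels.h5"), "w") as f:
        f.create_dataset("assignment", data=parcels.assignment)
        if parcels.parcel_traces is not None:
            f.create_dataset("parcel_traces", data=parcels.parcel_traces)
        f.attrs["n_parcels"] = parcels.n_parcels
        f.attrs["iterations_run"] = parcels.iterations_run
        f.attrs["converged"] = parcels.converged
        if frame_rate_hz is not None:
            f.attrs["frame_rate_hz"] = frame_rate_hz
    if clusters is not None:
        cents = parcels.centroids()
        rows = []
        for pid in range(1, parcels.n_parcels + 1):
            hemi, hid = clusters.hemisphere_split.get(pid, ("", -1))
            rows.append(
                {
                    "parcel_id": pid,
                    "cluster_id": clusters.parcel_to_cluster[pid],
                    "hemisphere": hemi,
                    "hemi_cluster_id": hid,
                    "centroid_row": cents[pid][0],
                    "centroid_col": cents[pid][1],
                }
            )
        pd.DataFrame(rows).to_csv(out / "clusters.csv", index=False)
        pd.DataFrame(
            clusters.linkage_tree, columns=["child_a", "child_b", "height", "size"]
        ).to_csv(out / "linkage.csv", index=False)
        (out / "cut.json").write_text(
            json.dumps(
                {"cut_height": clusters.cut_height, "n_clusters": clusters.n_clusters,
                 "ordering": clusters.ordering}
            )
        )


def read_parcel_map(path: str | Path) -> ParcelMap:
    with h5py.File(str(path), "r") as f:
        return ParcelMap(
            f["assignment"][()],
            int(f.attrs["n_parcels"]),
            int(f.attrs["iterations_run"]),
            bool(f.attrs["converged"]),
            f["parcel_traces"][()] if "parcel_traces" in f else None,
        )


# ---------------------------------------------------------------------------
# ground truth


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    with h5py.File(str(path), "w") as f:
        f.create_dataset("region_map", data=truth.region_map)
        if truth.latent_corr is not None:
            f.create_dataset("latent_corr", data=truth.latent_corr)
        if truth.latent_traces is not None:
            f.create_dataset("latent_traces", data=truth.latent_traces)
        f.create_dataset("vein_mask", data=truth.vein_mask())
        f.attrs["seed"] = truth.seed
        f.attrs["margin"] = truth.margin
        f.attrs["vein_halfwidth"] = truth.vein_halfwidth
        if truth.frame_rate_hz is not None:
            f.attrs["frame_rate_hz"] = truth.frame_rate_hz
        f.attrs["region_labels"] = json.dumps(
            {str(k): list(v) for k, v in truth.region_labels.items()}
        )
        f.attrs["homotopic_pairs"] = json.dumps([list(p) for p in truth.homotopic_pairs])


def read_ground_truth(path: str | Path) -> GroundTruth:
    with h5py.File(str(path), "r") as f:
        labels = {
            int(k): tuple(v) for k, v in json.loads(f.attrs["region_labels"]).items()
        }
        return GroundTruth(
            region_map=f["region_map"][()],
            region_labels=labels,
            homotopic_pairs=[tuple(p) for p in json.loads(f.attrs["homotopic_pairs"])],
            latent_corr=f["latent_corr"][()] if "latent_corr" in f else None,
            latent_traces=f["latent_traces"][()] if "latent_traces" in f else None,
            frame_rate_hz=float(f.attrs["frame_rate_hz"]) if "frame_rate_hz" in f.attrs else None,
            nuisance={"vein_mask": f["vein_mask"][()]},
            seed=int(f.attrs["seed"]),
            margin=int(f.attrs["margin"]),
            vein_halfwidth=int(f.attrs["vein_halfwidth"]),
        )


def write_json_report(path: str | Path, report: dict[str, Any]) -> None:
    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    Path(path).write_text(json.dumps(report, indent=2, default=_default))
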