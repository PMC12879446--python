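"""Brain / hemisphere / vein masks.

Conventions (fixed for the whole package): pixel coordinates are 0-based,
row-major, origin at the top-left; rows run anterior -> posterior and
columns left -> right, so the left hemisphere occupies the lower column
indices. Hemisphere label images use 0 = background, 1 = left, 2 = right.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import MaskError

__all__ = ["MaskSet", "HEMI_LEFT", "HEMI_RIGHT", "HEMI_NONE"]

HEMI_NONE = 0
HEMI_LEFT = 1
HEMI_RIGHT = 2


@dataclass
class MaskSet:
    """Binary brain mask plus per-pixel hemisphere labels and a vein mask.

    Invariants: hemisphere labels are defined exactly where ``brain`` is
    true; left/right are disjoint by construction of the label raster; the
    vein mask is a subset of the brain mask.
    """

    brain: np.ndarray  # bool (rows, cols)
    hemisphere: np.ndarray  # uint8 (rows, cols), HEMI_* codes
    vein: np.ndarray = field(default=None)  # bool (rows, cols)

    def __post_init__(self) -> None:
        self.brain = np.asarray(self.brain, dtype=bool)
        self.hemisphere = np.asarray(self.hemisphere, dtype=np.uint8)
        if self.vein is None:
            self.vein = np.zeros_like(self.brain)
        self.vein = np.asarray(self.vein, dtype=bool)
        if self.hemisphere.shape != self.brain.shape or self.vein.shape != self.brain.shape:
            raise MaskError("brain, hemisphere and vein rasters must share a shape")
        if np.any((self.hemisphere != HEMI_NONE) & ~self.brain):
            raise MaskError("hemisphere labels found outside the brain mask")
        unlabeled = self.brain & (self.hemisphere == HEMI_NONE)
        if np.any(unlabeled):
            raise MaskError(
                f"{int(unlabeled.sum())} brain pixels carry no hemisphere label"
            )
        if np.any(self.vein & ~self.brain):
            raise MaskError("vein mask extends outside the brain mask")
        if not self.brain.any():
            warnings.warn("brain mask is empty", stacklevel=2)

    @property
    def shape(self) -> tuple[int, int]:
        return self.brain.shape

    @property
    def analysis(self) -> np.ndarray:
        """Pixels entering analysis: brain minus vein."""
        return self.brain & ~self.vein

    def hemi_mask(self, side: str) -> np.ndarray:
        code = {"left": HEMI_LEFT, "right": HEMI_RIGHT}[side]
        return self.analysis & (self.hemisphere == code)

    def with_vein(self, vein: np.ndarray) -> "MaskSet":
        return MaskSet(self.brain.copy(), self.hemisphere.copy(), np.asarray(vein, bool))

    @classmethod
    def from_label_image(cls, labels: np.ndarray, vein: np.ndarray | None = None) -> "MaskSet":
        """Build from a 3-valued label image (0 = background, 1 = left, 2 = right).

        A 4th value (3) is accepted as vein-on-brain; pixels labeled vein
        must then also be assigned a hemisphere via the ``vein`` argument or
        are attached to the nearer hemisphere by column.
        """
        labels = np.asarray(labels)
        bad = ~np.isin(labels, (0, 1, 2, 3))
        if np.any(bad):
            raise MaskError(
                f"label image contains values outside {{0,1,2,3}}: "
                f"{sorted(np.unique(labels[bad]).tolist())}"
            )
        vein_px = labels == 3
        brain = labels > 0
        hemisphere = np.where(labels == 3, 0, labels).astype(np.uint8)
        if np.any(vein_px):
            # attach vein pixels to the nearer hemisphere by column
            mid = labels.shape[1] / 2.0
            cols = np.arange(labels.shape[1])[None, :]
            side = np.where(cols + 0.5 <= mid, HEMI_LEFT, HEMI_RIGHT)
            hemisphere = np.where(vein_px, side, hemisphere).astype(np.uint8)
        if vein is not None:
            vein_px = vein_px | np.asarray(vein, bool)
        return cls(brain, hemisphere, vein_px)

    def to_label_image(self) -> np.ndarray:
        """Inverse of :meth:`from_label_image` (vein encoded as 3)."""
        out = self.hemisphere.astype(np.uint8).copy()
        out[self.vein] = 3
        return out
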