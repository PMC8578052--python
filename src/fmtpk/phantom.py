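"""Synthetic voxel-mask phantoms for exercising the IDV computation.

Real organ segmentations come from microCT; these ellipsoid phantoms are
synthetic stand-ins that make the Gaussian-blur spillover computation
testable without imaging data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .mixing import VoxelMaskSet

__all__ = ["Ellipsoid", "MaskPhantomSpec", "make_phantom", "load_masks_nifti"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid: center and semi-axes in voxel units."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    label: str


@dataclass(frozen=True)
class MaskPhantomSpec:
    """Grid plus labeled ellipsoids to rasterize into organ masks."""

    shape: tuple[int, int, int]
    spacing_mm: float
    ellipsoids: tuple[Ellipsoid, ...]

    def __post_init__(self) -> None:
        labels = [e.label for e in self.ellipsoids]
        if len(set(labels)) != len(labels):
            raise ValueError("ellipsoid labels must be unique")
        for e in self.ellipsoids:
            for c, a, n in zip(e.center, e.semi_axes, self.shape):
                if c - a < -0.5 or c + a > n - 0.5:
                    raise ValueError(f"ellipsoid {e.label!r} exceeds the grid")


def make_phantom(spec: MaskPhantomSpec) -> VoxelMaskSet:
    """Rasterize the spec into disjoint binary masks.

    A voxel belongs to an ellipsoid when its center lies inside it; where
    ellipsoids overlap, the first label wins (logged as a warning).
    """
    grids = np.indices(spec.shape, dtype=float)
    masks: dict[str, np.ndarray] = {}
    claimed = np.zeros(spec.shape, dtype=bool)
    for e in spec.ellipsoids:
        d = sum(
            ((grids[k] - e.center[k]) / e.semi_axes[k]) ** 2 for k in range(3)
        )
        m = d <= 1.0
        if not m.any():
            raise ValueError(f"ellipsoid {e.label!r} rasterizes to an empty mask")
        overlap = m & claimed
        if overlap.any():
            log.warning(
                "ellipsoid %r overlaps earlier masks in %d voxels; first label wins",
                e.label,
                int(overlap.sum()),
            )
            m = m & ~claimed
        claimed |= m
        masks[e.label] = m
    return VoxelMaskSet(masks=masks, spacing_mm=spec.spacing_mm)


def load_masks_nifti(paths: dict[str, str], spacing_mm: float) -> VoxelMaskSet:
    """Load per-organ binary masks from NIfTI files (label -> path)."""
    import nibabel as nib  # optional dependency, imported lazily

    masks = {
        label: np.asanyarray(nib.load(p).dataobj) > 0 for label, p in paths.items()
    }
    return VoxelMaskSet(masks=masks, spacing_mm=spacing_mm)
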