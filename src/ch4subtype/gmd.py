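"""Region grey-matter density from probabilistic-mask-weighted voxel maps.

The quantity computed here is the weighted mean of a (modulated, spatially
normalized) grey-matter map over a probabilistic region mask:

    GMD = sum_v gm[v] * w[v] / sum_v w[v]

i.e. the mask weights each voxel's grey-matter value by the probability that
the voxel belongs to the region (for the basal-forebrain Ch4 mask, a
histology-derived probability), and the result is standardized by the total
mask weight so it lives on the same scale as the grey-matter map itself.

Inputs are assumed to be already registered to a common template space on
identical voxel grids; mismatched grids raise rather than resample, because
silent interpolation changes GMD values irreproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "GreyMatterMap",
    "ProbabilisticMask",
    "RegionGMD",
    "TIVEstimate",
    "SpatialIncompatibilityError",
    "DegenerateMaskError",
    "load_map",
    "load_mask",
    "compute_region_gmd",
    "compute_tiv",
]

#: absolute per-element tolerance when comparing affines; accommodates float
#: serialization noise only, never a genuinely different space.
AFFINE_ATOL = 1e-4


class SpatialIncompatibilityError(ValueError):
    """Two volumes are not on the same voxel grid / in the same space."""


class DegenerateMaskError(ValueError):
    """A mask with zero total weight cannot define a weighted mean."""


def _voxel_size_from_affine(affine: np.ndarray) -> tuple[float, float, float]:
    return tuple(float(s) for s in np.sqrt((affine[:3, :3] ** 2).sum(axis=0)))


@dataclass(frozen=True)
class GreyMatterMap:
    """A 3D tissue map (grey-matter fraction or modulated volume per voxel)."""

    voxels: np.ndarray
    affine: np.ndarray
    source: str = "<memory>"

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("grey-matter map contains non-finite voxels")
        if np.any(vox < 0):
            raise ValueError("grey-matter map contains negative voxels")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return _voxel_size_from_affine(self.affine)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))


@dataclass(frozen=True)
class ProbabilisticMask:
    """Nonnegative voxel weights for a region, on the same grid as the maps."""

    weights: np.ndarray
    affine: np.ndarray
    region_name: str = "Ch4"
    source: str = "<memory>"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("mask contains non-finite weights")
        if np.any(w < 0):
            raise ValueError("mask contains negative weights")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return _voxel_size_from_affine(self.affine)


@dataclass(frozen=True)
class RegionGMD:
    """Weighted-mean grey matter over a region mask."""

    value: float
    total_weight: float
    n_voxels_support: int
    region_name: str = "Ch4"
    map_source: str = "<memory>"
    mask_source: str = "<memory>"


@dataclass(frozen=True)
class TIVEstimate:
    """Total intracranial volume in millilitres (tissue-fraction sum)."""

    value: float

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"TIV must be positive, got {self.value}")


def load_map(path: str | Path) -> GreyMatterMap:
    """Read a grey-matter (or any tissue) volume from a NIfTI file."""
    img = nib.load(str(path))
    return GreyMatterMap(
        voxels=np.asarray(img.get_fdata(), dtype=float),
        affine=np.asarray(img.affine, dtype=float),
        source=str(path),
    )


def load_mask(path: str | Path, region_name: str = "Ch4") -> ProbabilisticMask:
    """Read a probabilistic region mask from a NIfTI file."""
    img = nib.load(str(path))
    return ProbabilisticMask(
        weights=np.asarray(img.get_fdata(), dtype=float),
        affine=np.asarray(img.affine, dtype=float),
        region_name=region_name,
        source=str(path),
    )


def _check_same_grid(a_shape, a_aff, a_name, b_shape, b_aff, b_name) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise SpatialIncompatibilityError(
            f"{a_name} has shape {tuple(a_shape)} but {b_name} has shape "
            f"{tuple(b_shape)}; volumes must share one voxel grid"
        )
    if not np.allclose(a_aff, b_aff, atol=AFFINE_ATOL, rtol=0.0):
        raise SpatialIncompatibilityError(
            f"{a_name} and {b_name} have different affines "
            f"(max abs difference {np.max(np.abs(a_aff - b_aff)):.3g} > "
            f"{AFFINE_ATOL:g}); volumes must be in the same space"
        )


def compute_region_gmd(gm_map: GreyMatterMap, mask: ProbabilisticMask) -> RegionGMD:
    """Weighted-mean grey matter of ``gm_map`` under ``mask``.

    value = sum_v gm[v]*w[v] / sum_v w[v].  Raises
    :class:`SpatialIncompatibilityError` on grid mismatch and
    :class:`DegenerateMaskError` if the mask has zero total weight.
    """
    _check_same_grid(
        gm_map.voxels.shape, gm_map.affine, f"grey-matter map ({gm_map.source})",
        mask.weights.shape, mask.affine, f"mask ({mask.source})",
    )
    w = mask.weights
    total_weight = float(w.sum())
    if total_weight <= 0.0:
        raise DegenerateMaskError(
            f"mask '{mask.region_name}' has zero total weight; "
            "a weighted mean is undefined"
        )
    value = float((gm_map.voxels * w).sum() / total_weight)
    return RegionGMD(
        value=value,
        total_weight=total_weight,
        n_voxels_support=int(np.count_nonzero(w)),
        region_name=mask.region_name,
        map_source=gm_map.source,
        mask_source=mask.source,
    )


def compute_tiv(
    gm: GreyMatterMap, wm: GreyMatterMap, csf: GreyMatterMap
) -> TIVEstimate:
    """Total intracranial volume as the voxelwise tissue-fraction sum.

    value = sum_v (gm+wm+csf)[v] * voxel_volume, in mL.  The three maps are
    interpreted as tissue fractions in [0, 1] on one grid.
    """
    _check_same_grid(gm.voxels.shape, gm.affine, "GM map",
                     wm.voxels.shape, wm.affine, "WM map")
    _check_same_grid(gm.voxels.shape, gm.affine, "GM map",
                     csf.voxels.shape, csf.affine, "CSF map")
    for name, m in (("GM", gm), ("WM", wm), ("CSF", csf)):
        if np.any(m.voxels > 1.0 + 1e-9):
            raise ValueError(f"{name} map has values > 1; expected tissue fractions")
    total_mm3 = float((gm.voxels + wm.voxels + csf.voxels).sum()) * gm.voxel_volume_mm3
    if total_mm3 <= 0.0:
        raise ValueError("all-zero tissue maps: TIV is degenerate")
    return TIVEstimate(value=total_mm3 / 1000.0)
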