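"""Template-based selection of the default-mode-network component.

Given a set of component spatial Z-maps (e.g. from a group ICA of
resting-state fMRI), the DMN component is identified by a spherical
template: voxels with |Z| > 1.5 count as active, each template region
is a 5 mm-radius sphere around a published DMN coordinate, and each
component is scored as mean(Z inside the spheres) − mean(Z outside).
The highest-scoring component is designated the DMN, and the peak
active voxel of each of the 8 core ROIs is extracted within a search
sphere around its expected coordinate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

#: Active-voxel threshold on |Z|, strict inequality.
ACTIVE_Z_THRESHOLD = 1.5
#: Default template sphere radius (mm); varying it little affects selection.
DEFAULT_RADIUS_MM = 5.0


@dataclass
class SpatialMap:
    """A volumetric Z-map with its voxel-to-world (mm) affine."""

    data: np.ndarray
    affine: np.ndarray
    index: int | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"map must be 3-D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4 × 4")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("map contains non-finite values")

    @classmethod
    def from_nifti(cls, path: str | Path, index: int | None = None):
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=float),
                   np.asarray(img.affine), index=index)

    def to_nifti(self, path: str | Path) -> Path:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine),
                 str(path))
        return Path(path)


@dataclass(frozen=True)
class SphericalTemplate:
    """A set of spheres (center in world mm, radius mm)."""

    regions: tuple[tuple[tuple[float, float, float], float], ...]

    def __post_init__(self):
        if not self.regions:
            raise ValueError("template has no regions")
        for center, radius in self.regions:
            if radius <= 0:
                raise ValueError(f"sphere at {center} has radius {radius} <= 0")

    @classmethod
    def from_roi_table(cls, roi_table: pd.DataFrame,
                       radius_mm: float = DEFAULT_RADIUS_MM):
        """Build a template from an ROI table with x/y/z columns (mm)."""
        regions = tuple(
            ((float(r.x), float(r.y), float(r.z)), float(radius_mm))
            for r in roi_table.itertuples()
        )
        return cls(regions)


def world_coordinates(shape, affine) -> np.ndarray:
    """World (mm) coordinates of every voxel center; shape (*grid, 3)."""
    idx = np.indices(shape).reshape(3, -1)
    homo = np.vstack([idx, np.ones(idx.shape[1])])
    world = (np.asarray(affine) @ homo)[:3]
    return world.T.reshape(*shape, 3)


def sphere_mask(shape, affine, centers, radii) -> np.ndarray:
    """Boolean voxel mask of the union of spheres given in world mm."""
    coords = world_coordinates(shape, affine)
    mask = np.zeros(shape, dtype=bool)
    for center, radius in zip(centers, radii):
        d2 = ((coords - np.asarray(center, float)) ** 2).sum(axis=-1)
        mask |= d2 <= float(radius) ** 2
    return mask


def template_mask(map_: SpatialMap, template: SphericalTemplate) -> np.ndarray:
    centers = [c for c, _ in template.regions]
    radii = [r for _, r in template.regions]
    return sphere_mask(map_.data.shape, map_.affine, centers, radii)


def active_voxel_mask(map_: SpatialMap,
                      z_threshold: float = ACTIVE_Z_THRESHOLD) -> np.ndarray:
    """Voxels with |Z| strictly greater than the threshold."""
    return np.abs(map_.data) > z_threshold


def template_fit_score(map_: SpatialMap, template: SphericalTemplate) -> float:
    """Goodness of fit: mean Z inside the template spheres minus outside.

    Adding a constant to the whole map leaves the score unchanged (both
    means shift equally). A template covering zero or all voxels is
    degenerate and rejected.
    """
    mask = template_mask(map_, template)
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        raise ValueError(
            f"degenerate template: covers {n_in} of {mask.size} voxels")
    return float(map_.data[mask].mean() - map_.data[~mask].mean())


def select_best_component(maps: list[SpatialMap],
                          template: SphericalTemplate) -> int:
    """Index of the component with the greatest template-fit score.

    Ties break deterministically toward the lowest index, with a warning.
    """
    if not maps:
        raise ValueError("no component maps given")
    scores = np.array([template_fit_score(m, template) for m in maps])
    best = int(np.argmax(scores))
    if np.sum(scores == scores[best]) > 1:
        warnings.warn(
            f"template-fit tie at score {scores[best]:.6g}; "
            f"keeping lowest index {best}",
            RuntimeWarning, stacklevel=2,
        )
    return best


def extract_roi_peaks(
    map_: SpatialMap,
    roi_table: pd.DataFrame,
    search_radius_mm: float = 10.0,
    z_threshold: float = ACTIVE_Z_THRESHOLD,
) -> pd.DataFrame:
    """Peak active voxel of each ROI within its search sphere.

    The peak is the active voxel (|Z| > threshold) with the largest |Z|
    inside a sphere of ``search_radius_mm`` around the ROI's tabulated
    coordinate; ties break toward the smallest lexicographic world
    coordinate. ROIs whose sphere contains no active voxel are dropped
    with a warning. Returns a table with name, hemisphere, x, y, z,
    peak Z and the number of active voxels searched.
    """
    active = active_voxel_mask(map_, z_threshold)
    coords = world_coordinates(map_.data.shape, map_.affine)
    rows = []
    for r in roi_table.itertuples():
        center = np.array([r.x, r.y, r.z], dtype=float)
        d2 = ((coords - center) ** 2).sum(axis=-1)
        in_sphere = (d2 <= search_radius_mm ** 2) & active
        n_active = int(in_sphere.sum())
        if n_active == 0:
            warnings.warn(
                f"ROI {r.name}/{r.hemisphere}: no active voxel within "
                f"{search_radius_mm} mm of {tuple(center)}; dropped",
                RuntimeWarning, stacklevel=2,
            )
            continue
        vals = np.abs(map_.data[in_sphere])
        peak_val = vals.max()
        cand = np.argwhere(in_sphere & (np.abs(map_.data) == peak_val))
        cand_world = [tuple(coords[tuple(c)]) for c in cand]
        order = np.lexsort(np.array(cand_world).T[::-1])
        vi = tuple(cand[order[0]])
        x, y, z = coords[vi]
        rows.append({
            "name": r.name, "hemisphere": r.hemisphere,
            "x": float(x), "y": float(y), "z": float(z),
            "peak_z": float(map_.data[vi]), "n_active_voxels": n_active,
        })
    return pd.DataFrame(rows,
                        columns=["name", "hemisphere", "x", "y", "z",
                                 "peak_z", "n_active_voxels"])
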