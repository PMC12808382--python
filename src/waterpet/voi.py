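"""Volume-of-interest construction by the protocol's geometric rules.

Two muscle VOI types are built:

* a *contour* VOI: the posterior-compartment muscle in ten consecutive
  axial slices around the 60% lower-leg level, minus a 20-mm exclusion
  zone around the tibia and fibula (a safety margin against patient
  motion);
* a *dual-sphere* VOI: two 7.5-mm-radius spheres placed medially and
  laterally in the muscle at the same level, combined.

All distances are Euclidean in world millimetres, honouring anisotropic
voxels; a voxel belongs to a region iff its *center* does (no
partial-volume fractions, consistent with the no-PVC analysis).
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "VOIMask",
    "SphereSpec",
    "lower_leg_level",
    "bone_exclusion_zone",
    "muscle_contour_voi",
    "sphere_voi",
]


@dataclass(frozen=True)
class VOIMask:
    """Boolean 3D mask on the image grid with its provenance."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    provenance: str = "contour"

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise ValueError("VOI mask must be 3D")
        object.__setattr__(self, "mask", m)
        if self.provenance not in ("contour", "spheres", "idif", "label", "search"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mL(self) -> float:
        return self.n_voxels * float(np.prod(self.voxel_size_mm)) / 1000.0

    def save(self, path) -> None:
        aff = np.eye(4)
        aff[0, 0], aff[1, 1], aff[2, 2] = self.voxel_size_mm
        nib.save(nib.Nifti1Image(self.mask.astype(np.uint8), aff), str(path))

    @classmethod
    def load(cls, path, provenance: str = "label") -> "VOIMask":
        img = nib.load(str(path))
        return cls(
            mask=np.asarray(img.dataobj) > 0,
            voxel_size_mm=tuple(float(z) for z in img.header.get_zooms()[:3]),
            provenance=provenance,
        )


@dataclass(frozen=True)
class SphereSpec:
    """Sphere in world coordinates; default radius 7.5 mm."""

    center_mm: tuple[float, float, float]
    radius_mm: float = 7.5

    def __post_init__(self) -> None:
        if not (self.radius_mm > 0):
            raise ValueError("sphere radius must be positive")

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * np.pi * self.radius_mm**3


def lower_leg_level(malleolus_z_mm: float, knee_z_mm: float, fraction: float = 0.6) -> float:
    """Axial level at ``fraction`` of the lower-leg length.

    Measured from the distal end of the medial malleolus toward the knee
    joint space; the default 60% level is where single-slice calf-muscle
    measurements are most representative of muscle volume.
    """
    if not (malleolus_z_mm < knee_z_mm):
        raise ValueError("malleolus must lie below the knee (inverted landmarks)")
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must lie in [0, 1]")
    return malleolus_z_mm + fraction * (knee_z_mm - malleolus_z_mm)


def bone_exclusion_zone(bone_mask: VOIMask, margin_mm: float = 20.0) -> VOIMask:
    """Voxels within ``margin_mm`` (world mm) of any bone voxel, bone included.

    Distances are measured center-to-center with anisotropic voxel sizes.
    """
    if margin_mm < 0:
        raise ValueError("margin must be non-negative")
    bone = bone_mask.mask
    if margin_mm == 0 or not bone.any():
        zone = bone.copy()
    else:
        dist = ndimage.distance_transform_edt(~bone, sampling=bone_mask.voxel_size_mm)
        zone = dist <= margin_mm
    return VOIMask(mask=zone, voxel_size_mm=bone_mask.voxel_size_mm, provenance="label")


def _level_slice_index(level_z_mm: float, dz: float) -> int:
    # slice k is centered at z = k*dz and spans [k*dz - dz/2, k*dz + dz/2)
    return int(round(level_z_mm / dz))


def muscle_contour_voi(
    labels: np.ndarray,
    voxel_size_mm,
    level_z_mm: float,
    bone_zone: VOIMask,
    muscle_label: int = 3,
    n_slices: int = 10,
) -> VOIMask:
    """Contour VOI: muscle-compartment voxels in ``n_slices`` consecutive
    axial slices around the given level, minus the bone exclusion zone.

    The slice stack runs from ``level - ceil(n/2) + 1`` through
    ``level + floor(n/2)`` (for ten 1.5-mm slices: four below through five
    above the level slice), a deterministic convention since an even count
    cannot be symmetric about one slice.
    """
    labels = np.asarray(labels)
    dz = voxel_size_mm[2]
    level = _level_slice_index(level_z_mm, dz)
    nz = labels.shape[2]
    lo = level - (-(-n_slices // 2)) + 1  # level - ceil(n/2) + 1
    hi = level + n_slices // 2  # inclusive
    if lo < 0 or hi >= nz:
        raise ValueError(
            f"slice stack [{lo}, {hi}] does not fit in the volume (nz = {nz})"
        )
    mask = np.zeros_like(labels, dtype=bool)
    mask[:, :, lo : hi + 1] = labels[:, :, lo : hi + 1] == muscle_label
    mask &= ~bone_zone.mask
    if not mask.any():
        raise ValueError("contour VOI is empty after bone-zone exclusion")
    return VOIMask(mask=mask, voxel_size_mm=tuple(voxel_size_mm), provenance="contour")


def sphere_voi(spheres, grid_shape, voxel_size_mm) -> VOIMask:
    """Union of spheres, voxelized by voxel-center inclusion.

    Overlapping spheres are unioned (no double counting). Raises if any
    sphere contains no voxel center (entirely outside the grid or smaller
    than the voxel pitch everywhere off-center).
    """
    nx, ny, nz = grid_shape
    dx, dy, dz = voxel_size_mm
    x = np.arange(nx) * dx
    y = np.arange(ny) * dy
    z = np.arange(nz) * dz
    mask = np.zeros(grid_shape, dtype=bool)
    for sph in spheres:
        cx, cy, cz = sph.center_mm
        if not (
            x[0] - sph.radius_mm <= cx <= x[-1] + sph.radius_mm
            and y[0] - sph.radius_mm <= cy <= y[-1] + sph.radius_mm
            and z[0] - sph.radius_mm <= cz <= z[-1] + sph.radius_mm
        ):
            raise ValueError(f"sphere at {sph.center_mm} lies entirely outside the grid")
        d2 = (
            (x - cx)[:, None, None] ** 2
            + (y - cy)[None, :, None] ** 2
            + (z - cz)[None, None, :] ** 2
        )
        inside = d2 <= sph.radius_mm**2
        if not inside.any():
            raise ValueError(f"sphere at {sph.center_mm} contains no voxel center")
        mask |= inside
    if not mask.any():
        raise ValueError("sphere VOI is empty")
    return VOIMask(mask=mask, voxel_size_mm=tuple(voxel_size_mm), provenance="spheres")
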