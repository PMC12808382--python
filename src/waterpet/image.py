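"""4D dynamic-image container and NIfTI I/O.

Axis convention: arrays are indexed ``(x, y, z, frame)`` with z the axial
direction increasing foot -> abdomen. World coordinates are in mm with the
center of voxel (0, 0, 0) at the origin, so the center of axial slice k
lies at z = k * dz.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .framing import FramingScheme, O15_HALF_LIFE_S

__all__ = ["DynamicImage", "save_labels", "load_labels"]


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class DynamicImage:
    """4D activity-concentration volume (kBq/mL) plus its framing scheme."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    framing: FramingScheme
    decay_corrected: bool = True
    half_life_s: float = O15_HALF_LIFE_S
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("dynamic image data must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.framing.n_frames:
            raise ValueError(
                f"image has {self.data.shape[3]} frames but framing defines "
                f"{self.framing.n_frames}"
            )

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_volume_mL(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0

    def save(self, image_path: str | Path, sidecar_path: str | Path | None = None) -> None:
        """Write the 4D NIfTI and its JSON framing sidecar."""
        image_path = Path(image_path)
        img = nib.Nifti1Image(self.data.astype(np.float32), _affine(self.voxel_size_mm))
        img.header.set_zooms((*self.voxel_size_mm, 1.0))
        nib.save(img, str(image_path))
        if sidecar_path is None:
            name = image_path.name
            for suffix in (".nii.gz", ".nii"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
                    break
            sidecar_path = image_path.with_name(name + ".json")
        self.framing.to_sidecar(
            sidecar_path, decay_corrected=self.decay_corrected, half_life_s=self.half_life_s
        )

    @classmethod
    def load(cls, image_path: str | Path, sidecar_path: str | Path | None = None) -> "DynamicImage":
        image_path = Path(image_path)
        img = nib.load(str(image_path))
        if sidecar_path is None:
            name = image_path.name
            for suffix in (".nii.gz", ".nii"):
                if name.endswith(suffix):
                    name = name[: -len(suffix)]
                    break
            sidecar_path = image_path.with_name(name + ".json")
        framing = FramingScheme.from_sidecar(sidecar_path)
        import json

        payload = json.loads(Path(sidecar_path).read_text())
        zooms = img.header.get_zooms()[:3]
        return cls(
            data=np.asarray(img.dataobj),
            voxel_size_mm=tuple(float(z) for z in zooms),
            framing=framing,
            decay_corrected=bool(payload.get("decay_corrected", True)),
            half_life_s=float(payload.get("half_life_s", O15_HALF_LIFE_S)),
        )


def save_labels(labels: np.ndarray, voxel_size_mm, path: str | Path) -> None:
    """Write a 3D integer label volume as NIfTI (uint8)."""
    img = nib.Nifti1Image(labels.astype(np.uint8), _affine(voxel_size_mm))
    img.header.set_zooms(tuple(voxel_size_mm))
    nib.save(img, str(path))


def load_labels(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(np.int64), tuple(
        float(z) for z in img.header.get_zooms()[:3]
    )
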