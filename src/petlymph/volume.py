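"""3-D PET volume container with voxel geometry and NIfTI round-trip.

A :class:`PetVolume` holds either an activity-concentration grid (kBq/mL)
or an already-normalized SUV grid, together with the affine mapping voxel
indices to physical millimetres.  NIfTI-1 is the on-disk format; acquisition
metadata travels in a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["PetVolume"]


@dataclass
class PetVolume:
    """A 3-D scalar grid in physical space.

    Parameters
    ----------
    data
        Voxel values, shape ``(nx, ny, nz)``.  Units are whatever the
        producer put in (kBq/mL for raw activity, dimensionless for SUV);
        the ``units`` field records which.
    affine
        4x4 voxel-index -> mm affine.  For axis-aligned grids this is
        ``diag(spacing) @ translation``.
    units
        Free-text unit tag, e.g. ``"kBq/mL"`` or ``"SUV"``.
    meta
        Arbitrary JSON-serializable metadata (acquisition, ground truth...).
    """

    data: np.ndarray
    affine: np.ndarray
    units: str = "SUV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D grid, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @classmethod
    def from_spacing(
        cls,
        data: np.ndarray,
        spacing_mm,
        origin_mm=(0.0, 0.0, 0.0),
        **kw,
    ) -> "PetVolume":
        """Build an axis-aligned volume from per-axis spacing and origin."""
        spacing = np.asarray(spacing_mm, dtype=float)
        if spacing.shape != (3,) or np.any(spacing <= 0):
            raise ValueError("spacing_mm must be 3 positive values")
        affine = np.eye(4)
        affine[:3, :3] = np.diag(spacing)
        affine[:3, 3] = np.asarray(origin_mm, dtype=float)
        return cls(data=data, affine=affine, **kw)

    @property
    def spacing_mm(self) -> np.ndarray:
        """Per-axis voxel spacing in mm (norms of the affine columns)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def voxels_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map (n, 3) voxel indices to (n, 3) physical mm coordinates."""
        ijk = np.atleast_2d(np.asarray(ijk, dtype=float))
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    # ------------------------------------------------------------------ io
    def to_nifti(self, path: str | Path, sidecar: bool = True) -> Path:
        """Write the grid as NIfTI-1; metadata goes to ``<stem>.json``."""
        path = Path(path)
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_xyzt_units("mm")
        nib.save(img, path)
        if sidecar:
            side = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
            side.write_text(json.dumps({"units": self.units, **self.meta}, indent=1, default=float))
        return path

    @classmethod
    def from_nifti(cls, path: str | Path) -> "PetVolume":
        path = Path(path)
        img = nib.load(path)
        side = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
        meta: dict = {}
        units = "SUV"
        if side.exists():
            meta = json.loads(side.read_text())
            units = meta.pop("units", "SUV")
        return cls(
            data=np.asarray(img.dataobj, dtype=float),
            affine=np.asarray(img.affine, dtype=float),
            units=units,
            meta=meta,
        )
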