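"""Synthetic PET phantoms with exact lesion ground truth.

A phantom is a uniform-background SUV grid carrying non-overlapping
ellipsoidal lesions of uniform interior uptake, optionally with additive
Gaussian noise (truncated at zero).  Because lesions are analytic
ellipsoids, the ground truth — volume 4/3*pi*r1*r2*r3 and the exact
center — is stored alongside the rasterized volume, giving segmentation
code an oracle that does not depend on the rasterization itself.

Not modelled, deliberately: scanner physics (scatter, partial-volume
blur, reconstruction artefacts) and physiological background structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volume import PetVolume

__all__ = ["PhantomLesion", "PhantomSpec", "GroundTruthLesion", "generate_phantom", "write_phantom"]


@dataclass(frozen=True)
class PhantomLesion:
    """One ellipsoidal lesion: center (mm), per-axis radii (mm), peak SUV."""

    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float


@dataclass
class PhantomSpec:
    """Recipe for a synthetic PET volume.

    Defaults emulate a multi-lesion lymphoma presentation: whole-body-ish
    grid at 4 mm isotropic voxels, blood-pool-like background SUV 0.8,
    lesion peaks well above it.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 200)
    voxel_spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    background_suv: float = 0.8
    noise_sd: float = 0.0
    lesions: list[PhantomLesion] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if any(v <= 0 for v in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be positive")
        if self.background_suv < 0 or self.noise_sd < 0:
            raise ValueError("background_suv and noise_sd must be nonnegative")
        extent = np.array(self.grid_shape) * np.array(self.voxel_spacing_mm)
        for i, les in enumerate(self.lesions):
            c, r = np.asarray(les.center_mm, float), np.asarray(les.radii_mm, float)
            if np.any(r <= 0):
                raise ValueError(f"lesion {i}: radii must be positive")
            if les.peak_suv <= self.background_suv:
                raise ValueError(f"lesion {i}: peak_suv must exceed background_suv")
            if np.any(c - r < 0) or np.any(c + r > extent):
                raise ValueError(f"lesion {i}: ellipsoid extends outside the grid")
        # non-overlap via enclosing spheres: conservative, keeps ground truth
        # unambiguous (a rejected pair may in fact be disjoint ellipsoids)
        for i in range(len(self.lesions)):
            for j in range(i + 1, len(self.lesions)):
                ci = np.asarray(self.lesions[i].center_mm, float)
                cj = np.asarray(self.lesions[j].center_mm, float)
                if np.linalg.norm(ci - cj) <= max(self.lesions[i].radii_mm) + max(self.lesions[j].radii_mm):
                    raise ValueError(f"lesions {i} and {j} overlap (enclosing-sphere test)")


@dataclass(frozen=True)
class GroundTruthLesion:
    center_mm: tuple[float, float, float]
    radii_mm: tuple[float, float, float]
    peak_suv: float
    volume_mm3: float  # analytic 4/3*pi*r1*r2*r3, not rasterized


def generate_phantom(spec: PhantomSpec) -> tuple[PetVolume, list[GroundTruthLesion]]:
    """Rasterize a phantom and return it with its analytic ground truth.

    Voxels whose *centers* fall inside an ellipsoid get that lesion's peak
    SUV; everything else is background.  Gaussian noise of SD ``noise_sd``
    is added afterwards and the result clipped at zero.  Deterministic for
    a fixed ``spec.seed``.
    """
    spec.validate()
    shape = tuple(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing_mm, float)
    data = np.full(shape, spec.background_suv, dtype=float)

    truth: list[GroundTruthLesion] = []
    for les in spec.lesions:
        c = np.asarray(les.center_mm, float)
        r = np.asarray(les.radii_mm, float)
        lo = np.maximum(np.floor((c - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing).astype(int) + 1, shape)
        ax = [ (np.arange(lo[k], hi[k]) + 0.5) * spacing[k] for k in range(3) ]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        inside = (
            ((gx - c[0]) / r[0]) ** 2 + ((gy - c[1]) / r[1]) ** 2 + ((gz - c[2]) / r[2]) ** 2
        ) <= 1.0
        sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = les.peak_suv
        truth.append(
            GroundTruthLesion(
                center_mm=tuple(c),
                radii_mm=tuple(r),
                peak_suv=les.peak_suv,
                volume_mm3=float(4.0 / 3.0 * np.pi * np.prod(r)),
            )
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, size=shape), 0.0, None)

    # voxel-center world coordinates: index i maps to (i + 0.5) * spacing
    vol = PetVolume.from_spacing(
        data,
        spacing_mm=spacing,
        origin_mm=spacing / 2.0,
        units="SUV",
        meta={"seed": spec.seed, "background_suv": spec.background_suv, "noise_sd": spec.noise_sd},
    )
    return vol, truth


def write_phantom(
    vol: PetVolume, truth: list[GroundTruthLesion], path: str | Path
) -> Path:
    """Write the phantom as NIfTI with the ground truth in the JSON sidecar."""
    vol = PetVolume(
        data=vol.data,
        affine=vol.affine,
        units=vol.units,
        meta={
            **vol.meta,
            "ground_truth_lesions": [
                {
                    "center_mm": list(t.center_mm),
                    "radii_mm": list(t.radii_mm),
                    "peak_suv": t.peak_suv,
                    "volume_mm3": t.volume_mm3,
                }
                for t in truth
            ],
        },
    )
    return vol.to_nifti(path)


def read_ground_truth(path: str | Path) -> list[GroundTruthLesion]:
    """Load ground-truth lesions back from a phantom sidecar."""
    path = Path(path)
    side = path.with_name(path.name.removesuffix(".gz").removesuffix(".nii") + ".json")
    meta = json.loads(side.read_text())
    return [
        GroundTruthLesion(
            center_mm=tuple(d["center_mm"]),
            radii_mm=tuple(d["radii_mm"]),
            peak_suv=d["peak_suv"],
            volume_mm3=d["volume_mm3"],
        )
        for d in meta.get("ground_truth_lesions", [])
    ]
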