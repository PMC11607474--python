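"""Hypermetabolic lesion detection, 41%-SUVmax segmentation and burden features.

The workflow mirrors routine volumetric PET reading in lymphoma:

1. seed detection — connected components of voxels above a fixed SUV seed
   threshold (default 2.5), which stand in for the reader's click on each
   focus of uptake;
2. per-lesion segmentation — each seed grows an isocontour at 41% of its own
   SUVmax (the EANM-recommended relative threshold), restricted to the
   connected piece containing the seed's hottest voxel;
3. burden features — metabolic tumor volume (MTV, cm^3), total lesion
   glycolysis (TLG = sum of MTV_i * SUVmean_i), and per-patient SUVmax under
   each normalization;
4. organ rules — spleen involvement when uptake is focal or diffusely above
   1.5x the liver background; bone-marrow involvement when focal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .suv import SuvMaps
from .volume import PetVolume

__all__ = [
    "Lesion",
    "LesionSet",
    "ReferenceRegions",
    "QuantResult",
    "detect_candidates",
    "segment_41pct",
    "segment_lesions",
    "quantify_patient",
    "organ_involvement",
]

ISOCONTOUR_FRACTION = 0.41


def _structure(connectivity: int) -> np.ndarray:
    rank = {6: 1, 18: 2, 26: 3}
    if connectivity not in rank:
        raise ValueError(f"connectivity must be one of 6, 18, 26, got {connectivity}")
    return ndimage.generate_binary_structure(3, rank[connectivity])


@dataclass
class Lesion:
    """One segmented lesion with its SUV statistics and geometry."""

    voxel_indices: np.ndarray  # (n, 3) int
    suv_max: float
    suv_mean: float
    volume_cm3: float
    centroid_mm: np.ndarray  # (3,) intensity-weighted physical coordinates

    def __post_init__(self) -> None:
        if len(self.voxel_indices) == 0:
            raise ValueError("lesion voxel set must be nonempty")
        if self.suv_mean > self.suv_max + 1e-12:
            raise ValueError("suv_mean cannot exceed suv_max")


@dataclass
class LesionSet:
    """All lesions of one patient plus the additive burden totals."""

    lesions: list[Lesion] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.lesions)

    def __iter__(self):
        return iter(self.lesions)

    @property
    def total_mtv_cm3(self) -> float:
        return float(sum(l.volume_cm3 for l in self.lesions))

    @property
    def total_tlg(self) -> float:
        return float(sum(l.volume_cm3 * l.suv_mean for l in self.lesions))

    @property
    def centroids_mm(self) -> np.ndarray:
        if not self.lesions:
            return np.empty((0, 3))
        return np.vstack([l.centroid_mm for l in self.lesions])


@dataclass(frozen=True)
class ReferenceRegions:
    """Mean SUV of physiological reference regions and focal-uptake flags."""

    liver_suv_mean: float
    mediastinum_suv_mean: float | None = None
    spleen_suv_mean: float | None = None
    spleen_focal_flag: bool = False
    marrow_focal_flag: bool = False


@dataclass
class QuantResult:
    """Per-patient PET feature vector."""

    suv_bw_max: float
    suv_lbm_max: float
    suv_bsa_max: float
    mtv_cm3: float
    tlg: float
    n_lesions: int


def detect_candidates(
    suv_volume: PetVolume,
    seed_threshold_suv: float = 2.5,
    connectivity: int = 26,
    min_voxels: int = 2,
) -> list[np.ndarray]:
    """Connected components of voxels at or above the seed threshold.

    Returns per-component ``(n, 3)`` voxel-index arrays, ordered by
    descending component SUVmax (ties by discovery order), components with
    fewer than ``min_voxels`` voxels discarded.  Deterministic.
    """
    data = suv_volume.data
    if np.any(data < 0):
        raise ValueError("SUV volume must be nonnegative")
    mask = data >= seed_threshold_suv
    labels, n = ndimage.label(mask, structure=_structure(connectivity))
    comps: list[np.ndarray] = []
    maxima: list[float] = []
    for sl_idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        sub = labels[sl] == sl_idx
        if int(sub.sum()) < min_voxels:
            continue
        ijk = np.argwhere(sub) + np.array([s.start for s in sl])
        comps.append(ijk)
        maxima.append(float(data[tuple(ijk.T)].max()))
    order = np.argsort(-np.asarray(maxima), kind="stable") if comps else []
    return [comps[i] for i in order]


def segment_41pct(
    component: np.ndarray,
    suv_volume: PetVolume,
    fraction: float = ISOCONTOUR_FRACTION,
    connectivity: int = 26,
    margin_voxels: int = 10,
) -> Lesion:
    """Grow a lesion from a seed component at ``fraction`` of its SUVmax.

    The isocontour threshold is ``fraction * max(SUV over the component)``.
    Because the relative threshold is usually below the seed threshold, the
    lesion may extend beyond the seed: the component's bounding box is
    dilated by ``margin_voxels`` per axis, voxels at or above the threshold
    within that region are taken, and the connected piece containing the
    component's hottest voxel is kept.  A single-voxel component degrades
    gracefully to a one-voxel lesion.
    """
    component = np.atleast_2d(np.asarray(component, dtype=int))
    if component.size == 0:
        raise ValueError("component must be nonempty")
    data = suv_volume.data
    comp_vals = data[tuple(component.T)]
    suv_max = float(comp_vals.max())
    peak_ijk = component[int(np.argmax(comp_vals))]
    threshold = fraction * suv_max

    lo = np.maximum(component.min(axis=0) - margin_voxels, 0)
    hi = np.minimum(component.max(axis=0) + margin_voxels + 1, data.shape)
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = data[box]
    mask = sub >= threshold
    labels, _ = ndimage.label(mask, structure=_structure(connectivity))
    peak_local = tuple(peak_ijk - lo)
    lesion_label = labels[peak_local]
    if lesion_label == 0:  # cannot happen: peak >= threshold by construction
        raise RuntimeError("peak voxel fell below its own isocontour")
    ijk_local = np.argwhere(labels == lesion_label)
    ijk = ijk_local + lo

    vals = data[tuple(ijk.T)]
    weights = vals / vals.sum() if vals.sum() > 0 else np.full(len(vals), 1.0 / len(vals))
    centroid_vox = weights @ ijk
    centroid_mm = suv_volume.voxels_to_mm(centroid_vox)[0]
    return Lesion(
        voxel_indices=ijk,
        suv_max=float(vals.max()),
        suv_mean=float(vals.mean()),
        volume_cm3=len(ijk) * suv_volume.voxel_volume_mm3 / 1000.0,
        centroid_mm=centroid_mm,
    )


def segment_lesions(
    suv_volume: PetVolume,
    seed_threshold_suv: float = 2.5,
    connectivity: int = 26,
    min_voxels: int = 2,
    fraction: float = ISOCONTOUR_FRACTION,
) -> LesionSet:
    """Detect seeds and segment each at the relative isocontour.

    Seeds whose grown lesions coincide (same hottest voxel after growth)
    are merged into one lesion, so touching foci are not double counted.
    """
    comps = detect_candidates(suv_volume, seed_threshold_suv, connectivity, min_voxels)
    lesions: list[Lesion] = []
    seen: set[bytes] = set()
    for comp in comps:
        lesion = segment_41pct(comp, suv_volume, fraction, connectivity)
        key = lesion.voxel_indices[np.lexsort(lesion.voxel_indices.T[::-1])][0].tobytes()
        sig = (len(lesion.voxel_indices), key)
        sig_b = repr(sig).encode()
        if sig_b in seen:
            continue
        seen.add(sig_b)
        lesions.append(lesion)
    return LesionSet(lesions=lesions)


def quantify_patient(suv_maps: SuvMaps, lesions: LesionSet) -> QuantResult:
    """Per-patient burden features from SUVbw-segmented lesions.

    SUVmax under each normalization is the maximum over lesion voxels in
    the corresponding map; MTV and TLG are additive over lesions with
    SUVmean in body-weight units (the prevailing TLG convention).
    """
    if len(lesions) == 0:
        raise ValueError("empty lesion set: patient has no quantifiable disease")
    all_ijk = np.vstack([l.voxel_indices for l in lesions])
    idx = tuple(all_ijk.T)
    return QuantResult(
        suv_bw_max=float(suv_maps.suv_bw.data[idx].max()),
        suv_lbm_max=float(suv_maps.suv_lbm.data[idx].max()),
        suv_bsa_max=float(suv_maps.suv_bsa.data[idx].max()),
        mtv_cm3=lesions.total_mtv_cm3,
        tlg=lesions.total_tlg,
        n_lesions=len(lesions),
    )


def organ_involvement(refs: ReferenceRegions, spleen_liver_ratio: float = 1.5) -> dict:
    """Spleen and bone-marrow involvement flags.

    Spleen is involved when uptake is focal or when its diffuse mean exceeds
    ``spleen_liver_ratio`` times the liver background; marrow only when
    focal (diffuse marrow uptake is too nonspecific on FDG-PET).
    """
    if refs.liver_suv_mean is None or refs.liver_suv_mean <= 0:
        raise ValueError("liver reference mean is required and must be positive")
    diffuse = (
        refs.spleen_suv_mean is not None
        and refs.spleen_suv_mean > spleen_liver_ratio * refs.liver_suv_mean
    )
    return {
        "spleen_involved": bool(refs.spleen_focal_flag or diffuse),
        "marrow_involved": bool(refs.marrow_focal_flag),
    }
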