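"""Standardized uptake value (SUV) normalizations.

Converts an activity-concentration volume (kBq/mL) into SUV under three
normalizers of the injected dose:

* body weight (SUVbw)     -- dose per gram of body weight,
* lean body mass (SUVlbm) -- dose per gram of lean mass (James equations),
* body surface area (SUVbsa) -- dose per m^2 of Du Bois surface area.

SUVbw and SUVlbm are the usual dimensionless g/mL quantities.  SUVbsa has
no universally agreed unit convention; here the raw value C * BSA / ID
(BSA in m^2) is exposed together with the display variant that expresses
BSA in cm^2, i.e. ``suv_bsa = C / (ID / BSA_cm2)``.  The display variant
prints in the low single digits for typical adults (SUVbw 10 -> SUVbsa
~2.5), matching how clinical PET software reports it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .volume import PetVolume

__all__ = [
    "PatientMeta",
    "SuvMaps",
    "du_bois_bsa",
    "lean_body_mass",
    "activity_to_suv",
    "suv_maps",
]

BSA_DISPLAY_SCALE = 1e4  # m^2 -> cm^2 on the BSA normalizer


@dataclass(frozen=True)
class PatientMeta:
    """Anthropometrics and injection data needed for SUV computation.

    ``injected_activity_MBq`` is the net injected activity decay-corrected
    to scan start (standard console output); no decay arithmetic is done
    here.
    """

    sex: Literal["male", "female"]
    weight_kg: float
    height_cm: float
    injected_activity_MBq: float
    age_years: float | None = None
    uptake_time_min: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        for name in ("weight_kg", "height_cm", "injected_activity_MBq"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass
class SuvMaps:
    """Voxelwise SUV volumes under the three normalizations.

    ``suv_bsa`` carries the BSA-in-cm^2 display convention; ``suv_bsa_raw``
    is the unscaled C*BSA/ID value (BSA in m^2).  Constants used are kept
    for provenance.
    """

    suv_bw: PetVolume
    suv_lbm: PetVolume
    suv_bsa: PetVolume
    suv_bsa_raw: PetVolume
    constants: dict


def du_bois_bsa(weight_kg: float, height_cm: float) -> float:
    """Body surface area in m^2 by the Du Bois & Du Bois formula.

    BSA = 0.007184 * height_cm^0.725 * weight_kg^0.425
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be strictly positive")
    return 0.007184 * height_cm**0.725 * weight_kg**0.425


def lean_body_mass(
    weight_kg: float,
    height_cm: float,
    sex: str,
    formula: Literal["james", "janmahasatian"] = "james",
) -> float:
    """Lean body mass in kg.

    Default is the James (1976) equation pair; the Janmahasatian (2005)
    fat-free-mass model is available as an alternative.  Values outside
    (0, weight) indicate implausible anthropometrics and raise.
    """
    if weight_kg <= 0 or height_cm <= 0:
        raise ValueError("weight and height must be strictly positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if formula == "james":
        ratio = weight_kg / height_cm
        if sex == "male":
            lbm = 1.10 * weight_kg - 128.0 * ratio**2
        else:
            lbm = 1.07 * weight_kg - 148.0 * ratio**2
    elif formula == "janmahasatian":
        bmi = weight_kg / (height_cm / 100.0) ** 2
        if sex == "male":
            lbm = 9270.0 * weight_kg / (6680.0 + 216.0 * bmi)
        else:
            lbm = 9270.0 * weight_kg / (8780.0 + 244.0 * bmi)
    else:
        raise ValueError(f"unknown LBM formula {formula!r}")
    if not (0 < lbm < weight_kg):
        raise ValueError(
            f"lean body mass {lbm:.1f} kg outside (0, weight={weight_kg} kg): "
            "implausible anthropometrics"
        )
    return lbm


def activity_to_suv(
    volume: PetVolume,
    meta: PatientMeta,
    mode: Literal["bw", "lbm", "bsa", "bsa_raw"] = "bw",
    lbm_formula: Literal["james", "janmahasatian"] = "james",
) -> PetVolume:
    """Normalize an activity-concentration volume (kBq/mL) to SUV.

    SUV = C[Bq/mL] / (ID[Bq] / normalizer) with normalizer the body weight
    in grams (bw), lean body mass in grams (lbm), or Du Bois BSA in m^2
    (bsa_raw; ``bsa`` additionally applies the x100 display scale relative
    to SUVbw, see module docstring).
    """
    if np.any(volume.data < 0):
        raise ValueError("activity volume must be nonnegative")
    c_bq_ml = volume.data * 1000.0  # kBq/mL -> Bq/mL
    id_bq = meta.injected_activity_MBq * 1e6
    if mode == "bw":
        suv = c_bq_ml / (id_bq / (meta.weight_kg * 1000.0))
    elif mode == "lbm":
        lbm = lean_body_mass(meta.weight_kg, meta.height_cm, meta.sex, lbm_formula)
        suv = c_bq_ml / (id_bq / (lbm * 1000.0))
    elif mode in ("bsa", "bsa_raw"):
        bsa = du_bois_bsa(meta.weight_kg, meta.height_cm)
        suv = c_bq_ml * bsa / id_bq
        if mode == "bsa":
            suv = suv * BSA_DISPLAY_SCALE  # BSA in cm^2
    else:
        raise ValueError(f"unknown SUV mode {mode!r}")
    return PetVolume(data=suv, affine=volume.affine.copy(), units=f"SUV{mode}", meta=dict(volume.meta))


def suv_maps(
    volume: PetVolume,
    meta: PatientMeta,
    lbm_formula: Literal["james", "janmahasatian"] = "james",
) -> SuvMaps:
    """All three SUV normalizations of one activity volume."""
    bsa = du_bois_bsa(meta.weight_kg, meta.height_cm)
    lbm = lean_body_mass(meta.weight_kg, meta.height_cm, meta.sex, lbm_formula)
    return SuvMaps(
        suv_bw=activity_to_suv(volume, meta, "bw"),
        suv_lbm=activity_to_suv(volume, meta, "lbm", lbm_formula),
        suv_bsa=activity_to_suv(volume, meta, "bsa"),
        suv_bsa_raw=activity_to_suv(volume, meta, "bsa_raw"),
        constants={
            "weight_kg": meta.weight_kg,
            "lbm_kg": lbm,
            "bsa_m2": bsa,
            "injected_activity_MBq": meta.injected_activity_MBq,
            "bsa_display_scale": BSA_DISPLAY_SCALE,
            "lbm_formula": lbm_formula,
        },
    )
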