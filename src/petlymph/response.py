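"""End-of-treatment response: Deauville five-point scale and Lugano mapping.

The Deauville score grades residual uptake of the hottest residual focus
against two physiological references measured on the same scan:

1. no uptake above background,
2. uptake <= mediastinal blood pool,
3. mediastinum < uptake <= liver,
4. uptake moderately above liver (here: <= k x liver, default k = 2),
5. uptake markedly above liver (> k x liver) or any new lesion.

Equality with the liver is scored 3, following standard Deauville
semantics (DS3 is "uptake not above liver").  Lugano collapses the scale:
scores 1-3 are a complete metabolic response (CMR) unless new lesions are
present; 4-5 are not complete.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

__all__ = ["EotAssessment", "deauville_score", "lugano_response", "assess_eot"]

MARKED_UPTAKE_MULTIPLIER = 2.0


@dataclass(frozen=True)
class EotAssessment:
    residual_suv_max: float
    mediastinum_suv: float
    liver_suv: float
    new_lesions: bool
    deauville: int
    response: Literal["complete", "not_complete"]


def deauville_score(
    residual_suv_max: float,
    mediastinum_suv: float,
    liver_suv: float,
    new_lesions: bool = False,
    marked_multiplier: float = MARKED_UPTAKE_MULTIPLIER,
) -> int:
    """Deauville score 1-5 for the hottest residual focus.

    ``residual_suv_max`` of 0 means no residual uptake above background.
    New lesions force a score of 5 regardless of intensity.
    """
    if residual_suv_max < 0:
        raise ValueError("residual SUV cannot be negative")
    if mediastinum_suv <= 0 or liver_suv <= 0:
        raise ValueError("reference SUVs must be strictly positive")
    if mediastinum_suv >= liver_suv:
        warnings.warn(
            "mediastinal blood pool >= liver reference: check reference ROIs",
            stacklevel=2,
        )
    if new_lesions:
        return 5
    if residual_suv_max == 0:
        return 1
    if residual_suv_max <= mediastinum_suv:
        return 2
    if residual_suv_max <= liver_suv:
        return 3
    if residual_suv_max <= marked_multiplier * liver_suv:
        return 4
    return 5


def lugano_response(deauville: int, new_lesions: bool = False) -> str:
    """Binary Lugano metabolic response from a Deauville score.

    Complete metabolic response iff the score is 1-3 and no new lesions
    appeared (new lesions mean progressive disease even at low residual
    uptake).
    """
    if deauville not in (1, 2, 3, 4, 5):
        raise ValueError(f"Deauville score must be 1..5, got {deauville}")
    return "complete" if deauville <= 3 and not new_lesions else "not_complete"


def assess_eot(
    residual_suv_max: float,
    mediastinum_suv: float,
    liver_suv: float,
    new_lesions: bool = False,
    marked_multiplier: float = MARKED_UPTAKE_MULTIPLIER,
) -> EotAssessment:
    """Score a scan and map to Lugano response in one step."""
    ds = deauville_score(residual_suv_max, mediastinum_suv, liver_suv, new_lesions, marked_multiplier)
    return EotAssessment(
        residual_suv_max=residual_suv_max,
        mediastinum_suv=mediastinum_suv,
        liver_suv=liver_suv,
        new_lesions=new_lesions,
        deauville=ds,
        response=lugano_response(ds, new_lesions),  # type: ignore[arg-type]
    )
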