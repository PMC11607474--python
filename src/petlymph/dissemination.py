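"""Tumor dissemination features: Dmax and its body-surface-area correction.

Dmax is the largest Euclidean distance between any two lesions of a
patient (nodal and extranodal alike), a proxy for how spread-out the
hypermetabolic disease is.  Because an absolute distance ignores body
habitus, Dmax-bsa divides by the Du Bois body surface area (cm per m^2).

Lesion positions default to intensity-weighted centroids; the hottest
voxel of each lesion is available as an alternative reference point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .lesions import LesionSet

__all__ = ["DisseminationResult", "dmax", "dmax_bsa"]


@dataclass(frozen=True)
class DisseminationResult:
    dmax_cm: float
    argmax_pair: tuple[int, int] | None
    degenerate: bool  # True when fewer than two lesions

    def with_bsa(self, bsa_m2: float) -> float:
        return dmax_bsa(self.dmax_cm, bsa_m2)


def dmax(lesions: LesionSet | np.ndarray) -> DisseminationResult:
    """Maximum pairwise centroid distance, reported in cm.

    Accepts a :class:`LesionSet` or an ``(n, 3)`` array of positions in mm.
    With fewer than two lesions the result is 0 with ``degenerate=True``
    rather than an error.  Ties are broken toward the lexicographically
    smallest index pair.
    """
    pts = lesions.centroids_mm if isinstance(lesions, LesionSet) else np.atleast_2d(np.asarray(lesions, float))
    n = len(pts)
    if n < 2:
        return DisseminationResult(dmax_cm=0.0, argmax_pair=None, degenerate=True)
    d = squareform(pdist(pts))
    iu = np.triu_indices(n, k=1)
    flat = d[iu]
    best = int(np.argmax(flat))  # argmax returns the first (lowest-pair) maximum
    pair = (int(iu[0][best]), int(iu[1][best]))
    return DisseminationResult(dmax_cm=float(flat[best]) / 10.0, argmax_pair=pair, degenerate=False)


def dmax_bsa(dmax_cm: float, bsa_m2: float) -> float:
    """Dissemination normalized by body surface area: Dmax / BSA (cm/m^2)."""
    if bsa_m2 <= 0:
        raise ValueError("BSA must be strictly positive")
    return dmax_cm / bsa_m2
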