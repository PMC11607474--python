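"""Synthetic patient cohorts with survival under a known hazard model.

The simulator emulates an advanced mantle-cell-lymphoma population at the
feature level (no voxel data): every patient carries at least two
hypermetabolic lesions, PET burden features with marginals in the ranges
typical of the disease (SUVbw roughly 3.5-14.5, MTV 2-4000 cm^3, Dmax
6-82 cm), standard clinical covariates, an end-of-treatment Deauville /
Lugano response driven by age and Ki-67, and progression-free / overall
survival generated under Weibull proportional-hazards models in which
baseline tumor burden (MTV) and metabolic response drive progression while
dissemination (Dmax-bsa) drives death.

Endpoint coupling: latent progression and death times are drawn
independently given the covariates; a death occurring before progression
right-censors the progression endpoint at the death time.  The observed
PFS time therefore never exceeds the observed OS time, both endpoints stay
exactly proportional-hazards in their generating covariates, and the PFS
event flag means relapse/progression only.

Dichotomous "high burden" / "high dissemination" indicators used in the
hazards are within-cohort median splits of the continuous features, so
recovery analyses can condition on exactly the covariates that generated
the risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dissemination import dmax as _dmax
from .suv import du_bois_bsa, lean_body_mass

__all__ = ["CohortSimConfig", "sample_survival", "generate_cohort"]


@dataclass(frozen=True)
class WeibullBaseline:
    """Weibull PH baseline: S0(t) = exp(-(t/scale)^shape), t in months."""

    shape: float
    scale_months: float

    def validate(self) -> None:
        if self.shape <= 0 or self.scale_months <= 0:
            raise ValueError("Weibull shape and scale must be positive")


@dataclass
class CohortSimConfig:
    """Study conditions for the cohort generator.

    Log-hazard coefficients default to the multivariate effect pattern of
    the target population: HR 2.7 for high baseline MTV and 3.5 for an
    incomplete metabolic response on progression, HR 1.75 for high
    Dmax-bsa on death.
    """

    n_patients: int = 120
    seed: int = 0

    # lesion count: 2 + Poisson(lambda), guaranteeing >= 2 lesions
    lesion_count_lambda: float = 3.0
    # log-normal laws (mu, sigma of log) with plausibility clips
    suv_law: tuple[float, float] = (np.log(9.8), 0.33)
    suv_clip: tuple[float, float] = (3.5, 14.5)
    mtv_law: tuple[float, float] = (np.log(358.0), 0.794)
    mtv_clip: tuple[float, float] = (2.0, 4000.0)
    suv_mean_fraction: float = 0.7  # SUVmean/SUVmax inside a 41% isocontour
    # body habitus, normal (mean, sd) per sex
    weight_law: dict = field(
        default_factory=lambda: {"male": (78.0, 12.0), "female": (65.0, 11.0)}
    )
    height_law: dict = field(
        default_factory=lambda: {"male": (174.0, 7.0), "female": (161.0, 7.0)}
    )
    male_fraction: float = 0.75
    # lesion scatter geometry: axial span as fraction of height, xy jitter mm
    axial_fraction: float = 0.47
    xy_jitter_mm: float = 50.0

    # log-hazard coefficients
    beta_mtv_pfs: float = float(np.log(2.7))
    beta_response_pfs: float = float(np.log(3.5))
    beta_dmax_bsa_os: float = float(np.log(1.75))

    pfs_baseline: WeibullBaseline = field(default_factory=lambda: WeibullBaseline(1.1, 85.0))
    os_baseline: WeibullBaseline = field(default_factory=lambda: WeibullBaseline(1.1, 112.0))
    censor_admin_months: float = 120.0

    # incomplete-response model: logit P(non-CR) = a + b_age*(age-65.6)/1 + b_ki67*ki67_high
    response_intercept: float = -1.2
    response_beta_age: float = 0.04  # per year
    response_beta_ki67: float = 1.0

    # clinical covariate marginals
    p_stage: tuple[float, float, float] = (0.042, 0.092, 0.866)  # II, III, IV
    p_mipi: tuple[float, float, float] = (0.30, 0.375, 0.325)  # low, int, high
    p_blastoid: float = 0.133
    p_b_symptoms: float = 0.242
    p_ldh_increased: float = 0.358
    p_b2m_increased: float = 0.317
    p_bulky: float = 0.133
    p_splenomegaly: float = 0.408
    p_ki67_high: float = 0.358
    p_marrow: float = 0.283

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.lesion_count_lambda < 0:
            raise ValueError("lesion_count_lambda must be nonnegative")
        for law in (self.suv_law, self.mtv_law):
            if law[1] <= 0:
                raise ValueError("log-normal sigma must be positive")
        self.pfs_baseline.validate()
        self.os_baseline.validate()
        if self.censor_admin_months <= 0:
            raise ValueError("censoring horizon must be positive")


def sample_survival(
    linear_predictor: float | np.ndarray,
    baseline: WeibullBaseline,
    censor_months: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw right-censored Weibull PH event times.

    T = scale * (-ln U * exp(-lp))^(1/shape); observed time = min(T, censor),
    event flag 1 iff T <= censor.  ``censor_months`` may be ``np.inf``
    (no censoring) or 0 (everything censored at baseline).
    """
    baseline.validate()
    lp = np.atleast_1d(np.asarray(linear_predictor, dtype=float))
    u = rng.uniform(size=lp.shape)
    t = baseline.scale_months * (-np.log(u) * np.exp(-lp)) ** (1.0 / baseline.shape)
    time = np.minimum(t, censor_months)
    event = (t <= censor_months).astype(int)
    return time, event


def _lesion_geometry(rng, n_lesions: int, height_cm: float, cfg: CohortSimConfig) -> float:
    """Scatter lesion centers in a body-shaped region; return Dmax in cm."""
    span_mm = cfg.axial_fraction * height_cm * 10.0
    z = rng.uniform(0.0, span_mm, size=n_lesions)
    xy = rng.normal(0.0, cfg.xy_jitter_mm, size=(n_lesions, 2))
    pts = np.column_stack([xy, z])
    return _dmax(pts).dmax_cm


def generate_cohort(config: CohortSimConfig | None = None) -> pd.DataFrame:
    """Simulate a patient-level cohort table.

    Returns one row per patient with anthropometrics, clinical covariates,
    PET burden and dissemination features, Deauville/Lugano response, and
    ``(time, event)`` pairs for PFS and OS.  ``df.attrs`` records the seed
    and the true high-burden cutoffs used inside the hazard model.
    Deterministic for a fixed ``config.seed``.
    """
    cfg = config or CohortSimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients

    sex = np.where(rng.uniform(size=n) < cfg.male_fraction, "male", "female")
    age = np.clip(rng.normal(65.6, 10.0, size=n), 30.0, 89.0)
    weight = np.empty(n)
    height = np.empty(n)
    for s in ("male", "female"):
        m = sex == s
        weight[m] = np.clip(rng.normal(*cfg.weight_law[s], size=m.sum()), 40.0, 140.0)
        height[m] = np.clip(rng.normal(*cfg.height_law[s], size=m.sum()), 140.0, 205.0)
    bsa = np.array([du_bois_bsa(w, h) for w, h in zip(weight, height)])
    lbm = np.array([lean_body_mass(w, h, s) for w, h, s in zip(weight, height, sex)])

    stage = rng.choice(["II", "III", "IV"], size=n, p=np.asarray(cfg.p_stage) / sum(cfg.p_stage))
    mipi = rng.choice(["low", "intermediate", "high"], size=n, p=np.asarray(cfg.p_mipi) / sum(cfg.p_mipi))
    blastoid = rng.uniform(size=n) < cfg.p_blastoid
    b_symptoms = rng.uniform(size=n) < cfg.p_b_symptoms
    ldh_inc = rng.uniform(size=n) < cfg.p_ldh_increased
    b2m_inc = rng.uniform(size=n) < cfg.p_b2m_increased
    bulky = rng.uniform(size=n) < cfg.p_bulky
    splenomegaly = rng.uniform(size=n) < cfg.p_splenomegaly
    ki67_high = rng.uniform(size=n) < cfg.p_ki67_high
    marrow = rng.uniform(size=n) < cfg.p_marrow

    n_lesions = 2 + rng.poisson(cfg.lesion_count_lambda, size=n)
    suv_bw = np.clip(rng.lognormal(*cfg.suv_law, size=n), *cfg.suv_clip)
    mtv = np.clip(rng.lognormal(*cfg.mtv_law, size=n), *cfg.mtv_clip)
    suv_lbm = suv_bw * lbm / weight
    suv_bsa = suv_bw * bsa / weight * 10.0  # BSA-in-cm^2 display convention

    # per-lesion split of MTV and SUV for TLG
    tlg = np.empty(n)
    dmax_cm = np.empty(n)
    for i in range(n):
        k = n_lesions[i]
        vols = mtv[i] * rng.dirichlet(np.ones(k))
        suvmax_i = suv_bw[i] * np.r_[1.0, rng.uniform(0.5, 1.0, size=k - 1)]
        tlg[i] = float(np.sum(vols * cfg.suv_mean_fraction * suvmax_i))
        dmax_cm[i] = _lesion_geometry(rng, k, height[i], cfg)
    dmax_bsa = dmax_cm / bsa

    # end-of-treatment response, driven by age and Ki-67
    logit = (
        cfg.response_intercept
        + cfg.response_beta_age * (age - 65.6)
        + cfg.response_beta_ki67 * ki67_high.astype(float)
    )
    non_cr = rng.uniform(size=n) < 1.0 / (1.0 + np.exp(-logit))
    response = np.where(non_cr, "not_complete", "complete")
    deauville = np.empty(n, dtype=int)
    cmr = ~non_cr
    deauville[cmr] = rng.choice([1, 2, 3], size=int(cmr.sum()), p=[62 / 83, 12 / 83, 9 / 83])
    deauville[non_cr] = rng.choice([4, 5], size=int(non_cr.sum()), p=[19 / 35, 16 / 35])

    # within-cohort median splits = the true hazard covariates
    mtv_cutoff = float(np.median(mtv))
    dmax_bsa_cutoff = float(np.median(dmax_bsa))
    high_mtv = (mtv > mtv_cutoff).astype(int)
    high_dbsa = (dmax_bsa > dmax_bsa_cutoff).astype(int)

    lp_pfs = cfg.beta_mtv_pfs * high_mtv + cfg.beta_response_pfs * non_cr.astype(float)
    lp_os = cfg.beta_dmax_bsa_os * high_dbsa

    t_prog, _ = sample_survival(lp_pfs, cfg.pfs_baseline, np.inf, rng)
    t_death, _ = sample_survival(lp_os, cfg.os_baseline, np.inf, rng)

    c = cfg.censor_admin_months
    os_months = np.minimum(t_death, c)
    os_event = (t_death <= c).astype(int)
    pfs_censor = np.minimum(t_death, c)  # death before progression censors PFS
    pfs_months = np.minimum(t_prog, pfs_censor)
    pfs_event = (t_prog <= pfs_censor).astype(int)

    df = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "sex": sex,
            "age_years": age,
            "weight_kg": weight,
            "height_cm": height,
            "bsa_m2": bsa,
            "stage": stage,
            "stage_iv": (stage == "IV").astype(int),
            "mipi": mipi,
            "mipi_high": (mipi == "high").astype(int),
            "blastoid": blastoid.astype(int),
            "b_symptoms": b_symptoms.astype(int),
            "ldh_increased": ldh_inc.astype(int),
            "b2m_increased": b2m_inc.astype(int),
            "bulky": bulky.astype(int),
            "splenomegaly": splenomegaly.astype(int),
            "ki67_high": ki67_high.astype(int),
            "marrow_involved": marrow.astype(int),
            "n_lesions": n_lesions,
            "suv_bw_max": suv_bw,
            "suv_lbm_max": suv_lbm,
            "suv_bsa_max": suv_bsa,
            "mtv_cm3": mtv,
            "tlg": tlg,
            "dmax_cm": dmax_cm,
            "dmax_bsa": dmax_bsa,
            "high_mtv_true": high_mtv,
            "high_dmax_bsa_true": high_dbsa,
            "deauville": deauville,
            "response": response,
            "non_complete_response": non_cr.astype(int),
            "pfs_months": pfs_months,
            "pfs_event": pfs_event,
            "os_months": os_months,
            "os_event": os_event,
        }
    )
    df.attrs["seed"] = cfg.seed
    df.attrs["mtv_cutoff_true"] = mtv_cutoff
    df.attrs["dmax_bsa_cutoff_true"] = dmax_bsa_cutoff
    return df
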