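"""End-to-end orchestration: quantify volumes, run the survival analysis.

``run_quantify`` turns a directory of SUV volumes (NIfTI + JSON sidecar
metadata) into a per-patient feature table; ``run_survival`` runs the
full prognostic chain on a cohort table: descriptives, response-group
comparison, ROC dichotomization of continuous features, univariate
log-rank/Cox screening, multivariate Cox on the univariately significant
covariates, and the combined burden-by-response stratification.  Every
run writes a JSON manifest with the config, seed and package version so
results can be reproduced byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .dissemination import dmax, dmax_bsa
from .lesions import quantify_patient, segment_lesions
from .suv import PatientMeta, du_bois_bsa, suv_maps
from .survival import (
    COMBINED_GROUP_ORDER,
    CoxPH,
    SurvivalSample,
    combined_strata,
    km_estimate,
    logrank_test,
    roc_best_cutoff,
)
from .volume import PetVolume

logger = logging.getLogger("petlymph")

__all__ = ["RunConfig", "run_quantify", "run_survival", "quantify_volume"]

#: continuous PET features dichotomized before survival screening
CONTINUOUS_FEATURES = ["suv_bw_max", "suv_lbm_max", "suv_bsa_max", "mtv_cm3", "tlg", "dmax_cm", "dmax_bsa"]
#: binary clinical covariates entering the univariate screen as-is
BINARY_COVARIATES = [
    "stage_iv", "b_symptoms", "blastoid", "ldh_increased", "b2m_increased",
    "bulky", "splenomegaly", "ki67_high", "mipi_high", "non_complete_response",
]
ENDPOINTS = {"pfs": ("pfs_months", "pfs_event"), "os": ("os_months", "os_event")}


@dataclass
class RunConfig:
    """Knobs of a quantification + survival run."""

    seed_threshold_suv: float = 2.5
    connectivity: int = 26
    min_voxels: int = 2
    isocontour_fraction: float = 0.41
    deauville_marked_multiplier: float = 2.0
    cox_ties: str = "efron"
    alpha: float = 0.05
    output_dir: str | None = None
    seed: int = 0
    extra: dict = field(default_factory=dict)


def quantify_volume(volume: PetVolume, meta: PatientMeta, config: RunConfig | None = None) -> dict:
    """Quantify one patient volume into the per-patient feature row.

    ``volume`` may hold raw activity (kBq/mL, normalized here) or be an
    SUV volume already (``units`` starting with 'SUV').
    """
    cfg = config or RunConfig()
    if volume.units.upper().startswith("SUV"):
        maps = None
        suv_vol = volume
    else:
        maps = suv_maps(volume, meta)
        suv_vol = maps.suv_bw
    lesions = segment_lesions(
        suv_vol,
        seed_threshold_suv=cfg.seed_threshold_suv,
        connectivity=cfg.connectivity,
        min_voxels=cfg.min_voxels,
        fraction=cfg.isocontour_fraction,
    )
    bsa = du_bois_bsa(meta.weight_kg, meta.height_cm)
    row: dict = {
        "n_lesions": len(lesions),
        "mtv_cm3": lesions.total_mtv_cm3,
        "tlg": lesions.total_tlg,
        "bsa_m2": bsa,
    }
    if len(lesions) == 0:
        row.update({"suv_bw_max": 0.0, "dmax_cm": 0.0, "dmax_bsa": 0.0, "no_lesions_flag": True})
        return row
    if maps is not None:
        q = quantify_patient(maps, lesions)
        row.update(
            suv_bw_max=q.suv_bw_max, suv_lbm_max=q.suv_lbm_max, suv_bsa_max=q.suv_bsa_max
        )
    else:
        all_ijk = np.vstack([l.voxel_indices for l in lesions])
        row["suv_bw_max"] = float(suv_vol.data[tuple(all_ijk.T)].max())
    d = dmax(lesions)
    row["dmax_cm"] = d.dmax_cm
    row["dmax_bsa"] = dmax_bsa(d.dmax_cm, bsa) if not d.degenerate else 0.0
    row["dmax_degenerate"] = d.degenerate
    return row


def run_quantify(volumes_dir: str | Path, config: RunConfig | None = None) -> pd.DataFrame:
    """Quantify every NIfTI volume in a directory into a feature table.

    Each ``<name>.nii[.gz]`` needs a ``<name>.json`` sidecar with
    ``weight_kg``, ``height_cm``, ``sex`` and ``injected_MBq``.  Volumes
    with missing metadata or unreadable data are skipped with a logged
    reason; the returned table has one row per successfully quantified
    patient, sorted by patient id for determinism.
    """
    cfg = config or RunConfig()
    volumes_dir = Path(volumes_dir)
    rows = []
    paths = sorted(list(volumes_dir.glob("*.nii")) + list(volumes_dir.glob("*.nii.gz")))
    for path in paths:
        pid = path.name.removesuffix(".gz").removesuffix(".nii")
        try:
            vol = PetVolume.from_nifti(path)
            m = vol.meta
            meta = PatientMeta(
                sex=m["sex"],
                weight_kg=float(m["weight_kg"]),
                height_cm=float(m["height_cm"]),
                injected_activity_MBq=float(m.get("injected_MBq", m.get("injected_activity_MBq", 0))),
            )
        except Exception as exc:  # unreadable volume or bad metadata -> skip with reason
            logger.warning("skipping %s: %s", path.name, exc)
            continue
        row = {"patient_id": pid, **quantify_volume(vol, meta, cfg)}
        rows.append(row)
    df = pd.DataFrame(rows)
    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        df.to_csv(out / "features.csv", index=False)
        _write_manifest(out, cfg, {"n_volumes_seen": len(paths), "n_quantified": len(df)})
    return df


# ----------------------------------------------------------------- survival


def _describe(df: pd.DataFrame) -> pd.DataFrame:
    """Descriptive table: counts/percentages and mean +- SD (range), median."""
    rows = []
    for col in BINARY_COVARIATES:
        if col in df:
            x = df[col].dropna()
            rows.append({"variable": col, "n": int(x.sum()), "pct": 100.0 * x.mean()})
    for col in [c for c in ["age_years"] + CONTINUOUS_FEATURES if c in df]:
        x = df[col].dropna()
        rows.append(
            {
                "variable": col,
                "mean": x.mean(),
                "sd": x.std(ddof=1),
                "min": x.min(),
                "max": x.max(),
                "median": x.median(),
            }
        )
    return pd.DataFrame(rows)


def _compare_groups(df: pd.DataFrame) -> pd.DataFrame:
    """Response-group comparison: Welch t for continuous, chi-square for binary."""
    cmr = df["non_complete_response"] == 0
    rows = []
    for col in BINARY_COVARIATES:
        if col == "non_complete_response" or col not in df:
            continue
        tab = pd.crosstab(df[col], df["non_complete_response"])
        if tab.shape == (2, 2):
            _, p, _, _ = stats.chi2_contingency(tab, correction=True)
        else:
            p = np.nan
        rows.append({"variable": col, "test": "chi2", "p": p})
    for col in [c for c in ["age_years"] + CONTINUOUS_FEATURES if c in df]:
        a, b = df.loc[cmr, col].dropna(), df.loc[~cmr, col].dropna()
        t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append({"variable": col, "test": "welch_t", "p": p, "mean_cmr": a.mean(), "mean_noncmr": b.mean()})
    return pd.DataFrame(rows)


def _screen_endpoint(df: pd.DataFrame, endpoint: str, cfg: RunConfig) -> tuple[pd.DataFrame, dict]:
    """Univariate screening of all covariates against one endpoint.

    Continuous PET features are dichotomized at their ROC-optimal (Youden)
    cutoff against the endpoint's event flag; binary covariates enter
    directly.  Each covariate gets a univariate Cox HR/CI/p and a log-rank
    p.  Returns the screen table and the cutoffs used.
    """
    tcol, ecol = ENDPOINTS[endpoint]
    sample = SurvivalSample(df[tcol].to_numpy(), df[ecol].to_numpy(), endpoint)
    cutoffs: dict = {}
    rows = []
    for col in BINARY_COVARIATES + CONTINUOUS_FEATURES:
        if col not in df:
            continue
        if col in CONTINUOUS_FEATURES:
            try:
                cut = roc_best_cutoff(df[col].to_numpy(), df[ecol].to_numpy())
            except ValueError:
                continue
            cutoffs[col] = cut.threshold
            indicator = (df[col].to_numpy() > cut.threshold).astype(int)
        else:
            indicator = df[col].to_numpy().astype(int)
        if indicator.min() == indicator.max():
            continue
        fit = CoxPH(sample, indicator[:, None], names=[col]).fit(ties=cfg.cox_ties)
        ci = fit.conf_int(cfg.alpha)[0]
        chi2, p_lr = logrank_test(sample.subset(indicator == 0), sample.subset(indicator == 1))
        rows.append(
            {
                "variable": col,
                "dichotomized": col in CONTINUOUS_FEATURES,
                "HR": fit.hazard_ratios[0],
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_cox": fit.pvalues[0],
                "p_logrank": p_lr,
                "converged": fit.converged,
            }
        )
    return pd.DataFrame(rows), cutoffs


def run_survival(df: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Full prognostic analysis of a cohort feature table.

    Returns a bundle (dict) with descriptives, the response-group
    comparison, per-endpoint univariate screens, multivariate Cox fits on
    the univariately significant covariates, Kaplan-Meier summaries of the
    combined MTV-by-response strata, and the ROC cutoffs used.  Endpoints
    with fewer than 2 events are skipped with a warning.
    """
    cfg = config or RunConfig()
    if len(df) == 0:
        raise ValueError("empty feature table")
    for col in ("pfs_months", "pfs_event", "os_months", "os_event"):
        if col not in df:
            raise ValueError(f"cohort table lacks required endpoint column {col!r}")

    bundle: dict = {
        "descriptives": _describe(df),
        "response_comparison": _compare_groups(df) if "non_complete_response" in df else None,
        "univariate": {},
        "multivariate": {},
        "cutoffs": {},
        "combined_strata": None,
        "manifest": {"version": __version__, "seed": cfg.seed, "config": asdict(cfg), "n_patients": len(df)},
    }

    for endpoint, (tcol, ecol) in ENDPOINTS.items():
        if df[ecol].sum() < 2:
            logger.warning("endpoint %s skipped: fewer than 2 events", endpoint)
            continue
        screen, cutoffs = _screen_endpoint(df, endpoint, cfg)
        bundle["univariate"][endpoint] = screen
        bundle["cutoffs"][endpoint] = cutoffs
        sig = screen.loc[screen["p_cox"] < cfg.alpha, "variable"].tolist()
        if sig:
            X = np.column_stack(
                [
                    (df[v].to_numpy() > cutoffs[v]).astype(int) if v in cutoffs else df[v].to_numpy()
                    for v in sig
                ]
            )
            sample = SurvivalSample(df[tcol].to_numpy(), df[ecol].to_numpy(), endpoint)
            bundle["multivariate"][endpoint] = CoxPH(sample, X, names=sig).fit(ties=cfg.cox_ties)

    # combined baseline burden x metabolic response strata on PFS
    if "response" in df and "mtv_cm3" in df and "pfs" in bundle["cutoffs"]:
        cut = bundle["cutoffs"]["pfs"].get("mtv_cm3", float(df["mtv_cm3"].median()))
        groups = [combined_strata(m, cut, r) for m, r in zip(df["mtv_cm3"], df["response"])]
        n_missing = sum(g is None for g in groups)
        if n_missing:
            logger.info("combined strata: %d patients excluded for missing response", n_missing)
        strata = {}
        for name in COMBINED_GROUP_ORDER:
            mask = np.array([g == name for g in groups])
            if mask.sum() == 0:
                continue
            curve = km_estimate(SurvivalSample(df["pfs_months"].to_numpy()[mask], df["pfs_event"].to_numpy()[mask]))
            strata[name] = {"n": int(mask.sum()), "median_pfs_months": curve.median_months, "curve": curve}
        bundle["combined_strata"] = {"mtv_cutoff": cut, "groups": strata, "n_missing_response": n_missing}

    if cfg.output_dir:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["descriptives"].to_csv(out / "descriptives.csv", index=False)
        if bundle["response_comparison"] is not None:
            bundle["response_comparison"].to_csv(out / "response_comparison.csv", index=False)
        for ep, tab in bundle["univariate"].items():
            tab.to_csv(out / f"univariate_{ep}.csv", index=False)
        for ep, fit in bundle["multivariate"].items():
            fit.summary(cfg.alpha).to_csv(out / f"multivariate_{ep}.csv")
        _write_manifest(out, cfg, {"cutoffs": bundle["cutoffs"], "n_patients": len(df)})
    return bundle


def _write_manifest(out: Path, cfg: RunConfig, extra: dict) -> None:
    manifest = {"version": __version__, "config": asdict(cfg), **extra}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=float))
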