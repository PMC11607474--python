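"""Survival statistics: Kaplan-Meier, log-rank, Cox PH, ROC dichotomization.

The chain implemented here is the standard prognostic-factor analysis of
oncology imaging studies: continuous PET features are dichotomized at a
ROC-derived cutoff (Youden's J against the endpoint event indicator),
groups are compared with Kaplan-Meier curves and two-sided log-rank tests,
and effect sizes come from Cox proportional-hazards regression reported as
hazard ratios with 95% Wald confidence intervals.

The Cox model follows the statsmodels idiom: build a :class:`CoxPH` model
from arrays or a DataFrame, call :meth:`CoxPH.fit`, and read estimates off
the returned :class:`CoxResults` (``hazard_ratios``, ``conf_int()``,
``summary()``).  The partial likelihood is maximized by Newton-Raphson
with Efron (default) or Breslow tie handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SurvivalSample",
    "SurvivalCurve",
    "km_estimate",
    "logrank_test",
    "CoxPH",
    "CoxResults",
    "RocCutoff",
    "roc_best_cutoff",
    "combined_strata",
    "COMBINED_GROUP_ORDER",
]


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored follow-up: times in months, binary event flags."""

    times: np.ndarray
    events: np.ndarray
    endpoint: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        e = np.asarray(self.events, dtype=int)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("times and events must be equal-length 1-D arrays")
        if np.any(t < 0) or np.any(~np.isfinite(t)):
            raise ValueError("times must be finite and nonnegative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("events must be 0/1 flags")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "events", e)

    def __len__(self) -> int:
        return len(self.times)

    def subset(self, mask: np.ndarray) -> "SurvivalSample":
        return SurvivalSample(self.times[mask], self.events[mask], self.endpoint)


@dataclass
class SurvivalCurve:
    """Product-limit estimate with at-risk counts and the survival median."""

    event_times: np.ndarray
    survival_probabilities: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    median_months: float | None  # None when S(t) never reaches 0.5

    def survival_at(self, t: float | np.ndarray) -> np.ndarray:
        """Step-function value S(t); S = 1 before the first event."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        if len(self.event_times) == 0:
            return np.ones_like(t)
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return np.where(idx >= 0, self.survival_probabilities[np.clip(idx, 0, None)], 1.0)


def km_estimate(sample: SurvivalSample) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    S(t) = prod_{t_i <= t} (1 - d_i / n_i) over distinct event times t_i,
    with d_i events among n_i at risk.  The median is the earliest event
    time with S(t) <= 0.5, undefined (None) if the curve never gets there.
    """
    if len(sample) == 0:
        raise ValueError("empty sample")
    t = np.sort(sample.times)
    te = np.sort(sample.times[sample.events == 1])
    uniq = np.unique(te)
    n_at_risk = len(t) - np.searchsorted(t, uniq, side="left")
    d = np.searchsorted(te, uniq, side="right") - np.searchsorted(te, uniq, side="left")
    surv = np.cumprod(1.0 - d / n_at_risk) if len(uniq) else np.array([])
    median = None
    if len(uniq):
        below = np.nonzero(surv <= 0.5)[0]
        if below.size:
            median = float(uniq[below[0]])
    return SurvivalCurve(
        event_times=uniq,
        survival_probabilities=surv,
        at_risk=n_at_risk,
        n_events=d,
        median_months=median,
    )


def logrank_test(group_a: SurvivalSample, group_b: SurvivalSample) -> tuple[float, float]:
    """Two-group, two-sided log-rank test (1 df).

    Returns ``(chi2, p)``.  The statistic pools observed-minus-expected
    event counts for group A over all distinct event times, with the usual
    hypergeometric variance.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")

    def _counts(sorted_all, sorted_events, u):
        at_risk = len(sorted_all) - np.searchsorted(sorted_all, u, side="left")
        d = np.searchsorted(sorted_events, u, side="right") - np.searchsorted(
            sorted_events, u, side="left"
        )
        return at_risk, d

    ta = np.sort(group_a.times)
    tae = np.sort(group_a.times[group_a.events == 1])
    tb = np.sort(group_b.times)
    tbe = np.sort(group_b.times[group_b.events == 1])
    pooled = np.sort(np.concatenate([ta, tb]))
    pooled_e = np.sort(np.concatenate([tae, tbe]))
    uniq = np.unique(pooled_e)
    n, d = _counts(pooled, pooled_e, uniq)
    n_a, d_a = _counts(ta, tae, uniq)
    o_minus_e = float(np.sum(d_a - d * n_a / n))
    with np.errstate(invalid="ignore", divide="ignore"):
        v = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
    var = float(np.sum(v[n > 1]))
    if var <= 0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


# --------------------------------------------------------------------- Cox


class CoxPH:
    """Cox proportional-hazards model for right-censored data.

    Parameters
    ----------
    sample
        Follow-up times and event flags.
    exog
        Covariate matrix, shape ``(n, p)``.  Columns must not be constant.
    names
        Covariate names for reporting.

    Use :meth:`from_dataframe` to build from a cohort table.
    """

    def __init__(
        self,
        sample: SurvivalSample,
        exog: np.ndarray,
        names: Sequence[str] | None = None,
    ):
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.shape[0] != len(sample):
            raise ValueError("exog rows must match sample length")
        if sample.events.sum() < 1:
            raise ValueError("at least one event is required")
        const = np.ptp(X, axis=0) == 0
        if const.any():
            bad = np.nonzero(const)[0]
            raise ValueError(f"covariate column(s) {bad.tolist()} are constant")
        self.sample = sample
        self.exog = X
        self.names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        duration_col: str,
        event_col: str,
        covariates: Sequence[str],
    ) -> "CoxPH":
        sample = SurvivalSample(df[duration_col].to_numpy(), df[event_col].to_numpy(), duration_col)
        return cls(sample, df[list(covariates)].to_numpy(dtype=float), names=list(covariates))

    # -- partial likelihood machinery -----------------------------------
    def _loglike_grad_hess(self, beta: np.ndarray, ties: str):
        """Partial log-likelihood, gradient and Hessian at ``beta``.

        Fully vectorized: suffix sums give the risk-set aggregates per
        distinct event time, and the Efron tie correction is expanded to
        one row per (event time, tie rank) pair.
        """
        t, e, X = self.sample.times, self.sample.events, self.exog
        order = np.argsort(t, kind="stable")
        t, e, X = t[order], e[order], X[order]
        n, p = X.shape
        eta = X @ beta
        eta = eta - eta.max()  # guard overflow; cancels in all ratios
        w = np.exp(eta)
        wx = X * w[:, None]
        wxx = X[:, :, None] * X[:, None, :] * w[:, None, None]
        # suffix sums: S*[i] aggregates the risk set {j : t_j >= t_i}
        S0 = np.cumsum(w[::-1])[::-1]
        S1 = np.cumsum(wx[::-1], axis=0)[::-1]
        S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

        starts = np.r_[0, np.nonzero(np.diff(t))[0] + 1]  # unique-time blocks
        ew = w * e
        d = np.add.reduceat(e.astype(float), starts).astype(int)
        keep = d > 0
        starts_k, d_k = starts[keep], d[keep]
        td0 = np.add.reduceat(ew, starts)[keep]
        td1 = np.add.reduceat(wx * e[:, None], starts, axis=0)[keep]
        td2 = np.add.reduceat(wxx * e[:, None, None], starts, axis=0)[keep]

        ev = e == 1
        ll = float(eta[ev].sum())
        grad = X[ev].sum(axis=0)

        # expand each event-time block to its d tie ranks (Efron fractions)
        reps = np.repeat(np.arange(len(d_k)), d_k)
        k_rank = np.arange(d_k.sum()) - np.repeat(np.r_[0, np.cumsum(d_k)[:-1]], d_k)
        frac = k_rank / d_k[reps] if ties == "efron" else np.zeros(len(reps))
        r0 = S0[starts_k][reps] - frac * td0[reps]
        r1 = S1[starts_k][reps] - frac[:, None] * td1[reps]
        r2 = S2[starts_k][reps] - frac[:, None, None] * td2[reps]

        ll -= float(np.log(r0).sum())
        a = r1 / r0[:, None]
        grad -= a.sum(axis=0)
        hess = -((r2 / r0[:, None, None]).sum(axis=0) - np.einsum("mi,mj->ij", a, a))
        return ll, grad, hess

    def fit(
        self,
        ties: Literal["efron", "breslow"] = "efron",
        tol: float = 1e-10,
        max_iter: int = 100,
    ) -> "CoxResults":
        """Maximize the partial likelihood by Newton-Raphson.

        Step-halving is applied when a full Newton step decreases the
        log-likelihood.  Monotone-likelihood / separation problems are
        flagged on the results object rather than raised.
        """
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        p = self.exog.shape[1]
        beta = np.zeros(p)
        ll_old: float | None = None
        converged = False
        flags: list[str] = []
        for _ in range(max_iter):
            ll, grad, hess = self._loglike_grad_hess(beta, ties)
            if ll_old is not None and abs(ll - ll_old) < tol and np.max(np.abs(grad)) < 1e-7:
                converged = True
                break
            ll_old = ll
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError:
                flags.append("singular information matrix")
                break
            # step-halve until the likelihood does not decrease
            scale = 1.0
            for _ in range(30):
                ll_new, _, _ = self._loglike_grad_hess(beta + scale * step, ties)
                if ll_new >= ll - 1e-12:
                    break
                scale /= 2.0
            beta = beta + scale * step
        if not converged:
            flags.append("did not converge")
        if np.any(np.abs(beta) > 20):
            flags.append("monotone likelihood suspected (|beta| > 20): possible perfect separation")
        ll, grad, hess = self._loglike_grad_hess(beta, ties)
        try:
            cov = np.linalg.inv(-hess)
            se = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            cov = np.full((p, p), np.nan)
            se = np.full(p, np.nan)
            flags.append("covariance not invertible")
        return CoxResults(
            model=self,
            params=beta,
            bse=se,
            cov_params=cov,
            llf=float(ll),
            ties=ties,
            converged=converged,
            flags=flags,
        )


@dataclass
class CoxResults:
    """Fitted Cox model: coefficients, hazard ratios, Wald inference."""

    model: CoxPH
    params: np.ndarray
    bse: np.ndarray
    cov_params: np.ndarray
    llf: float
    ties: str
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    @property
    def zvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> np.ndarray:
        return 2 * stats.norm.sf(np.abs(self.zvalues))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        """Wald CI for the hazard ratios, shape (p, 2)."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = np.exp(self.params - z * self.bse)
        hi = np.exp(self.params + z * self.bse)
        return np.column_stack([lo, hi])

    def summary(self, alpha: float = 0.05) -> pd.DataFrame:
        """Coefficient table in the shape prognostic-factor papers print."""
        ci = self.conf_int(alpha)
        return pd.DataFrame(
            {
                "coef": self.params,
                "HR": self.hazard_ratios,
                f"HR {100*(1-alpha):.0f}% CI low": ci[:, 0],
                f"HR {100*(1-alpha):.0f}% CI high": ci[:, 1],
                "se(coef)": self.bse,
                "z": self.zvalues,
                "p": self.pvalues,
            },
            index=self.model.names,
        )

    def __repr__(self) -> str:
        status = "converged" if self.converged else "NOT CONVERGED"
        return f"<CoxResults ({self.ties} ties, {status}, llf={self.llf:.3f})>\n" + self.summary().to_string()


# --------------------------------------------------------------------- ROC


@dataclass(frozen=True)
class RocCutoff:
    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    auc: float


def roc_best_cutoff(feature_values, binary_outcome) -> RocCutoff:
    """Optimal dichotomization threshold by Youden's J.

    Candidate thresholds are the midpoints between consecutive sorted
    unique feature values ("value > threshold" predicts the event).  Ties
    in J resolve to the lowest threshold.  AUC is the trapezoidal area
    under the empirical ROC curve (equivalently the Mann-Whitney
    probability of correct ranking).
    """
    x = np.asarray(feature_values, dtype=float)
    y = np.asarray(binary_outcome, dtype=int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature and outcome must be equal-length 1-D arrays")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    uniq = np.unique(x)
    cand = (uniq[:-1] + uniq[1:]) / 2.0 if len(uniq) > 1 else uniq
    best = None
    for thr in cand:  # ascending: first maximum = lowest threshold
        pred = x > thr
        sens = float((pred & (y == 1)).sum() / n_pos)
        spec = float((~pred & (y == 0)).sum() / n_neg)
        j = sens + spec - 1.0
        if best is None or j > best[0] + 1e-12:
            best = (j, thr, sens, spec)
    # trapezoidal AUC over the full empirical curve
    order = np.argsort(-x, kind="stable")
    tps = np.cumsum(y[order])
    fps = np.cumsum(1 - y[order])
    # collapse tied feature values to the last index of each tie block
    keep = np.r_[np.nonzero(np.diff(x[order]))[0], len(x) - 1]
    tpr = np.r_[0.0, tps[keep] / n_pos]
    fpr = np.r_[0.0, fps[keep] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    j, thr, sens, spec = best
    return RocCutoff(threshold=float(thr), sensitivity=sens, specificity=spec, youden_j=float(j), auc=auc)


# ----------------------------------------------------------- combined strata

COMBINED_GROUP_ORDER = ["lowMTV_CMR", "lowMTV_nonCMR", "highMTV_CMR", "highMTV_nonCMR"]


def combined_strata(mtv_value: float, mtv_cutoff: float, response: str | None) -> str | None:
    """Four-way baseline-burden x metabolic-response stratum.

    ``mtv_value > mtv_cutoff`` is the high-burden group (values exactly at
    the cutoff fall in the low group).  A missing response (e.g. death
    before the end-of-treatment scan) returns None; callers exclude those
    patients with a logged count.
    """
    if response is None or (isinstance(response, float) and np.isnan(response)):
        return None
    if response not in ("complete", "not_complete"):
        raise ValueError(f"response must be 'complete' or 'not_complete', got {response!r}")
    burden = "highMTV" if mtv_value > mtv_cutoff else "lowMTV"
    resp = "CMR" if response == "complete" else "nonCMR"
    return f"{burden}_{resp}"
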