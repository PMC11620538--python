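"""Total exposure→outcome effect and its sensitivity analyses.

Estimates the total effect γ (SD outcome per SD exposure) by OLS, supports
the change-in-estimate forward selection of covariates, fixed-effects
meta-analysis across cohorts with Cochran's Q heterogeneity test, and the
robustness value quantifying how strong an unmeasured confounder would have
to be to nullify the estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .containers import StudyFrame

log = logging.getLogger(__name__)


@dataclass
class TotalEffect:
    """OLS total effect of exposure on outcome with Wald t-based CI."""

    gamma: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    n: int
    df: int
    t: float

    def to_dict(self) -> dict:
        return {
            "gamma": self.gamma, "se": self.se, "ci_low": self.ci_low,
            "ci_high": self.ci_high, "p": self.p, "n": self.n, "df": self.df,
            "t": self.t,
        }


@dataclass
class MetaResult:
    """Inverse-variance fixed-effects pooled estimate with Cochran's Q."""

    estimates: np.ndarray
    ses: np.ndarray
    pooled: float
    pooled_se: float
    Q: float
    df_Q: int
    p_het: float

    def to_dict(self) -> dict:
        return {
            "pooled": self.pooled, "pooled_se": self.pooled_se, "Q": self.Q,
            "df_Q": self.df_Q, "p_het": self.p_het,
            "estimates": list(self.estimates), "ses": list(self.ses),
        }


def total_effect(
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    conf: float = 0.95,
) -> TotalEffect:
    """γ from OLS of outcome on exposure plus covariates.

    The CI uses t-distribution critical values on the residual df.
    """
    C = study.design_matrix(covariates)
    X = pd.concat([study.exposure.rename("__exposure__"), C], axis=1)
    X = sm.add_constant(X.astype(float), prepend=True)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(study.outcome.astype(float), X).fit()
    gamma = float(fit.params["__exposure__"])
    se = float(fit.bse["__exposure__"])
    df = int(fit.df_resid)
    tcrit = stats.t.ppf(0.5 + conf / 2, df)
    tval = gamma / se if se > 0 else math.inf
    p = 2 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else 0.0
    return TotalEffect(
        gamma=gamma, se=se, ci_low=gamma - tcrit * se, ci_high=gamma + tcrit * se,
        p=float(p), n=study.n, df=df, t=float(tval),
    )


def forward_select_covariates(
    study: StudyFrame,
    base: Sequence[str],
    candidates: Sequence[str],
    threshold: float = 0.10,
) -> list[str]:
    """Change-in-estimate forward selection.

    Starting from the base set, repeatedly add the candidate whose inclusion
    changes γ the most *relative to the current γ*; retain it iff the
    relative change exceeds ``threshold`` (default 10%). Ties break by
    covariate name; stops when no candidate qualifies.
    """
    selected = list(base)
    remaining = sorted(candidates)
    gamma_cur = total_effect(study, selected).gamma
    while remaining:
        changes = []
        for cand in remaining:
            g = total_effect(study, selected + [cand]).gamma
            if abs(gamma_cur) > 1e-12:
                rel = abs(g - gamma_cur) / abs(gamma_cur)
            else:
                log.warning("current gamma ~ 0; using absolute change for %s", cand)
                rel = abs(g - gamma_cur)
            changes.append((rel, cand))
        changes.sort(key=lambda rc: (-rc[0], rc[1]))
        best_rel, best = changes[0]
        if best_rel <= threshold:
            break
        selected.append(best)
        remaining.remove(best)
        gamma_cur = total_effect(study, selected).gamma
    return selected


def fixed_effects_meta(estimates, ses) -> MetaResult:
    """Inverse-variance fixed-effects pooling with Cochran's Q.

    Q = Σ w_i (b_i − pooled)², w_i = 1/se_i²; heterogeneity p from χ² with
    (groups − 1) df.
    """
    b = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if b.shape != se.shape or b.ndim != 1:
        raise ValueError("estimates and ses must be 1-d and conform")
    if len(b) < 2:
        raise ValueError("meta-analysis needs at least two groups")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * b) / np.sum(w))
    pooled_se = float(np.sqrt(1.0 / np.sum(w)))
    Q = float(np.sum(w * (b - pooled) ** 2))
    df_Q = len(b) - 1
    p_het = float(stats.chi2.sf(Q, df_Q))
    return MetaResult(b, se, pooled, pooled_se, Q, df_Q, p_het)


def robustness_value(t: float, df: int, q: float = 1.0) -> float:
    """Minimum confounder strength (partial R² with both exposure and
    outcome residuals) needed to reduce the estimate by fraction ``q``.

    Built from the partial Cohen's f of the exposure coefficient,
    f = q·|t|/√df, via RV = ½(√(f⁴ + 4f²) − f²); returned as a fraction in
    [0, 1).
    """
    if df <= 0:
        raise ValueError("df must be positive")
    f = q * abs(t) / math.sqrt(df)
    f2 = f * f
    return 0.5 * (math.sqrt(f2 * f2 + 4 * f2) - f2)


def cohort_meta(study: StudyFrame, covariates: Sequence[str] | None = None) -> MetaResult:
    """Per-cohort total effects pooled by fixed-effects meta-analysis.

    Cohort-constant covariates are dropped within each cohort fit.
    """
    ests, ses = [], []
    for g in sorted(study.cohort.unique()):
        sub = study.subset(study.sample_ids[study.cohort == g])
        covs = covariates if covariates is not None else list(sub.covariates.columns)
        usable = [c for c in covs if sub.covariates[c].nunique() > 1]
        te = total_effect(sub, usable)
        ests.append(te.gamma)
        ses.append(te.se)
    return fixed_effects_meta(ests, ses)
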