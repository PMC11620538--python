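"""High-dimensional mediation across early, intermediate, and late integration.

All three modes follow the product-of-coefficients logic: per-feature
exposure→mediator coefficients α by OLS, mediator→outcome coefficients β
from a penalized outcome model (exposure and covariates unpenalized), and
per-feature indirect effects α·β with distribution-of-the-product CIs and
percent of total effect mediated (100·α·β/γ).

* early — one lasso over the concatenated, preselected features, followed
  by a joint OLS refit of the selected set for debiased β and SEs;
* intermediate — one lasso whose penalty is scaled per omics layer
  (group-lasso-type shrinkage), multipliers tuned by cross-validation;
  β SEs by nonparametric bootstrap;
* late — the early procedure applied to each layer separately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .containers import MultiOmics, StudyFrame
from .exposure_outcome import TotalEffect, total_effect
from .prodclin import prodclin_ci

log = logging.getLogger(__name__)

MEDIATION_COLUMNS = [
    "layer", "feature_id", "alpha", "se_alpha", "beta", "se_beta",
    "indirect", "ci_low", "ci_high", "p", "fdr_q", "pct_te", "selected",
    "significant",
]

#: 5-point log-grid of per-layer penalty multipliers searched during tuning
MULTIPLIER_GRID = (0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class MediationResult:
    """Per-feature mediation table plus the total effect and fit metadata."""

    table: pd.DataFrame
    gamma: TotalEffect
    meta: dict = field(default_factory=dict)

    @property
    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]]

    @property
    def significant(self) -> pd.DataFrame:
        """Reported mediators: penalized-selected AND BH joint-significant."""
        return self.table[self.table["significant"]]


def _design(study: StudyFrame, covariates) -> np.ndarray:
    C = study.design_matrix(covariates).to_numpy(dtype=float)
    x = study.exposure.to_numpy(dtype=float)
    return np.column_stack([np.ones(study.n), x, C])


def _alpha_ols(M: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-feature exposure coefficient, SE, and two-sided p (exposure is
    column 1 of the design)."""
    n, k = D.shape
    DtD_inv = np.linalg.inv(D.T @ D)
    coef = DtD_inv @ (D.T @ M)
    resid = M - D @ coef
    sse = np.einsum("ij,ij->j", resid, resid)
    sigma2 = sse / (n - k)
    se = np.sqrt(sigma2 * DtD_inv[1, 1])
    alpha = coef[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, alpha / se, np.inf)
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return alpha, se, p


def _partial_out(D: np.ndarray, *mats):
    Q, _ = np.linalg.qr(D)
    return tuple(m - Q @ (Q.T @ m) for m in mats)


def _cv_lasso(Mres: np.ndarray, yres: np.ndarray, seed: int,
              rule: str = "1se") -> tuple[float, np.ndarray, float]:
    """Cross-validated lasso on residualized data.

    Returns (chosen lambda, coefficients at that lambda, min mean CV MSE).
    ``rule='1se'`` picks the largest lambda within one SE of the CV optimum
    (conservative, favors sparsity); ``'min'`` picks the CV optimum.
    """
    cv = KFold(n_splits=10, shuffle=True, random_state=seed)
    las = LassoCV(cv=cv, alphas=100, max_iter=50_000, tol=1e-6)
    las.fit(Mres, yres)
    mean_mse = las.mse_path_.mean(axis=1)
    i_min = int(np.argmin(mean_mse))
    if rule == "1se":
        se_min = las.mse_path_[i_min].std(ddof=1) / np.sqrt(las.mse_path_.shape[1])
        ok = np.where(mean_mse <= mean_mse[i_min] + se_min)[0]
        lam = float(las.alphas_[ok].max())  # alphas_ descending; max = sparsest
    else:
        lam = float(las.alphas_[i_min])
    fit = Lasso(alpha=lam, max_iter=50_000, tol=1e-6).fit(Mres, yres)
    return lam, fit.coef_.copy(), float(mean_mse[i_min])


def _joint_refit(y: np.ndarray, D: np.ndarray, Msel: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of outcome on selected features + exposure + covariates; returns
    the features' coefficients, SEs, and two-sided p-values."""
    Xfull = np.column_stack([Msel, D])
    n, k = Xfull.shape
    XtX_inv = np.linalg.pinv(Xfull.T @ Xfull)
    coef = XtX_inv @ (Xfull.T @ y)
    resid = y - Xfull @ coef
    sigma2 = float(resid @ resid) / (n - k)
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    m = Msel.shape[1]
    beta, se_b = coef[:m], se[:m]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se_b > 0, beta / se_b, np.inf)
    p = 2 * stats.t.sf(np.abs(t), n - k)
    return beta, se_b, p


def _assemble_table(
    feature_ids, layers, alpha, se_alpha, p_alpha, sel_mask,
    beta_sel, se_beta_sel, p_beta_sel, gamma: TotalEffect,
    conf: float, fdr: float, ci: bool = True,
) -> pd.DataFrame:
    p_feat = len(feature_ids)
    beta = np.zeros(p_feat)
    se_beta = np.full(p_feat, np.nan)
    p_beta = np.full(p_feat, np.nan)
    beta[sel_mask] = beta_sel
    se_beta[sel_mask] = se_beta_sel
    p_beta[sel_mask] = p_beta_sel

    indirect = alpha * beta
    ci_low = np.full(p_feat, np.nan)
    ci_high = np.full(p_feat, np.nan)
    for i in (np.where(sel_mask)[0] if ci else []):
        if se_alpha[i] > 0 and se_beta[i] > 0:
            ci_low[i], ci_high[i] = prodclin_ci(
                alpha[i], se_alpha[i], beta[i], se_beta[i], conf
            )
    p_joint = np.full(p_feat, np.nan)
    p_joint[sel_mask] = np.maximum(p_alpha[sel_mask], p_beta[sel_mask])
    fdr_q = np.full(p_feat, np.nan)
    if sel_mask.any():
        _, q, _, _ = multipletests(p_joint[sel_mask], method="fdr_bh")
        fdr_q[sel_mask] = q

    if abs(gamma.gamma) > 0:
        pct_te = 100.0 * indirect / gamma.gamma
    else:
        log.warning("total effect gamma = 0; %%TE undefined")
        pct_te = np.full(p_feat, np.nan)
    significant = sel_mask & np.where(np.isnan(fdr_q), False, fdr_q < fdr)
    return pd.DataFrame({
        "layer": layers, "feature_id": feature_ids,
        "alpha": alpha, "se_alpha": se_alpha,
        "beta": beta, "se_beta": se_beta,
        "indirect": indirect, "ci_low": ci_low, "ci_high": ci_high,
        "p": p_joint, "fdr_q": fdr_q, "pct_te": pct_te,
        "selected": sel_mask, "significant": significant,
    })[MEDIATION_COLUMNS]


def _split_layer_ids(columns) -> tuple[list, list]:
    layers, feats = [], []
    for c in columns:
        layer, sep, feat = str(c).partition(":")
        if sep:
            layers.append(layer)
            feats.append(feat)
        else:
            layers.append("layer")
            feats.append(str(c))
    return layers, feats


def mediate_early(
    omics: pd.DataFrame,
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    *,
    seed: int = 0,
    conf: float = 0.95,
    fdr: float = 0.05,
    gamma: TotalEffect | None = None,
    ci: bool = True,
) -> MediationResult:
    """Early-integration high-dimensional mediation on a concatenated,
    preselected feature matrix.

    Outcome model: lasso of outcome on all features with exposure and
    covariates unpenalized (profiled out exactly by partialling them out of
    outcome and features); the lasso penalty is chosen by 10-fold CV at the
    1-SE rule. Selected features are refit jointly by OLS for debiased β
    and SEs; per-feature p-values are joint-significance (max of the α and
    β marginal p-values) with Benjamini–Hochberg correction across the
    selected set.
    """
    if gamma is None:
        gamma = total_effect(study, covariates)
    M = omics.to_numpy(dtype=float)
    y = study.outcome.to_numpy(dtype=float)
    D = _design(study, covariates)
    alpha, se_alpha, p_alpha = _alpha_ols(M, D)
    Mres, yres = _partial_out(D, M, y)
    lam, coef, _ = _cv_lasso(Mres, yres, seed)
    sel = coef != 0
    if sel.any():
        beta_sel, se_beta_sel, p_beta_sel = _joint_refit(y, D, M[:, sel])
    else:
        beta_sel = se_beta_sel = p_beta_sel = np.empty(0)
    layers, feats = _split_layer_ids(omics.columns)
    table = _assemble_table(feats, layers, alpha, se_alpha, p_alpha, sel,
                            beta_sel, se_beta_sel, p_beta_sel, gamma, conf,
                            fdr, ci=ci)
    return MediationResult(table, gamma,
                           meta={"mode": "early", "lambda": lam, "seed": seed})


def _tune_multipliers(
    Mres: np.ndarray, yres: np.ndarray, layer_slices: Mapping[str, slice],
    seed: int, sweeps: int = 2,
) -> dict[str, float]:
    """Coordinate-wise search of per-layer penalty multipliers on the
    5-point log grid, minimizing 10-fold CV MSE (min rule during search)."""
    mult = {name: 1.0 for name in layer_slices}

    def cv_err(m: Mapping[str, float]) -> float:
        w = np.empty(Mres.shape[1])
        for name, sl in layer_slices.items():
            w[sl] = m[name]
        _, _, err = _cv_lasso(Mres / w, yres, seed, rule="min")
        return err

    best = cv_err(mult)
    for _ in range(sweeps):
        changed = False
        for name in layer_slices:
            for cand in MULTIPLIER_GRID:
                if cand == mult[name]:
                    continue
                trial = dict(mult, **{name: cand})
                err = cv_err(trial)
                if err < best - 1e-12:
                    best, mult, changed = err, trial, True
        if not changed:
            break
    return mult


def mediate_intermediate(
    omics: MultiOmics,
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    *,
    bootstrap_B: int = 200,
    seed: int = 0,
    multipliers: Mapping[str, float] | None = None,
    conf: float = 0.95,
    fdr: float = 0.05,
    gamma: TotalEffect | None = None,
) -> MediationResult:
    """Intermediate-integration mediation with layer-specific penalties.

    Three steps: (1) per-feature α by OLS; (2) one penalized outcome
    regression over all layers with a distinct penalty multiplier per layer
    (tuned by CV unless ``multipliers`` is given), exposure and covariates
    unpenalized; β SEs by nonparametric pairs bootstrap (``bootstrap_B``
    resamples); (3) indirect effects with distribution-of-the-product CIs.
    """
    if len(omics) < 2 and multipliers is None:
        log.info("single layer: intermediate integration reduces to early")
    if bootstrap_B < 50:
        log.warning("bootstrap_B=%d < 50; SEs will be unstable", bootstrap_B)
    if gamma is None:
        gamma = total_effect(study, covariates)

    usable = [name for name in omics if omics[name].shape[1] > 0]
    skipped = [name for name in omics if name not in usable]
    if skipped:
        log.info("skipping empty layers: %s", skipped)
    cat = omics.concat(usable)
    M = cat.to_numpy(dtype=float)
    y = study.outcome.to_numpy(dtype=float)
    D = _design(study, covariates)
    alpha, se_alpha, p_alpha = _alpha_ols(M, D)
    Mres, yres = _partial_out(D, M, y)

    slices, start = {}, 0
    for name in usable:
        p_l = omics[name].shape[1]
        slices[name] = slice(start, start + p_l)
        start += p_l

    if multipliers is None:
        multipliers = _tune_multipliers(Mres, yres, slices, seed)
    w = np.empty(M.shape[1])
    for name, sl in slices.items():
        w[sl] = multipliers[name]

    lam, coef_scaled, _ = _cv_lasso(Mres / w, yres, seed)
    beta_full = coef_scaled / w
    sel = beta_full != 0

    rng = np.random.default_rng(seed)
    n = study.n
    boot = np.zeros((bootstrap_B, M.shape[1]))
    for bix in range(bootstrap_B):
        idx = rng.integers(0, n, n)
        Db, Mb, yb = D[idx], M[idx], y[idx]
        Mb_r, yb_r = _partial_out(Db, Mb, yb)
        fit = Lasso(alpha=lam, max_iter=50_000, tol=1e-6).fit(Mb_r / w, yb_r)
        boot[bix] = fit.coef_ / w
    se_beta_all = boot.std(axis=0, ddof=1)

    se_beta_sel = se_beta_all[sel]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_beta_sel > 0, beta_full[sel] / se_beta_sel, np.inf)
    p_beta_sel = 2 * stats.norm.sf(np.abs(z))

    layers, feats = _split_layer_ids(cat.columns)
    table = _assemble_table(feats, layers, alpha, se_alpha, p_alpha, sel,
                            beta_full[sel], se_beta_sel, p_beta_sel,
                            gamma, conf, fdr)
    return MediationResult(table, gamma, meta={
        "mode": "intermediate", "lambda": lam,
        "multipliers": dict(multipliers), "bootstrap_B": bootstrap_B,
        "seed": seed,
    })


def mediate_late(
    omics: MultiOmics,
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    *,
    seed: int = 0,
    conf: float = 0.95,
    fdr: float = 0.05,
    gamma: TotalEffect | None = None,
) -> dict[str, MediationResult]:
    """Late integration: the early-integration procedure run independently
    per layer, with no cross-layer conditioning."""
    if gamma is None:
        gamma = total_effect(study, covariates)
    results: dict[str, MediationResult] = {}
    for name in omics:
        mat = omics[name].copy()
        mat.columns = [f"{name}:{c}" for c in mat.columns]
        results[name] = mediate_early(
            mat, study, covariates, seed=seed, conf=conf, fdr=fdr, gamma=gamma
        )
        results[name].meta["mode"] = "late"
    return results


def combine_late(results: Mapping[str, MediationResult]) -> pd.DataFrame:
    """Stack per-layer mediation tables from :func:`mediate_late`."""
    if not results:
        return pd.DataFrame(columns=MEDIATION_COLUMNS)
    return pd.concat([r.table for r in results.values()], ignore_index=True)
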