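"""Mediation with latent factors.

Dimensionality reduction first — per-layer or concatenated PCA keeping the
smallest leading component set explaining more than a variance threshold
(default 80%), or a joint-and-individual decomposition that splits
multi-layer variance into a shared low-rank part, layer-specific low-rank
parts, and residual (ranks selected by a permutation test) — then
component-level mediation with the penalized outcome model, and Pearson
feature–component correlations for downstream pathway interpretation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import MultiOmics, StudyFrame
from .exposure_outcome import TotalEffect, total_effect
from .hdmed import mediate_early

log = logging.getLogger(__name__)

JOINT = "joint"


@dataclass
class FactorModel:
    """Scores and loadings of joint and layer-individual variance components.

    ``scores`` is samples × components; each component's ``source`` is either
    ``"joint"`` or a layer name, and ``explained_variance`` is the fraction
    of (its source's) total variance it carries. For joint/individual
    decompositions, ``ranks`` records (joint rank, per-layer individual
    ranks) and ``converged`` whether the alternating fit converged.
    """

    scores: pd.DataFrame
    loadings: dict[str, pd.DataFrame]
    source: list[str]
    explained_variance: np.ndarray
    ranks: dict = field(default_factory=dict)
    converged: bool = True
    meta: dict = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Make each component's largest-|loading| entry positive (signs of
    singular vectors are arbitrary; fixing them makes output reproducible)."""
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
            U[:, j] = -U[:, j]
    return U, V


def pca_factors(X: pd.DataFrame, var_threshold: float = 0.80,
                source: str = JOINT) -> FactorModel:
    """Principal components retaining the smallest leading set whose
    cumulative explained variance exceeds ``var_threshold``."""
    if not 0 < var_threshold <= 1:
        raise ValueError("var_threshold must be in (0, 1]")
    M = X.to_numpy(dtype=float)
    M = M - M.mean(axis=0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ValueError("matrix has zero variance")
    frac = s**2 / total
    cum = np.cumsum(frac)
    r = int(np.searchsorted(cum, var_threshold) + 1) if cum[-1] > var_threshold \
        else len(s)
    # ">80%": keep the first set strictly exceeding the threshold
    while r < len(s) and cum[r - 1] <= var_threshold:
        r += 1
    scores = U[:, :r] * s[:r]
    V = Vt[:r].T
    scores, V = _fix_signs(scores, V)
    names = [f"{source}_{j + 1}" for j in range(r)]
    return FactorModel(
        scores=pd.DataFrame(scores, index=X.index, columns=names),
        loadings={source: pd.DataFrame(V, index=X.columns, columns=names)},
        source=[source] * r,
        explained_variance=frac[:r],
        ranks={"joint": r if source == JOINT else 0},
        meta={"method": "pca", "var_threshold": var_threshold},
    )


def _svd_approx(M: np.ndarray, r: int):
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return U[:, :r], s[:r], Vt[:r]


def _perm_joint_rank(mats: list[np.ndarray], n_perm: int, rng) -> int:
    """Joint rank: observed singular values of the concatenated matrix vs.
    the 95th percentile of the largest singular value after permuting sample
    order independently within each layer (destroys cross-layer alignment,
    preserves within-layer structure)."""
    obs = np.linalg.svd(np.hstack(mats), compute_uv=False)
    null_max = np.empty(n_perm)
    n = mats[0].shape[0]
    for b in range(n_perm):
        perm = [m[rng.permutation(n)] for m in mats]
        null_max[b] = np.linalg.svd(np.hstack(perm), compute_uv=False)[0]
    thresh = np.quantile(null_max, 0.95)
    return int(np.sum(obs > thresh))


def _perm_layer_rank(X: np.ndarray, n_perm: int, rng) -> int:
    """Total within-layer signal rank: observed singular values vs. the
    null where every feature column is permuted independently across
    samples (destroys low-rank sample structure, preserves marginals).

    Under the joint/individual model a layer's signal rank is
    r_joint + r_individual, so individual ranks follow by subtracting the
    joint rank — testing the raw layer rather than the joint-fit residual
    avoids the rank-one leakage a subtracted *estimated* joint component
    leaves behind.
    """
    obs = np.linalg.svd(X, compute_uv=False)
    n, p = X.shape
    null_max = np.empty(n_perm)
    for b in range(n_perm):
        Xp = np.empty_like(X)
        for j in range(p):
            Xp[:, j] = X[rng.permutation(n), j]
        null_max[b] = np.linalg.svd(Xp, compute_uv=False)[0]
    thresh = np.quantile(null_max, 0.95)
    return int(np.sum(obs > thresh))


def jive_decompose(
    omics: MultiOmics,
    ranks: tuple[int, Sequence[int]] | str = "permutation",
    n_perm: int = 100,
    seed: int = 0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> FactorModel:
    """Joint-and-individual variance decomposition of multiple omics layers.

    Each column-centered layer is scaled to unit Frobenius norm so that
    high-dimensional layers do not dominate the joint structure. The model
    X_i = J_i + A_i + E_i is fit by alternating truncated SVDs: the joint
    part from a rank-r_J SVD of the concatenated (X − A), the individual
    parts from rank-r_i SVDs of each layer's residual projected orthogonal
    to the joint sample space. Ranks are either given explicitly as
    ``(r_J, [r_i ...])`` or selected by the permutation method.
    """
    if len(omics) < 2:
        raise ValueError("joint/individual decomposition needs >= 2 layers")
    names = omics.layer_names
    mats = []
    for name in names:
        M = omics[name].to_numpy(dtype=float)
        M = M - M.mean(axis=0)
        fro = np.linalg.norm(M)
        if fro <= 0:
            raise ValueError(f"layer {name!r} has zero variance")
        mats.append(M / fro)
    n = mats[0].shape[0]

    rng = np.random.default_rng(seed)
    if ranks == "permutation":
        r_joint = _perm_joint_rank(mats, n_perm, rng)
        r_ind = [max(0, _perm_layer_rank(m, n_perm, rng) - r_joint)
                 for m in mats]
    else:
        r_joint, r_ind = int(ranks[0]), [int(r) for r in ranks[1]]
        if len(r_ind) != len(names):
            raise ValueError("one individual rank per layer required")

    A = [np.zeros_like(m) for m in mats]
    J = [np.zeros_like(m) for m in mats]
    U = np.zeros((n, r_joint))
    sse_prev = np.inf
    converged = False
    objective_trace: list[float] = []
    splits = np.cumsum([m.shape[1] for m in mats])[:-1]
    for _ in range(max_iter):
        if r_joint > 0:
            stacked = np.hstack([m - a for m, a in zip(mats, A)])
            U, s, Vt = _svd_approx(stacked, r_joint)
            Jcat = U @ (np.diag(s) @ Vt)
            J = np.hsplit(Jcat, splits)
        for i, m in enumerate(mats):
            if r_ind[i] > 0:
                R = m - J[i]
                if r_joint > 0:
                    R = R - U @ (U.T @ R)
                Ui, si, Vti = _svd_approx(R, r_ind[i])
                A[i] = Ui @ (np.diag(si) @ Vti)
            else:
                A[i] = np.zeros_like(m)
        sse = sum(float(np.linalg.norm(m - j - a) ** 2)
                  for m, j, a in zip(mats, J, A))
        objective_trace.append(sse)
        if sse > sse_prev + 1e-10:
            log.warning("joint/individual objective increased; stopping")
            break
        if sse_prev - sse < tol * max(sse_prev, 1e-12):
            converged = True
            break
        sse_prev = sse
    if not converged and (r_joint > 0 or any(r_ind)):
        log.warning("decomposition did not converge in %d iterations", max_iter)
    if r_joint == 0 and not any(r_ind):
        converged = True

    scores_cols, source, expvar = [], [], []
    loadings: dict[str, pd.DataFrame] = {}
    score_names: list[str] = []
    total_ss = sum(float(np.linalg.norm(m) ** 2) for m in mats)

    if r_joint > 0:
        Jcat = np.hstack(J)
        Uj, sj, Vjt = _svd_approx(Jcat, r_joint)
        Sc = Uj * sj
        Vj = Vjt.T
        Sc, Vj = _fix_signs(Sc, Vj)
        names_j = [f"{JOINT}_{k + 1}" for k in range(r_joint)]
        scores_cols.append(Sc)
        score_names += names_j
        source += [JOINT] * r_joint
        expvar += list(sj**2 / total_ss)
        all_feats = [f"{nm}:{c}" for nm in names for c in omics[nm].columns]
        loadings[JOINT] = pd.DataFrame(Vj, index=all_feats, columns=names_j)

    for i, nm in enumerate(names):
        if r_ind[i] > 0:
            Ua, sa, Vat = _svd_approx(A[i], r_ind[i])
            Sc = Ua * sa
            Va = Vat.T
            Sc, Va = _fix_signs(Sc, Va)
            names_i = [f"{nm}_{k + 1}" for k in range(r_ind[i])]
            scores_cols.append(Sc)
            score_names += names_i
            source += [nm] * r_ind[i]
            layer_ss = float(np.linalg.norm(mats[i]) ** 2)
            expvar += list(sa**2 / layer_ss)
            loadings[nm] = pd.DataFrame(Va, index=omics[nm].columns,
                                        columns=names_i)

    scores = (np.hstack(scores_cols) if scores_cols
              else np.empty((n, 0)))
    return FactorModel(
        scores=pd.DataFrame(scores, index=omics.sample_ids, columns=score_names),
        loadings=loadings,
        source=source,
        explained_variance=np.asarray(expvar),
        ranks={"joint": r_joint,
               "individual": dict(zip(names, r_ind))},
        converged=converged,
        meta={"method": "jive", "n_perm": n_perm, "seed": seed,
              "objective_trace": objective_trace},
    )


COMPONENT_COLUMNS = [
    "component", "source", "alpha", "se_alpha", "beta", "se_beta",
    "indirect", "ci_low", "ci_high", "p", "fdr_q", "pct_te",
    "pct_te_scaled", "significant",
]


def mediate_components(
    factors: FactorModel,
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    *,
    seed: int = 0,
    fdr: float = 0.05,
    gamma: TotalEffect | None = None,
) -> pd.DataFrame:
    """Component-level mediation of the exposure→outcome association.

    Scores are standardized; α per component by OLS on the exposure, β from
    the penalized joint outcome fit over all components (same machinery as
    early-integration mediation); joint-significance p-values with BH
    correction; ``pct_te`` is 100·α·β/γ and ``pct_te_scaled`` rescales the
    significant components' mediated effects to sum to 100%.
    """
    if factors.n_components == 0:
        return pd.DataFrame(columns=COMPONENT_COLUMNS)
    if gamma is None:
        gamma = total_effect(study, covariates)
    Z = factors.scores.copy()
    Z = (Z - Z.mean()) / Z.std(ddof=1)
    res = mediate_early(Z, study, covariates, seed=seed, fdr=fdr, gamma=gamma)
    tbl = res.table.rename(columns={"feature_id": "component"})
    tbl["source"] = [factors.source[list(factors.scores.columns).index(c)]
                     for c in tbl["component"]]
    tbl["significant"] = tbl["fdr_q"].notna() & (tbl["fdr_q"] < fdr)
    sig = tbl["significant"]
    tbl["pct_te_scaled"] = np.nan
    denom = tbl.loc[sig, "indirect"].sum()
    if sig.any() and abs(denom) > 0:
        tbl.loc[sig, "pct_te_scaled"] = 100.0 * tbl.loc[sig, "indirect"] / denom
    return tbl[COMPONENT_COLUMNS]


def component_feature_correlations(
    factors: FactorModel, omics: MultiOmics
) -> pd.DataFrame:
    """Pearson r and two-sided p between every omics feature and every
    component.

    For a layer-individual component, features of *other* layers are flagged
    ``applicable=False`` with no correlation (those features played no part
    in that component). Constant features are flagged with undefined r.
    """
    S = factors.scores.to_numpy(dtype=float)
    n = S.shape[0]
    Sz = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
    rows = []
    comp_names = list(factors.scores.columns)
    for layer, mat in omics.items():
        M = mat.to_numpy(dtype=float)
        sd = M.std(axis=0, ddof=1)
        const = sd <= 0
        Mz = np.zeros_like(M)
        np.divide(M - M.mean(axis=0), np.where(const, 1.0, sd), out=Mz)
        R = Mz.T @ Sz / (n - 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = R * np.sqrt((n - 2) / np.clip(1 - R**2, 1e-300, None))
        P = 2 * stats.t.sf(np.abs(tstat), n - 2)
        for j, comp in enumerate(comp_names):
            src = factors.source[j]
            applicable = src == JOINT or src == layer
            for i, feat in enumerate(mat.columns):
                if not applicable:
                    rows.append((layer, feat, comp, np.nan, np.nan, False))
                elif const[i]:
                    rows.append((layer, feat, comp, np.nan, np.nan, False))
                else:
                    rows.append((layer, feat, comp, R[i, j], P[i, j], True))
    return pd.DataFrame(
        rows, columns=["layer", "feature_id", "component", "r", "p",
                       "applicable"]
    )
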