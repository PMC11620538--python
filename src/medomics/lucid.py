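"""Integrated/quasi-mediation via latent unknown clusters.

The generative model links exposure → latent cluster → omics and outcome:
cluster membership follows a multinomial-logistic model in the exposure,
omics features are independent normals given the cluster (cluster-specific
means, shared per-feature variance), and — in supervised fits — the
outcome is normal with a cluster-specific mean. The model is fit by EM;
each sample's posterior inclusion probabilities (PIPs) over clusters are
the central output. Rather than separating direct and indirect effects,
the exposure's entire effect is taken to flow through the clusters, which
define interpretable risk subgroups.

Three integration modes:

* early — one latent cluster variable over the concatenated layers;
* parallel — one latent cluster variable per layer, fit jointly (layers
  conditionally independent given their clusters; outcome additive in the
  per-layer cluster effects), enumerating all K^m configurations;
* serial — a chain of single-layer models where each model's non-reference
  PIPs become the "exposure" of the next, the last fit supervised.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans
from sklearn.linear_model import LogisticRegression

from .containers import MultiOmics, StudyFrame

log = logging.getLogger(__name__)

_LOG2PI = np.log(2.0 * np.pi)
_VAR_FLOOR = 1e-6


@dataclass
class LucidFit:
    """EM output for one latent-cluster model.

    ``delta`` holds exposure→cluster log-odds (rows = clusters, columns =
    intercept then exposure column(s)); the reference cluster's row is 0.
    ``eta`` is each cluster's outcome-mean difference vs. the reference
    (0 for the reference; all-zero when unsupervised). ``pips`` is the
    samples × clusters posterior membership matrix.
    """

    K: int
    delta: np.ndarray
    mu: pd.DataFrame
    sigma2: np.ndarray
    eta: np.ndarray
    outcome_ref: float
    sigma2_y: float
    pips: pd.DataFrame
    loglik_trace: np.ndarray
    converged: bool
    supervised: bool
    meta: dict = field(default_factory=dict)

    @property
    def assignments(self) -> np.ndarray:
        return self.pips.to_numpy().argmax(axis=1)


def _as_exposure_matrix(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    return x[:, None] if x.ndim == 1 else x


def _log_gauss(Z: np.ndarray, mu: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """log f(Z | cluster k) for each sample and cluster; diagonal normal."""
    n = Z.shape[0]
    K = mu.shape[0]
    out = np.empty((n, K))
    const = -0.5 * np.sum(_LOG2PI + np.log(sigma2))
    for k in range(K):
        d = (Z - mu[k]) / np.sqrt(sigma2)
        out[:, k] = const - 0.5 * np.einsum("ij,ij->i", d, d)
    return out


def _weighted_logistic(X: np.ndarray, resp: np.ndarray,
                       model: LogisticRegression | None
                       ) -> tuple[np.ndarray, np.ndarray, LogisticRegression]:
    """Weighted multinomial logistic M-step via sample expansion.

    Returns (log membership probs n×K, reference-coded coefficients K×(1+d),
    fitted model for warm-starting the next M-step).
    """
    n, d = X.shape
    K = resp.shape[1]
    Xrep = np.tile(X, (K, 1))
    yrep = np.repeat(np.arange(K), n)
    wrep = resp.T.reshape(-1)
    if model is None:
        model = LogisticRegression(C=np.inf, solver="lbfgs",
                                   max_iter=500, warm_start=True, tol=1e-8)
    model.fit(Xrep, yrep, sample_weight=np.maximum(wrep, 1e-12))
    logp_rep = model.predict_log_proba(X)
    coefs = np.column_stack([model.intercept_, model.coef_])
    if coefs.shape[0] == 1:  # binary: sklearn stores class-1 vs class-0
        W = np.vstack([np.zeros(d + 1), coefs[0]])
    else:
        W = coefs - coefs[0]
    return logp_rep, W, model


def _em_single(
    X: np.ndarray, Z: np.ndarray, y: np.ndarray | None, K: int,
    seed: int, max_iter: int, tol: float,
) -> dict:
    """One EM run from a k-means initialization; returns raw parameters."""
    n, p = Z.shape
    rng = np.random.default_rng(seed)
    km = KMeans(n_clusters=K, n_init=5, random_state=int(rng.integers(2**31)))
    labels = km.fit_predict(Z)
    resp = np.full((n, K), 0.05 / max(K - 1, 1))
    resp[np.arange(n), labels] = 0.95

    logistic_model = None
    mu = np.zeros((K, p))
    sigma2 = np.ones(p)
    m_y = np.zeros(K)
    s2_y = 1.0
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # M-step
        wsum = resp.sum(axis=0)
        if np.any(wsum < 1.0):
            return {"failed": True, "empty_cluster": True, "trace": trace}
        mu = (resp.T @ Z) / wsum[:, None]
        sq = np.zeros(p)
        for k in range(K):
            d = Z - mu[k]
            sq += resp[:, k] @ (d * d)
        sigma2 = np.maximum(sq / n, _VAR_FLOOR)
        if y is not None:
            m_y = (resp.T @ y) / wsum
            s2_y = max(
                sum(resp[:, k] @ (y - m_y[k]) ** 2 for k in range(K)) / n,
                _VAR_FLOOR,
            )
        logpi, W, logistic_model = _weighted_logistic(X, resp, logistic_model)

        # E-step + observed-data log-likelihood
        logjoint = logpi + _log_gauss(Z, mu, sigma2)
        if y is not None:
            logjoint += (-0.5 * (_LOG2PI + np.log(s2_y))
                         - 0.5 * (y[:, None] - m_y[None, :]) ** 2 / s2_y)
        ll_i = logsumexp(logjoint, axis=1)
        resp = np.exp(logjoint - ll_i[:, None])
        ll = float(ll_i.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(ll - trace[-2]) < tol * abs(trace[-2]):
            converged = True
            break
    return {
        "failed": False, "W": W, "mu": mu, "sigma2": sigma2,
        "m_y": m_y, "s2_y": s2_y, "resp": resp,
        "trace": np.asarray(trace), "converged": converged,
    }


def _finalize(raw: dict, K: int, y, feature_ids, sample_ids,
              supervised: bool, meta: dict) -> LucidFit:
    """Relabel clusters canonically and package the fit.

    Reference cluster = lowest outcome mean (supervised) or lowest
    first-feature mean (unsupervised); delta/eta reported relative to it.
    """
    if supervised:
        order = np.argsort(raw["m_y"], kind="stable")
    else:
        order = np.argsort(raw["mu"][:, 0], kind="stable")
    W = raw["W"][order]
    delta = W - W[0]
    mu = raw["mu"][order]
    resp = raw["resp"][:, order]
    if supervised:
        m_y = raw["m_y"][order]
        eta = m_y - m_y[0]
        y_ref = float(m_y[0])
    else:
        eta = np.zeros(K)
        y_ref = float(np.mean(y)) if y is not None else np.nan
    return LucidFit(
        K=K, delta=delta,
        mu=pd.DataFrame(mu, index=[f"cluster_{k}" for k in range(K)],
                        columns=feature_ids),
        sigma2=raw["sigma2"], eta=eta, outcome_ref=y_ref,
        sigma2_y=float(raw["s2_y"]) if supervised else np.nan,
        pips=pd.DataFrame(resp, index=sample_ids,
                          columns=[f"cluster_{k}" for k in range(K)]),
        loglik_trace=np.asarray(raw["trace"]), converged=raw["converged"],
        supervised=supervised, meta=meta,
    )


def lucid_early(
    study: StudyFrame,
    omics: pd.DataFrame,
    K: int = 2,
    supervised: bool = True,
    seed: int = 0,
    *,
    exposure=None,
    max_iter: int = 500,
    tol: float = 1e-6,
    n_restarts: int = 5,
) -> LucidFit:
    """Latent-cluster model on a (concatenated) omics matrix.

    EM with k-means initialization; ``n_restarts`` restarts keep the best
    final log-likelihood. ``exposure`` overrides the study exposure (used by
    serial chaining, where the previous model's PIPs act as the exposure).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Z = omics.to_numpy(dtype=float)
    y = study.outcome.to_numpy(dtype=float) if supervised else None
    X = _as_exposure_matrix(
        study.exposure.to_numpy(dtype=float) if exposure is None else exposure
    )
    n, p = Z.shape
    ids = omics.columns
    meta = {"mode": "early", "seed": seed}

    if K == 1:
        mu = Z.mean(axis=0, keepdims=True)
        sigma2 = np.maximum(Z.var(axis=0), _VAR_FLOOR)
        ll = float(_log_gauss(Z, mu, sigma2).sum())
        if y is not None:
            s2y = max(float(np.var(y)), _VAR_FLOOR)
            ll += float(np.sum(-0.5 * (_LOG2PI + np.log(s2y))
                               - 0.5 * (y - y.mean()) ** 2 / s2y))
        else:
            s2y = np.nan
        return LucidFit(
            K=1, delta=np.zeros((1, X.shape[1] + 1)),
            mu=pd.DataFrame(mu, index=["cluster_0"], columns=ids),
            sigma2=sigma2,
            eta=np.zeros(1),
            outcome_ref=float(study.outcome.mean()),
            sigma2_y=s2y,
            pips=pd.DataFrame(np.ones((n, 1)), index=study.sample_ids,
                              columns=["cluster_0"]),
            loglik_trace=np.asarray([ll]), converged=True,
            supervised=supervised, meta=meta,
        )

    best = None
    failures = 0
    for r in range(n_restarts + 5):
        raw = _em_single(X, Z, y, K, seed + 1000 * r, max_iter, tol)
        if raw.get("failed"):
            failures += 1
            if failures > 5:
                raise RuntimeError(
                    f"EM failed: empty cluster after {failures} restarts "
                    f"(n={n}, p={p}, K={K})"
                )
            continue
        if best is None or raw["trace"][-1] > best["trace"][-1]:
            best = raw
        if r + 1 - failures >= n_restarts:
            break
    if best is None:
        raise RuntimeError("EM produced no successful run")
    return _finalize(best, K, study.outcome.to_numpy(dtype=float), ids,
                     study.sample_ids, supervised, meta)


@dataclass
class ParallelLucid:
    """Joint fit of one latent cluster variable per layer."""

    fits: dict[str, LucidFit]
    subgroups: pd.DataFrame
    config_posteriors: pd.DataFrame
    loglik_trace: np.ndarray
    converged: bool


def _config_design(configs: list[tuple[int, ...]], Ks: list[int]) -> np.ndarray:
    """Outcome design per configuration: intercept + per-layer non-reference
    cluster indicators (additive main effects)."""
    q = 1 + sum(K - 1 for K in Ks)
    D = np.zeros((len(configs), q))
    D[:, 0] = 1.0
    for c, cfg in enumerate(configs):
        col = 1
        for l, K in enumerate(Ks):
            for k in range(1, K):
                if cfg[l] == k:
                    D[c, col] = 1.0
                col += 1
    return D


def lucid_parallel(
    study: StudyFrame,
    layers: MultiOmics,
    K_per_layer: int = 2,
    seed: int = 0,
    *,
    supervised: bool = True,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ParallelLucid:
    """Parallel (intermediate-integration) latent-cluster model.

    One latent cluster variable per layer, assumed independent across layers
    given the exposure; the outcome is additive in the per-layer cluster
    effects. The E-step enumerates all K^m cluster configurations. With one
    layer this reduces exactly to :func:`lucid_early`.
    """
    names = layers.layer_names
    m = len(names)
    K = K_per_layer
    if K ** m > 1024:
        raise ValueError(
            f"{K}^{m} = {K**m} configurations; use serial integration instead"
        )
    if m == 1:
        fit = lucid_early(study, layers[names[0]], K=K, supervised=supervised,
                          seed=seed)
        assign = fit.assignments
        sub = _subgroup_table({names[0]: fit}, study,
                              pd.DataFrame({names[0]: assign},
                                           index=study.sample_ids))
        return ParallelLucid({names[0]: fit}, sub, fit.pips,
                             fit.loglik_trace, fit.converged)

    X = _as_exposure_matrix(study.exposure.to_numpy(dtype=float))
    y = study.outcome.to_numpy(dtype=float) if supervised else None
    n = study.n
    Zs = [layers[nm].to_numpy(dtype=float) for nm in names]
    Ks = [K] * m
    configs = list(itertools.product(*[range(K) for _ in range(m)]))
    Dcfg = _config_design(configs, Ks)
    cfg_idx = np.asarray(configs)  # (n_cfg, m)

    rng = np.random.default_rng(seed)
    resp_l = []
    for Z in Zs:
        km = KMeans(n_clusters=K, n_init=5,
                    random_state=int(rng.integers(2**31)))
        lab = km.fit_predict(Z)
        r = np.full((n, K), 0.05 / (K - 1))
        r[np.arange(n), lab] = 0.95
        resp_l.append(r)

    logistic_models: list = [None] * m
    mus = [np.zeros((K, Z.shape[1])) for Z in Zs]
    sig2s = [np.ones(Z.shape[1]) for Z in Zs]
    theta = np.zeros(Dcfg.shape[1])
    s2_y = 1.0
    trace: list[float] = []
    converged = False
    gamma_cfg = None
    for _ in range(max_iter):
        # M-step per layer from marginal responsibilities
        logpis = []
        for l in range(m):
            wsum = resp_l[l].sum(axis=0)
            if np.any(wsum < 1.0):
                raise RuntimeError(f"empty cluster in layer {names[l]!r}")
            mus[l] = (resp_l[l].T @ Zs[l]) / wsum[:, None]
            sq = np.zeros(Zs[l].shape[1])
            for k in range(K):
                d = Zs[l] - mus[l][k]
                sq += resp_l[l][:, k] @ (d * d)
            sig2s[l] = np.maximum(sq / n, _VAR_FLOOR)
            logpi, _, logistic_models[l] = _weighted_logistic(
                X, resp_l[l], logistic_models[l]
            )
            logpis.append(logpi)
        if y is not None and gamma_cfg is not None:
            wc = gamma_cfg.sum(axis=0)
            A = Dcfg.T @ (wc[:, None] * Dcfg)
            rhs = Dcfg.T @ (gamma_cfg.T @ y)
            theta = np.linalg.solve(A + 1e-10 * np.eye(len(theta)), rhs)
            mu_y_cfg = Dcfg @ theta
            s2_y = max(
                float(np.sum(gamma_cfg * (y[:, None] - mu_y_cfg[None, :]) ** 2)) / n,
                _VAR_FLOOR,
            )
        elif y is not None:
            theta[0] = float(np.mean(y))
            s2_y = max(float(np.var(y)), _VAR_FLOOR)

        # E-step over configurations
        layer_ll = [logpis[l] + _log_gauss(Zs[l], mus[l], sig2s[l])
                    for l in range(m)]
        logjoint = np.zeros((n, len(configs)))
        for l in range(m):
            logjoint += layer_ll[l][:, cfg_idx[:, l]]
        if y is not None:
            mu_y_cfg = Dcfg @ theta
            logjoint += (-0.5 * (_LOG2PI + np.log(s2_y))
                         - 0.5 * (y[:, None] - mu_y_cfg[None, :]) ** 2 / s2_y)
        ll_i = logsumexp(logjoint, axis=1)
        gamma_cfg = np.exp(logjoint - ll_i[:, None])
        for l in range(m):
            r = np.zeros((n, K))
            for k in range(K):
                r[:, k] = gamma_cfg[:, cfg_idx[:, l] == k].sum(axis=1)
            resp_l[l] = r
        ll = float(ll_i.sum())
        trace.append(ll)
        if len(trace) > 1 and abs(ll - trace[-2]) < tol * abs(trace[-2]):
            converged = True
            break

    # package per-layer fits with canonical labels
    fits: dict[str, LucidFit] = {}
    eta_by_layer = []
    col = 1
    for l, nm in enumerate(names):
        eta_full = np.concatenate([[0.0], theta[col:col + K - 1]]) \
            if y is not None else np.zeros(K)
        col += K - 1
        _, W, _ = _weighted_logistic(X, resp_l[l], logistic_models[l])
        raw = {
            "W": W, "mu": mus[l], "sigma2": sig2s[l],
            "m_y": eta_full, "s2_y": s2_y, "resp": resp_l[l],
            "trace": np.asarray(trace), "converged": converged,
        }
        fit = _finalize(raw, K, study.outcome.to_numpy(dtype=float),
                        layers[nm].columns, study.sample_ids,
                        supervised=y is not None,
                        meta={"mode": "parallel", "layer": nm, "seed": seed})
        fit.sigma2_y = float(s2_y) if y is not None else np.nan
        fits[nm] = fit
        eta_by_layer.append(fit.eta)

    assign = pd.DataFrame(
        {nm: fits[nm].assignments for nm in names}, index=study.sample_ids
    )
    sub = _subgroup_table(fits, study, assign)
    cfg_names = ["-".join(str(k) for k in cfg) for cfg in configs]
    return ParallelLucid(
        fits, sub,
        pd.DataFrame(gamma_cfg, index=study.sample_ids, columns=cfg_names),
        np.asarray(trace), converged,
    )


def _subgroup_table(fits: dict[str, LucidFit], study: StudyFrame,
                    assign: pd.DataFrame) -> pd.DataFrame:
    """Per-configuration sample counts, mean exposure/outcome, and the
    modal (cluster-mean) omics profile handle."""
    names = list(assign.columns)
    Ks = [fits[nm].K for nm in names]
    rows = []
    for cfg in itertools.product(*[range(K) for K in Ks]):
        mask = np.ones(len(assign), dtype=bool)
        for nm, k in zip(names, cfg):
            mask &= assign[nm].to_numpy() == k
        rows.append({
            "configuration": "-".join(str(k) for k in cfg),
            **{f"cluster_{nm}": k for nm, k in zip(names, cfg)},
            "n_samples": int(mask.sum()),
            "mean_exposure": float(study.exposure[mask].mean()) if mask.any()
            else np.nan,
            "mean_outcome": float(study.outcome[mask].mean()) if mask.any()
            else np.nan,
        })
    return pd.DataFrame(rows)


def lucid_serial(
    study: StudyFrame,
    layers: MultiOmics,
    K: int = 2,
    seed: int = 0,
    *,
    layer_order: Sequence[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> list[LucidFit]:
    """Serial (late-integration) chain of latent-cluster models.

    The first model is unsupervised with the study exposure and the first
    layer; each subsequent model takes the previous model's non-reference
    PIP column(s) as its exposure; the final model is supervised (includes
    the outcome). The layer order encodes the biological hypothesis (e.g.
    methylation → miRNA → transcripts).
    """
    order = list(layer_order) if layer_order is not None else layers.layer_names
    if len(order) == 1:
        log.info("serial chain of length 1 is equivalent to early integration")
    fits: list[LucidFit] = []
    exposure = None
    for i, nm in enumerate(order):
        last = i == len(order) - 1
        fit = lucid_early(
            study, layers[nm], K=K, supervised=last,
            seed=seed + i, exposure=exposure, max_iter=max_iter, tol=tol,
        )
        fit.meta.update({"mode": "serial", "layer": nm, "position": i})
        fits.append(fit)
        exposure = fit.pips.to_numpy()[:, 1:]  # non-reference PIP columns
    return fits


def cluster_omics_profile(fit: LucidFit, omics: pd.DataFrame) -> pd.DataFrame:
    """PIP-weighted expected value of each feature within each cluster.

    Equals the fitted cluster means at convergence; recomputed from the data
    for auditability. Returns a long table (feature, cluster,
    expected_value).
    """
    Z = omics.to_numpy(dtype=float)
    resp = fit.pips.to_numpy()
    wsum = resp.sum(axis=0)
    prof = (resp.T @ Z) / wsum[:, None]
    rows = []
    for k, cname in enumerate(fit.pips.columns):
        for j, feat in enumerate(omics.columns):
            rows.append((feat, cname, prof[k, j]))
    return pd.DataFrame(rows, columns=["feature", "cluster", "expected_value"])
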