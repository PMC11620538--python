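"""Harmonization and standardization of exposure, outcome, and omics layers.

The pipeline all downstream stages assume is:

1. cord-blood exposure measurements harmonized to the maternal-blood scale
   (division by the cord:maternal ratio 1.7);
2. exposure and continuous outcome scaled to mean 0, SD 1 *within each
   cohort*, so cohort cannot confound either side of the mediation;
3. every omics feature replaced by its internally studentized residual from
   the regression on the covariates, re-orthogonalized against the design
   and rescaled to mean 0, SD 1.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import StudyFrame

log = logging.getLogger(__name__)

#: cord-blood : maternal-whole-blood total-mercury concentration ratio
CORD_TO_MATERNAL_RATIO = 1.7


def harmonize_cord_mercury(values, is_cord) -> np.ndarray:
    """Put cord-blood total mercury on the maternal whole-blood scale.

    Cord-blood entries are divided by 1.7; maternal entries pass through.

    Parameters
    ----------
    values : array-like of non-negative concentrations.
    is_cord : boolean array-like, True where the measurement is cord blood.
    """
    values = np.asarray(values, dtype=float)
    is_cord = np.asarray(is_cord, dtype=bool)
    if values.shape != is_cord.shape:
        raise ValueError("values and is_cord must have the same shape")
    if np.any(values < 0):
        raise ValueError("negative mercury concentration")
    out = values.copy()
    out[is_cord] = out[is_cord] / CORD_TO_MATERNAL_RATIO
    return out


def scale_within_groups(x, groups) -> np.ndarray:
    """Scale ``x`` to mean 0, SD 1 (n-1 denominator) within each group.

    Raises if any group is constant (zero within-group SD), naming the group.
    """
    x = pd.Series(np.asarray(x, dtype=float))
    groups = pd.Series(np.asarray(groups), index=x.index)
    for g, vals in x.groupby(groups):
        if len(vals) < 2 or vals.nunique() < 2:
            raise ValueError(f"group {g!r} is constant or has <2 values")
    means = x.groupby(groups).transform("mean")
    sds = x.groupby(groups).transform(lambda v: v.std(ddof=1))
    return ((x - means) / sds).to_numpy()


def _design_with_intercept(covariates: pd.DataFrame) -> np.ndarray:
    n = len(covariates)
    if covariates.shape[1] == 0:
        return np.ones((n, 1))
    return np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])


def residualize_features(
    layer: pd.DataFrame,
    covariates: pd.DataFrame,
    *,
    max_missing_frac: float = 0.05,
) -> pd.DataFrame:
    """Internally studentized residuals of each feature on the covariates.

    Each feature column is regressed on the covariate design (plus
    intercept); the residual is studentized as e_i / (s * sqrt(1 - h_ii)),
    re-orthogonalized against the design so no covariate correlation
    survives, and z-scored. Features with zero residual variance are dropped
    with a logged warning. Features with a missing fraction below
    ``max_missing_frac`` are mean-imputed first; more-missing features are
    dropped.
    """
    if not layer.index.equals(covariates.index):
        raise ValueError("layer and covariates must share the sample index")
    D = _design_with_intercept(covariates)
    n, k = D.shape
    if n <= k:
        raise ValueError(f"need n > {k} samples for {k}-column design")
    if np.linalg.matrix_rank(D) < k:
        raise ValueError("covariate design matrix is rank deficient")

    M = layer.to_numpy(dtype=float).copy()
    keep = np.ones(M.shape[1], dtype=bool)
    miss = np.isnan(M)
    if miss.any():
        frac = miss.mean(axis=0)
        too_missing = frac >= max_missing_frac
        if too_missing.any():
            dropped = list(layer.columns[too_missing])
            log.warning("dropping %d features with >=%.0f%% missing: %s",
                        len(dropped), 100 * max_missing_frac, dropped[:5])
            keep &= ~too_missing
        col_means = np.nanmean(np.where(miss, np.nan, M), axis=0)
        M = np.where(miss, col_means[None, :], M)

    Q, _ = np.linalg.qr(D)
    h = np.einsum("ij,ij->i", Q, Q)  # leverage
    proj = Q @ (Q.T @ M)
    E = M - proj
    sse = np.einsum("ij,ij->j", E, E)
    zero_var = sse <= 1e-12 * np.maximum(1.0, np.einsum("ij,ij->j", M, M))
    if (zero_var & keep).any():
        dropped = list(layer.columns[zero_var & keep])
        log.warning("dropping %d features with zero residual variance: %s",
                    len(dropped), dropped[:5])
        keep &= ~zero_var

    s = np.sqrt(sse / (n - k))
    with np.errstate(divide="ignore", invalid="ignore"):
        R = E / (s[None, :] * np.sqrt(np.maximum(1.0 - h, 1e-12))[:, None])
    # studentization is not a projection; one more pass restores exact
    # orthogonality to the covariates
    R = R - Q @ (Q.T @ R)
    R = R[:, keep]
    R = (R - R.mean(axis=0)) / R.std(axis=0, ddof=1)
    return pd.DataFrame(R, index=layer.index, columns=layer.columns[keep])


def prepare_study(
    study: StudyFrame,
    *,
    log_exposure: bool = False,
    cord_mask=None,
    scale_outcome: bool = True,
) -> StudyFrame:
    """Complete-case filter, optional cord harmonization and log transform,
    then within-cohort scaling of exposure (and continuous outcome).

    ``log_exposure`` applies log(x) before scaling — mercury distributions
    are right-skewed, but the transform is opt-in rather than automatic.
    """
    mask = (
        study.exposure.notna()
        & study.outcome.notna()
        & study.covariates.notna().all(axis=1)
        & study.cohort.notna()
    )
    dropped = int((~mask).sum())
    if dropped:
        log.info("complete-case filter dropped %d of %d samples", dropped, study.n)
    s = study.subset(study.sample_ids[mask])

    exp = s.exposure.to_numpy(dtype=float)
    if cord_mask is not None:
        exp = harmonize_cord_mercury(exp, np.asarray(cord_mask)[mask.to_numpy()])
    if log_exposure:
        if np.any(exp <= 0):
            raise ValueError("log transform requires strictly positive exposure")
        exp = np.log(exp)
    exp = scale_within_groups(exp, s.cohort.to_numpy())

    out = s.outcome.to_numpy(dtype=float)
    if scale_outcome:
        out = scale_within_groups(out, s.cohort.to_numpy())

    return StudyFrame(
        exposure=pd.Series(exp, index=s.sample_ids, name=study.exposure.name),
        outcome=pd.Series(out, index=s.sample_ids, name=study.outcome.name),
        covariates=s.covariates,
        cohort=s.cohort,
    )
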