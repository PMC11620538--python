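"""Meet-in-the-middle screening with a sure-independence-screening budget.

Features are ranked within each layer by |α·β|, where α is the
exposure→feature coefficient (adjusted for covariates) and β the
feature→outcome coefficient (adjusted for exposure and covariates); the
per-layer retention budget comes from the 2n/ln(n) sure-independence-
screening rule, rounded up to the nearest multiple of five and divided
across layers.
"""

from __future__ import annotations

import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MultiOmics, StudyFrame

log = logging.getLogger(__name__)


def sis_feature_budget(n: int, n_layers: int) -> tuple[int, int]:
    """Total and per-layer screening budgets from the 2n/ln(n) rule.

    The raw budget is rounded *up* to the nearest multiple of five, then
    divided across layers with a per-layer ceiling, so the returned total is
    per_layer · n_layers.

    >>> sis_feature_budget(420, 5)
    (140, 28)
    """
    if n_layers <= 0:
        raise ValueError("n_layers must be positive")
    if n < 8:
        raise ValueError("need n >= 8 for a meaningful budget")
    raw = 2.0 * n / math.log(n)
    total0 = int(math.ceil(raw / 5.0)) * 5
    per_layer = int(math.ceil(total0 / n_layers))
    return per_layer * n_layers, per_layer


def _alpha_beta(layer: np.ndarray, x: np.ndarray, y: np.ndarray,
                C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature α (feature ~ exposure + covs) and β (outcome ~ feature +
    exposure + covs), vectorized across features.

    α comes from the shared design [1, x, C]; β via Frisch–Waugh: partial
    [1, x, C] out of both outcome and feature, then the simple-regression
    slope of the residualized outcome on the residualized feature.
    """
    n = len(x)
    D = np.column_stack([np.ones(n), x, C])
    coef, *_ = np.linalg.lstsq(D, layer, rcond=None)
    alpha = coef[1]

    Q, _ = np.linalg.qr(D)
    ey = y - Q @ (Q.T @ y)
    EM = layer - Q @ (Q.T @ layer)
    denom = np.einsum("ij,ij->j", EM, EM)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (EM.T @ ey) / denom
    beta[denom <= 1e-12] = 0.0
    return alpha, beta


def meet_in_middle_rank(
    layer: pd.DataFrame,
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    k: int = 28,
    layer_name: str = "layer",
) -> pd.DataFrame:
    """Rank a layer's features by |α·β| and flag the top-k as retained.

    Ties in |α·β| break by feature id ascending. If ``k`` exceeds the layer
    width all features are retained (with a logged notice).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = study.exposure.to_numpy(dtype=float)
    y = study.outcome.to_numpy(dtype=float)
    C = study.design_matrix(covariates).to_numpy(dtype=float)
    alpha, beta = _alpha_beta(layer.to_numpy(dtype=float), x, y, C)
    product = alpha * beta

    tbl = pd.DataFrame({
        "layer": layer_name,
        "feature_id": layer.columns,
        "alpha": alpha,
        "beta": beta,
        "product": product,
    })
    order = tbl.assign(_abs=np.abs(product)).sort_values(
        ["_abs", "feature_id"], ascending=[False, True]
    ).index
    tbl["rank"] = 0
    tbl.loc[order, "rank"] = np.arange(1, len(tbl) + 1)
    if k > len(tbl):
        log.info("k=%d exceeds %d features in %s; retaining all", k, len(tbl),
                 layer_name)
    tbl["retained"] = tbl["rank"] <= k
    return tbl.sort_values("rank").reset_index(drop=True)


def screen_multiomics(
    omics: MultiOmics,
    study: StudyFrame,
    covariates: Sequence[str] | None = None,
    budget: int | None = None,
) -> tuple[pd.DataFrame, MultiOmics]:
    """Apply the meet-in-the-middle screen to every layer.

    ``budget`` overrides the per-layer SIS budget; by default it comes from
    :func:`sis_feature_budget` with the study's n. Returns the combined
    screen table and the retained (pre-selected) MultiOmics.
    """
    if budget is None:
        _, per_layer = sis_feature_budget(study.n, len(omics))
    else:
        per_layer = budget
    tables, keep = [], {}
    for name, mat in omics.items():
        tbl = meet_in_middle_rank(mat, study, covariates, k=per_layer,
                                  layer_name=name)
        tables.append(tbl)
        keep[name] = tbl.loc[tbl["retained"], "feature_id"].tolist()
    return pd.concat(tables, ignore_index=True), omics.subset_features(keep)
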