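"""Seeded generators of synthetic multi-omics exposure studies.

Real multi-cohort multi-omics data of the kind this package targets (five
layers spanning ~4×10^5 CpG sites down to tens of proteins, a continuous
exposure with cohort structure, sparse exposure→mediator→outcome paths)
are access-restricted; these generators reproduce the *statistical*
structure each analysis stage assumes at desk scale, with a truth table so
recovery can be scored. Default layer widths (500/300/100/36/177) preserve
the relative size ordering of a methylome / transcriptome / miRNA /
proteome / metabolome design while keeping full-pipeline runs fast.

All randomness flows from ``SimSpec.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import MultiOmics, StudyFrame

#: default scaled-down layer widths, largest to smallest assay
DEFAULT_LAYERS = (
    ("methylome", 500),
    ("transcriptome", 300),
    ("mirna", 100),
    ("proteome", 36),
    ("metabolome", 177),
)


@dataclass
class LayerSpec:
    name: str
    p: int
    block_size: int = 10
    rho: float = 0.3  # exchangeable within-block correlation
    n_active: int = 0


@dataclass
class SimSpec:
    """Parameters of a synthetic study.

    ``mode`` chooses the generative structure: sparse mediation paths
    ("mediation"), shared/individual latent factors ("latent_factor"), or
    exposure-dependent latent clusters ("latent_cluster").
    """

    n: int = 420
    n_cohorts: int = 4
    cohort_props: Sequence[float] | None = None
    layers: Sequence[LayerSpec] = field(
        default_factory=lambda: [LayerSpec(nm, p) for nm, p in DEFAULT_LAYERS]
    )
    alpha_effect: float = 0.4
    beta_effect: float = 0.4
    gamma_direct: float = 0.1
    noise_sd: float = 1.0
    cohort_shift_sd: float = 0.3  # SD of cohort-level exposure mean shifts
    mode: str = "mediation"
    seed: int = 0
    # latent-factor mode
    r_joint: int = 1
    r_individual: Sequence[int] | None = None
    snr: float = 10.0
    exposure_loading: float = 0.5
    outcome_loading: float = 0.5
    # latent-cluster mode
    K: int = 2
    delta_effect: float = 0.8  # exposure→cluster log-odds
    cluster_sep: float = 2.0   # between-cluster mean separation, in SD units
    eta_effect: float = 1.0    # per-layer cluster→outcome effect

    def validate(self) -> None:
        if self.n < 4:
            raise ValueError("n must be >= 4")
        if self.mode not in {"mediation", "latent_factor", "latent_cluster"}:
            raise ValueError(f"unknown mode {self.mode!r}")
        for ls in self.layers:
            if ls.n_active > ls.p:
                raise ValueError(f"layer {ls.name}: n_active > p")
            if not 0 <= ls.rho < 1:
                raise ValueError(f"layer {ls.name}: rho must be in [0, 1)")
        if self.cohort_props is not None:
            if len(self.cohort_props) != self.n_cohorts:
                raise ValueError("cohort_props length must equal n_cohorts")


def _cohorts_and_exposure(spec: SimSpec, rng) -> tuple[np.ndarray, np.ndarray]:
    props = (np.asarray(spec.cohort_props, dtype=float)
             if spec.cohort_props is not None
             else np.full(spec.n_cohorts, 1.0 / spec.n_cohorts))
    props = props / props.sum()
    counts = np.floor(props * spec.n).astype(int)
    counts[-1] = spec.n - counts[:-1].sum()
    cohorts = np.repeat(np.arange(spec.n_cohorts), counts)
    shifts = rng.normal(0.0, spec.cohort_shift_sd, spec.n_cohorts)
    exposure = rng.normal(shifts[cohorts], 1.0)
    return cohorts, exposure


def _block_noise(n: int, ls: LayerSpec, rng) -> np.ndarray:
    """Exchangeable block-correlated unit-variance noise."""
    E = rng.normal(size=(n, ls.p))
    if ls.rho <= 0:
        return E
    out = np.empty_like(E)
    a, b = np.sqrt(ls.rho), np.sqrt(1.0 - ls.rho)
    for start in range(0, ls.p, ls.block_size):
        stop = min(start + ls.block_size, ls.p)
        shared = rng.normal(size=n)[:, None]
        out[:, start:stop] = a * shared + b * E[:, start:stop]
    return out


def _frame(spec: SimSpec, cohorts, exposure, outcome) -> StudyFrame:
    ids = pd.Index([f"s{i:05d}" for i in range(spec.n)], name="sample_id")
    cohort_labels = pd.Series(
        [f"cohort{c}" for c in cohorts], index=ids, name="cohort"
    )
    return StudyFrame(
        exposure=pd.Series(exposure, index=ids, name="exposure"),
        outcome=pd.Series(outcome, index=ids, name="outcome"),
        covariates=pd.DataFrame(index=ids),
        cohort=cohort_labels,
    )


def _layers_df(spec: SimSpec, arrays: dict[str, np.ndarray],
               ids: pd.Index) -> MultiOmics:
    return MultiOmics({
        ls.name: pd.DataFrame(
            arrays[ls.name], index=ids,
            columns=[f"{ls.name}_f{j:04d}" for j in range(ls.p)],
        )
        for ls in spec.layers
    })


def simulate_mediation_study(spec: SimSpec
                             ) -> tuple[StudyFrame, MultiOmics, pd.DataFrame]:
    """Sparse-path mediation study.

    Active features follow M_j = α·X + block-correlated noise; the outcome
    is Y = γ_direct·X + Σ_j β·M_j + N(0, noise_sd²). The truth table lists
    each active feature with its true α and β.
    """
    spec.validate()
    if spec.mode != "mediation":
        raise ValueError("spec.mode must be 'mediation'")
    rng = np.random.default_rng(spec.seed)
    cohorts, x = _cohorts_and_exposure(spec, rng)

    arrays: dict[str, np.ndarray] = {}
    truth_rows = []
    mediator_sum = np.zeros(spec.n)
    for ls in spec.layers:
        M = _block_noise(spec.n, ls, rng)
        active = np.arange(ls.n_active)  # first features of the layer
        M[:, active] += spec.alpha_effect * x[:, None]
        mediator_sum += M[:, active].sum(axis=1) * spec.beta_effect
        arrays[ls.name] = M
        for j in active:
            truth_rows.append({
                "layer": ls.name, "feature_id": f"{ls.name}_f{j:04d}",
                "alpha": spec.alpha_effect, "beta": spec.beta_effect,
            })
    y = spec.gamma_direct * x + mediator_sum + rng.normal(0, spec.noise_sd,
                                                          spec.n)
    study = _frame(spec, cohorts, x, y)
    omics = _layers_df(spec, arrays, study.sample_ids)
    truth = pd.DataFrame(truth_rows,
                         columns=["layer", "feature_id", "alpha", "beta"])
    return study, omics, truth


def simulate_factor_study(spec: SimSpec
                          ) -> tuple[StudyFrame, MultiOmics, pd.DataFrame]:
    """Latent-factor study: joint factors shared across layers plus
    layer-individual factors.

    The exposure loads on the first joint factor and the outcome on the
    same factor, making it a latent mediator. Factor components are scaled
    so that the per-layer factor-to-noise energy ratio equals ``snr``.
    """
    spec.validate()
    if spec.mode != "latent_factor":
        raise ValueError("spec.mode must be 'latent_factor'")
    rng = np.random.default_rng(spec.seed)
    cohorts, x = _cohorts_and_exposure(spec, rng)
    r_ind = (list(spec.r_individual) if spec.r_individual is not None
             else [0] * len(spec.layers))

    FJ = rng.normal(size=(spec.n, spec.r_joint)) if spec.r_joint else \
        np.zeros((spec.n, 0))
    if spec.r_joint and spec.exposure_loading:
        FJ[:, 0] = spec.exposure_loading * x + \
            np.sqrt(max(1 - spec.exposure_loading**2, 0.01)) * FJ[:, 0]

    arrays: dict[str, np.ndarray] = {}
    truth_rows = []
    for ls, ri in zip(spec.layers, r_ind):
        E = rng.normal(size=(spec.n, ls.p))
        signal = np.zeros((spec.n, ls.p))
        if spec.r_joint:
            WJ = rng.normal(size=(spec.r_joint, ls.p))
            signal += FJ @ WJ
        if ri:
            FI = rng.normal(size=(spec.n, ri))
            WI = rng.normal(size=(ri, ls.p))
            signal += FI @ WI
        if spec.r_joint or ri:
            scale = np.sqrt(spec.snr) * np.linalg.norm(E) / \
                max(np.linalg.norm(signal), 1e-12)
            signal *= scale
        arrays[ls.name] = signal + E
        truth_rows.append({"layer": ls.name, "r_joint": spec.r_joint,
                           "r_individual": ri})
    y = (spec.outcome_loading * (FJ[:, 0] if spec.r_joint else 0.0)
         + rng.normal(0, spec.noise_sd, spec.n))
    study = _frame(spec, cohorts, x, y)
    omics = _layers_df(spec, arrays, study.sample_ids)
    return study, omics, pd.DataFrame(truth_rows)


def simulate_cluster_study(spec: SimSpec
                           ) -> tuple[StudyFrame, MultiOmics, pd.DataFrame]:
    """Latent-cluster study: per layer, cluster membership follows a
    logistic model in the exposure (log-odds ``delta_effect``); features
    are N(±cluster_sep/2, 1) by cluster; the outcome is additive in the
    per-layer cluster effects (``eta_effect`` each) plus noise.

    The truth table stores per-sample memberships; true delta, mu
    separation, and eta are in the table's ``attrs``.
    """
    spec.validate()
    if spec.mode != "latent_cluster":
        raise ValueError("spec.mode must be 'latent_cluster'")
    if spec.K != 2:
        raise ValueError("generator currently supports K = 2")
    rng = np.random.default_rng(spec.seed)
    cohorts, x = _cohorts_and_exposure(spec, rng)

    arrays: dict[str, np.ndarray] = {}
    memberships: dict[str, np.ndarray] = {}
    y = rng.normal(0, spec.noise_sd, spec.n)
    half = spec.cluster_sep / 2.0
    for ls in spec.layers:
        logit = spec.delta_effect * x
        pk = 1.0 / (1.0 + np.exp(-logit))
        L = (rng.uniform(size=spec.n) < pk).astype(int)
        mu = np.where(L[:, None] == 1, half, -half)
        arrays[ls.name] = mu + _block_noise(spec.n, ls, rng)
        memberships[ls.name] = L
        y += spec.eta_effect * L
    study = _frame(spec, cohorts, x, y)
    omics = _layers_df(spec, arrays, study.sample_ids)
    truth = pd.DataFrame(memberships, index=study.sample_ids)
    truth.attrs.update({
        "delta": spec.delta_effect,
        "mu": (-half, half),
        "eta": spec.eta_effect,
    })
    return study, omics, truth


def simulate(spec: SimSpec):
    """Dispatch on ``spec.mode``."""
    return {
        "mediation": simulate_mediation_study,
        "latent_factor": simulate_factor_study,
        "latent_cluster": simulate_cluster_study,
    }[spec.mode](spec)
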