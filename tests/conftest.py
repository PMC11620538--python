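import numpy as np
import pandas as pd
import pytest

from medomics import LayerSpec, SimSpec, StudyFrame, simulate


def make_study(n=200, seed=0, n_cohorts=2, beta_conf=0.0):
    """Small study with optional confounder: conf -> exposure and outcome."""
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"s{i}" for i in range(n)], name="sample_id")
    conf = rng.normal(size=n)
    x = 0.5 * beta_conf * conf + rng.normal(size=n)
    y = 0.3 * x + beta_conf * conf + rng.normal(size=n)
    cohort = pd.Series(
        [f"c{i % n_cohorts}" for i in range(n)], index=ids, name="cohort"
    )
    return StudyFrame(
        exposure=pd.Series(x, index=ids, name="exposure"),
        outcome=pd.Series(y, index=ids, name="outcome"),
        covariates=pd.DataFrame({"conf": conf}, index=ids),
        cohort=cohort,
    )


@pytest.fixture
def small_study():
    return make_study()


@pytest.fixture
def mediation_sim():
    spec = SimSpec(
        n=400,
        layers=[LayerSpec("l1", 60, n_active=5), LayerSpec("l2", 40)],
        mode="mediation",
        gamma_direct=0.1,
        seed=7,
    )
    return simulate(spec)


@pytest.fixture
def cluster_sim():
    spec = SimSpec(
        n=400,
        layers=[LayerSpec("a", 10, rho=0.0)],
        mode="latent_cluster",
        seed=11,
        delta_effect=0.8,
        cluster_sep=2.0,
    )
    return simulate(spec)
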