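import numpy as np
import pandas as pd
import pytest

from medomics import (
    LayerSpec,
    SimSpec,
    cluster_omics_profile,
    lucid_early,
    lucid_parallel,
    lucid_serial,
    simulate,
)


def _cluster_sim(seed, n=400, n_layers=1, p=10, delta=0.8, sep=2.0):
    spec = SimSpec(
        n=n, layers=[LayerSpec(f"L{i}", p, rho=0.0) for i in range(n_layers)],
        mode="latent_cluster", seed=seed, delta_effect=delta, cluster_sep=sep,
    )
    return simulate(spec)


def _accuracy(fit, truth_col):
    t = truth_col.to_numpy()
    a = fit.assignments
    return max((a == t).mean(), (a == 1 - t).mean())


class TestLucidEarly:
    def test_separated_clusters_recovered(self, cluster_sim):
        study, omics, truth = cluster_sim
        fit = lucid_early(study, omics["a"], K=2, seed=1)
        assert _accuracy(fit, truth["a"]) >= 0.95
        assert fit.converged

    def test_loglik_monotone_and_pips_normalized(self, cluster_sim):
        study, omics, _ = cluster_sim
        fit = lucid_early(study, omics["a"], K=2, seed=2)
        ll = fit.loglik_trace
        assert (np.diff(ll) >= -1e-8 * np.abs(ll[:-1])).all()
        np.testing.assert_allclose(fit.pips.sum(axis=1), 1.0, atol=1e-10)

    def test_reference_cluster_anchored(self, cluster_sim):
        study, omics, _ = cluster_sim
        fit = lucid_early(study, omics["a"], K=2, seed=3)
        assert fit.delta[0] == pytest.approx(np.zeros(2))
        assert fit.eta[0] == 0.0
        assert fit.eta[1] >= 0.0  # clusters ordered by outcome mean

    def test_delta_recovery_large_n(self):
        study, omics, _ = _cluster_sim(seed=21, n=2000)
        fit = lucid_early(study, omics["L0"], K=2, seed=4)
        assert fit.delta[1, 1] == pytest.approx(0.8, abs=0.25)

    def test_k1_degenerates_to_grand_means(self, cluster_sim):
        study, omics, _ = cluster_sim
        fit = lucid_early(study, omics["a"], K=1, seed=0)
        assert (fit.pips.to_numpy() == 1.0).all()
        assert fit.eta == pytest.approx([0.0])
        np.testing.assert_allclose(fit.mu.iloc[0],
                                   omics["a"].mean(), atol=1e-10)

    def test_seeded_determinism(self, cluster_sim):
        study, omics, _ = cluster_sim
        f1 = lucid_early(study, omics["a"], K=2, seed=5)
        f2 = lucid_early(study, omics["a"], K=2, seed=5)
        assert np.array_equal(f1.pips.to_numpy(), f2.pips.to_numpy())
        assert np.array_equal(f1.delta, f2.delta)

    def test_supervision_barely_changes_null_outcome_fit(self):
        # outcome independent of clusters: dropping the outcome term should
        # relabel few samples
        study, omics, _ = _cluster_sim(seed=33)
        study.outcome[:] = np.random.default_rng(0).normal(size=study.n)
        sup = lucid_early(study, omics["L0"], K=2, seed=1, supervised=True)
        uns = lucid_early(study, omics["L0"], K=2, seed=1, supervised=False)
        a, b = sup.assignments, uns.assignments
        frac = min((a != b).mean(), (a != 1 - b).mean())
        assert frac < 0.05


class TestLucidParallel:
    @pytest.mark.parametrize("n_layers,n_configs", [(3, 8), (5, 32)])
    def test_configuration_enumeration(self, n_layers, n_configs):
        study, omics, _ = _cluster_sim(seed=40, n=200, n_layers=n_layers, p=5)
        par = lucid_parallel(study, omics, K_per_layer=2, seed=0)
        assert par.config_posteriors.shape[1] == n_configs
        assert len(par.subgroups) == n_configs
        assert par.subgroups["n_samples"].sum() == study.n

    def test_single_layer_reproduces_early(self, cluster_sim):
        study, omics, _ = cluster_sim
        early = lucid_early(study, omics["a"], K=2, seed=6)
        par = lucid_parallel(study, omics, K_per_layer=2, seed=6)
        fit = par.fits["a"]
        assert np.array_equal(fit.pips.to_numpy(), early.pips.to_numpy())
        assert np.array_equal(fit.delta, early.delta)
        assert np.array_equal(fit.loglik_trace, early.loglik_trace)

    def test_signal_layer_has_larger_exposure_effect(self):
        hits = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            study, omics, truth = _cluster_sim(seed=seed, n=500, n_layers=2,
                                               p=6, delta=1.2)
            # break the exposure->cluster link in layer 2 by shuffling its
            # features across samples
            L1 = omics["L1"].to_numpy().copy()
            omics["L1"].iloc[:, :] = L1[rng.permutation(study.n)]
            par = lucid_parallel(study, omics, K_per_layer=2, seed=seed)
            hits += abs(par.fits["L0"].delta[1, 1]) > abs(
                par.fits["L1"].delta[1, 1])
        assert hits >= 7

    def test_loglik_monotone(self):
        study, omics, _ = _cluster_sim(seed=50, n=250, n_layers=2, p=6)
        par = lucid_parallel(study, omics, K_per_layer=2, seed=1)
        ll = par.loglik_trace
        assert (np.diff(ll) >= -1e-8 * np.abs(ll[:-1])).all()

    def test_too_many_layers_advises_serial(self):
        study, omics, _ = _cluster_sim(seed=51, n=100, n_layers=11, p=2)
        with pytest.raises(ValueError, match="serial"):
            lucid_parallel(study, omics, K_per_layer=2, seed=0)


class TestLucidSerial:
    def test_chain_runs_and_last_is_supervised(self):
        study, omics, _ = _cluster_sim(seed=60, n=300, n_layers=3, p=6)
        fits = lucid_serial(study, omics, K=2, seed=1)
        assert len(fits) == 3
        assert not fits[0].supervised and not fits[1].supervised
        assert fits[2].supervised

    def test_degenerate_pips_match_hard_labels(self):
        # a perfectly separable first layer yields 0/1 PIPs; chaining those
        # is equivalent to passing hard cluster labels
        study, omics, truth = _cluster_sim(seed=61, n=300, n_layers=2, p=8,
                                           sep=8.0)
        fits = lucid_serial(study, omics, K=2, seed=2)
        pips0 = fits[0].pips.to_numpy()[:, 1]
        assert np.minimum(pips0, 1 - pips0).max() < 1e-3
        hard = (pips0 > 0.5).astype(float)
        from medomics.lucid import lucid_early as le
        alt = le(study, omics["L1"], K=2, seed=3, exposure=hard)
        ref = le(study, omics["L1"], K=2, seed=3, exposure=pips0)
        np.testing.assert_allclose(alt.mu.to_numpy(), ref.mu.to_numpy(),
                                   atol=1e-3)

    def test_bitwise_reproducible(self):
        study, omics, _ = _cluster_sim(seed=62, n=200, n_layers=2, p=5)
        f1 = lucid_serial(study, omics, K=2, seed=9)
        f2 = lucid_serial(study, omics, K=2, seed=9)
        for a, b in zip(f1, f2):
            assert np.array_equal(a.pips.to_numpy(), b.pips.to_numpy())

    def test_null_chain_outcome_effect_small(self):
        # independent noise layers: the final supervised fit should find no
        # material outcome separation between clusters
        etas = []
        for seed in range(6):
            study, omics, _ = _cluster_sim(seed=70 + seed, n=300,
                                           n_layers=2, p=6, delta=0.0,
                                           sep=0.0)
            study.outcome[:] = np.random.default_rng(seed).normal(
                size=study.n)
            fits = lucid_serial(study, omics, K=2, seed=seed)
            etas.append(abs(fits[-1].eta[1]))
        # outcome SD is 1; cluster separation should be a small fraction
        assert np.median(etas) < 0.5


class TestClusterProfile:
    def test_hard_assignments_equal_group_means(self, cluster_sim):
        study, omics, truth = cluster_sim
        fit = lucid_early(study, omics["a"], K=2, seed=1)
        hard = fit.pips.round(0)
        fit.pips.iloc[:, :] = hard.to_numpy()
        prof = cluster_omics_profile(fit, omics["a"])
        labels = fit.assignments
        for k in (0, 1):
            grp = omics["a"].to_numpy()[labels == k].mean(axis=0)
            got = prof[prof["cluster"] == f"cluster_{k}"][
                "expected_value"].to_numpy()
            np.testing.assert_allclose(got, grp, atol=1e-10)

    def test_uniform_pips_give_grand_mean(self, cluster_sim):
        study, omics, _ = cluster_sim
        fit = lucid_early(study, omics["a"], K=2, seed=1)
        fit.pips.iloc[:, :] = 0.5
        prof = cluster_omics_profile(fit, omics["a"])
        grand = omics["a"].mean()
        for k in (0, 1):
            got = prof[prof["cluster"] == f"cluster_{k}"][
                "expected_value"].to_numpy()
            np.testing.assert_allclose(got, grand.to_numpy(), atol=1e-10)

    def test_planted_means_recovered_large_n(self):
        study, omics, _ = _cluster_sim(seed=80, n=2000)
        fit = lucid_early(study, omics["L0"], K=2, seed=1)
        prof = cluster_omics_profile(fit, omics["L0"])
        means = prof.groupby("cluster")["expected_value"].mean()
        lo, hi = means.min(), means.max()
        assert lo == pytest.approx(-1.0, abs=0.1)
        assert hi == pytest.approx(1.0, abs=0.1)
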