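import numpy as np
import pandas as pd
import pytest

from medomics import (
    LayerSpec,
    MultiOmics,
    SimSpec,
    StudyFrame,
    component_feature_correlations,
    jive_decompose,
    mediate_components,
    pca_factors,
    simulate,
)

LAYERS3 = [LayerSpec("a", 30, rho=0.0), LayerSpec("b", 25, rho=0.0),
           LayerSpec("c", 20, rho=0.0)]


def _factor_sim(seed, r_joint=1, r_individual=None, snr=10.0, n=150):
    spec = SimSpec(n=n, layers=LAYERS3, mode="latent_factor", seed=seed,
                   r_joint=r_joint, r_individual=r_individual, snr=snr)
    return simulate(spec)


class TestPcaFactors:
    def test_single_column(self):
        X = pd.DataFrame({"f": np.random.default_rng(0).normal(size=40)})
        fm = pca_factors(X)
        assert fm.n_components == 1
        assert fm.explained_variance[0] == pytest.approx(1.0)

    def test_rank_one_plus_tiny_noise(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(np.outer(rng.normal(size=60), rng.normal(size=8))
                         + 1e-3 * rng.normal(size=(60, 8)))
        assert pca_factors(X, 0.80).n_components == 1

    def test_two_planted_factors_70_30(self):
        rng = np.random.default_rng(2)
        n = 300
        f1, f2 = rng.normal(size=n), rng.normal(size=n)
        v1, v2 = rng.normal(size=12), rng.normal(size=12)
        v1 *= np.sqrt(0.7) / np.linalg.norm(v1)
        v2 *= np.sqrt(0.3) / np.linalg.norm(v2)
        X = pd.DataFrame(np.outer(f1, v1) + np.outer(f2, v2)
                         + 1e-3 * rng.normal(size=(n, 12)))
        assert pca_factors(X, 0.80).n_components == 2

    def test_duplicated_layers_share_leading_subspace(self):
        rng = np.random.default_rng(3)
        A = pd.DataFrame(rng.normal(size=(50, 6)),
                         index=[f"s{i}" for i in range(50)])
        both = MultiOmics({"x": A, "y": A.copy()})
        fm1 = pca_factors(A, 0.5)
        fm2 = pca_factors(both.concat(), 0.5)
        s1 = fm1.scores.to_numpy()[:, :1]
        s2 = fm2.scores.to_numpy()[:, :1]
        cos = abs(s1.T @ s2) / (np.linalg.norm(s1) * np.linalg.norm(s2))
        assert cos.item() > 1 - 1e-6

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            pca_factors(pd.DataFrame(np.eye(3)), 1.5)


class TestJive:
    def test_planted_joint_factor_ranks(self):
        _, omics, _ = _factor_sim(seed=100)
        fm = jive_decompose(omics, "permutation", n_perm=100, seed=0)
        assert fm.ranks["joint"] == 1
        assert all(v == 0 for v in fm.ranks["individual"].values())

    def test_independent_layers_no_joint(self):
        _, omics, _ = _factor_sim(seed=200, r_joint=0)
        fm = jive_decompose(omics, "permutation", n_perm=100, seed=0)
        assert fm.ranks["joint"] == 0

    def test_individual_structure_detected(self):
        _, omics, _ = _factor_sim(seed=300, r_joint=1, r_individual=[1, 0, 0])
        fm = jive_decompose(omics, "permutation", n_perm=100, seed=0)
        assert fm.ranks["joint"] == 1
        assert fm.ranks["individual"]["a"] >= 1

    def test_explicit_ranks_contracts(self):
        _, omics, _ = _factor_sim(seed=400, r_joint=1,
                                  r_individual=[1, 1, 0], snr=5)
        fm = jive_decompose(omics, ranks=(1, [1, 1, 0]), seed=0)
        # objective non-increasing
        obj = fm.meta["objective_trace"]
        assert all(b <= a + 1e-10 for a, b in zip(obj, obj[1:]))
        # joint scores orthogonal to each layer's individual scores
        Sj = fm.scores[[c for c, s in zip(fm.scores.columns, fm.source)
                        if s == "joint"]].to_numpy()
        for layer in ("a", "b"):
            Si = fm.scores[[c for c, s in zip(fm.scores.columns, fm.source)
                            if s == layer]].to_numpy()
            if Si.size:
                num = np.linalg.norm(Sj.T @ Si)
                den = np.linalg.norm(Sj) * np.linalg.norm(Si)
                assert num / den < 1e-6
        # scores columns mutually orthogonal within source
        G = Sj.T @ Sj
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(G).max()
        # explained variance fractions are sane
        assert (fm.explained_variance >= 0).all()
        assert (fm.explained_variance <= 1).all()

    def test_needs_two_layers(self):
        _, omics, _ = _factor_sim(seed=1)
        one = MultiOmics({"a": omics["a"]})
        with pytest.raises(ValueError):
            jive_decompose(one)


class TestMediateComponents:
    def _complete_mediation(self, seed=0, n=500):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(size=n)
        y = 0.5 * m + rng.normal(size=n)
        ids = pd.Index([f"s{i}" for i in range(n)])
        study = StudyFrame(
            exposure=pd.Series(x, index=ids),
            outcome=pd.Series(y, index=ids),
            covariates=pd.DataFrame(index=ids),
            cohort=pd.Series(["c"] * n, index=ids),
        )
        # components: the mediator plus exposure-independent noise
        scores = pd.DataFrame(
            {"joint_1": m, "joint_2": rng.normal(size=n),
             "joint_3": rng.normal(size=n)}, index=ids)
        from medomics.latentmed import FactorModel
        fm = FactorModel(scores=scores, loadings={}, source=["joint"] * 3,
                         explained_variance=np.array([0.5, 0.3, 0.2]))
        return study, fm

    def test_complete_mediation_component(self):
        study, fm = self._complete_mediation()
        tbl = mediate_components(fm, study, seed=0)
        row = tbl[tbl["component"] == "joint_1"].iloc[0]
        assert row["significant"]
        assert row["pct_te"] == pytest.approx(100.0, abs=25.0)

    def test_null_components_not_significant(self):
        flags = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 300
            x, y = rng.normal(size=n), rng.normal(size=n)
            ids = pd.Index([f"s{i}" for i in range(n)])
            study = StudyFrame(
                exposure=pd.Series(x, index=ids),
                outcome=pd.Series(y, index=ids),
                covariates=pd.DataFrame(index=ids),
                cohort=pd.Series(["c"] * n, index=ids),
            )
            scores = pd.DataFrame(rng.normal(size=(n, 4)), index=ids,
                                  columns=[f"joint_{j}" for j in range(4)])
            from medomics.latentmed import FactorModel
            fm = FactorModel(scores=scores, loadings={},
                             source=["joint"] * 4,
                             explained_variance=np.full(4, 0.25))
            tbl = mediate_components(fm, study, seed=seed)
            flags.append(int(tbl["significant"].sum()))
        assert sum(f == 0 for f in flags) >= 9

    def test_single_component_no_rescaling(self):
        study, fm = self._complete_mediation(seed=3)
        from medomics.latentmed import FactorModel
        one = FactorModel(scores=fm.scores[["joint_1"]], loadings={},
                          source=["joint"],
                          explained_variance=np.array([1.0]))
        tbl = mediate_components(one, study, seed=0)
        row = tbl.iloc[0]
        expected = 100.0 * row["alpha"] * row["beta"]
        from medomics import total_effect
        expected /= total_effect(study).gamma
        assert row["pct_te"] == pytest.approx(expected, rel=1e-10)
        if row["significant"]:
            assert row["pct_te_scaled"] == pytest.approx(100.0)

    def test_empty_factor_model(self, small_study):
        from medomics.latentmed import FactorModel
        fm = FactorModel(
            scores=pd.DataFrame(index=small_study.sample_ids),
            loadings={}, source=[], explained_variance=np.empty(0))
        assert mediate_components(fm, small_study).empty


class TestComponentFeatureCorrelations:
    def test_duplicated_feature_perfect_correlation(self):
        _, omics, _ = _factor_sim(seed=7)
        from medomics.latentmed import FactorModel
        feat = omics["a"].iloc[:, 0]
        fm = FactorModel(
            scores=pd.DataFrame({"joint_1": feat}),
            loadings={}, source=["joint"],
            explained_variance=np.array([1.0]))
        tbl = component_feature_correlations(fm, omics)
        row = tbl[(tbl["feature_id"] == feat.name) & (tbl["layer"] == "a")]
        assert row["r"].item() == pytest.approx(1.0, abs=1e-12)
        assert row["p"].item() < 1e-10

    def test_other_layer_flagged_for_individual_components(self):
        _, omics, _ = _factor_sim(seed=8, r_individual=[1, 0, 0])
        fm = jive_decompose(omics, ranks=(1, [1, 0, 0]), seed=0)
        tbl = component_feature_correlations(fm, omics)
        ind = tbl[tbl["component"] == "a_1"]
        assert not ind[ind["layer"] == "b"]["applicable"].any()
        assert ind[ind["layer"] == "a"]["applicable"].all()

    def test_planted_correlation_recovered(self):
        hits = 0
        n = 400
        for seed in range(10):
            rng = np.random.default_rng(seed)
            comp = rng.normal(size=n)
            feat = 0.5 * comp + np.sqrt(1 - 0.25) * rng.normal(size=n)
            ids = pd.Index([f"s{i}" for i in range(n)])
            omics = MultiOmics({"a": pd.DataFrame({"f": feat}, index=ids)})
            from medomics.latentmed import FactorModel
            fm = FactorModel(
                scores=pd.DataFrame({"joint_1": comp}, index=ids),
                loadings={}, source=["joint"],
                explained_variance=np.array([1.0]))
            r = component_feature_correlations(fm, omics)["r"].item()
            hits += 0.41 <= r <= 0.58
        assert hits >= 9
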