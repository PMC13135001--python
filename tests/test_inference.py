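import numpy as np
import pytest

import spatlc as sl
from spatlc.data_io import ValidationError
from spatlc.inference import _Posterior


class TestClassicLeeCarter:
    def test_rank_one_exact_recovery(self):
        rng = np.random.default_rng(0)
        A, T = 12, 8
        beta = rng.uniform(0.5, 1.5, A)
        beta /= beta.sum()
        kappa = rng.normal(size=T)
        kappa -= kappa.mean()
        alpha = rng.normal(-4, 1, A)
        lr = alpha[:, None] + beta[:, None] * kappa[None, :]
        a, b, k = sl.classic_lee_carter(lr)
        np.testing.assert_allclose(a, alpha, atol=1e-10)
        np.testing.assert_allclose(b, beta, atol=1e-10)
        np.testing.assert_allclose(k, kappa, atol=1e-10)

    def test_time_constant_matrix_gives_zero_kappa(self):
        lr = np.tile(np.array([[-3.0], [-5.0], [-7.0]]), (1, 6))
        a, b, k = sl.classic_lee_carter(lr)
        np.testing.assert_allclose(k, 0.0)
        np.testing.assert_allclose(a, [-3.0, -5.0, -7.0])

    def test_eckart_young_reconstruction_error(self):
        """Rank-1 fit error matches the optimum from an eigendecomposition oracle."""
        rng = np.random.default_rng(3)
        lr = rng.normal(-4, 1, size=(10, 7))
        a, b, k = sl.classic_lee_carter(lr)
        fit = a[:, None] + b[:, None] * k[None, :]
        err = np.linalg.norm(lr - fit)
        M = lr - lr.mean(axis=1, keepdims=True)
        evals = np.linalg.eigvalsh(M @ M.T)
        best = np.sqrt(max(evals.sum() - evals.max(), 0.0))
        assert abs(err - best) < 1e-10

    def test_constraints_of_output(self):
        rng = np.random.default_rng(4)
        _, b, k = sl.classic_lee_carter(rng.normal(size=(6, 5)))
        assert abs(b.sum() - 1.0) < 1e-12
        assert abs(k.sum()) < 1e-10

    def test_non_finite_input_rejected(self):
        lr = np.zeros((3, 4))
        lr[0, 0] = np.nan
        with pytest.raises(ValidationError):
            sl.classic_lee_carter(lr)


class TestNutsOnGaussian:
    def test_recovers_moments_of_correlated_gaussian(self):
        """Sanity: engine reproduces mean/cov of a 3-d Gaussian target."""
        cov = np.array([[1.0, 0.6, 0.0], [0.6, 2.0, 0.3], [0.0, 0.3, 0.5]])
        prec = np.linalg.inv(cov)
        mean = np.array([1.0, -2.0, 0.5])

        def logp_grad(x):
            d = x - mean
            return -0.5 * float(d @ prec @ d), -prec @ d

        rng = np.random.default_rng(11)
        draws, diag = sl.nuts_sample(logp_grad, np.zeros(3), 500, 3000, rng)
        assert diag["n_divergent"] == 0
        np.testing.assert_allclose(draws.mean(axis=0), mean, atol=0.12)
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.3)

    def test_determinism(self):
        def logp_grad(x):
            return -0.5 * float(x @ x), -x
        d1, _ = sl.nuts_sample(logp_grad, np.zeros(2), 100, 50, np.random.default_rng(5))
        d2, _ = sl.nuts_sample(logp_grad, np.zeros(2), 100, 50, np.random.default_rng(5))
        np.testing.assert_array_equal(d1, d2)


@pytest.fixture(scope="module")
def small_fit():
    cfg = sl.SimConfig(seed=21, n_provinces=6, n_regions=2, n_island_provinces=1,
                       max_age=8, n_years=4)
    graph, spec, truth, ds = sl.simulate(cfg)
    fc = sl.FitConfig(seed=3, draws=60, warmup=80, chains=2, target_accept=0.9)
    with pytest.warns(UserWarning):  # short chains trip the Rhat warning by design
        summ = sl.fit(ds, graph, spec, fc)
    return {"cfg": cfg, "graph": graph, "spec": spec, "truth": truth,
            "dataset": ds, "fit_config": fc, "summary": summ}


class TestFit:
    def test_summary_shapes(self, small_fit):
        s = small_fit["summary"]
        spec = small_fit["spec"]
        A = len(spec.age_values)
        assert s.mean("alpha").shape == (A,)
        assert s.mean("beta").shape == (A,)
        assert s.mean("kappa").shape == (len(spec.year_values),)
        assert s.mean("omega").shape == (6, spec.n_groups, 1)
        assert s.mean("beta_kappa").shape == (A, len(spec.year_values))
        assert s.mean("spatial_surface").shape == s.mean("omega").shape

    def test_quantiles_ordered(self, small_fit):
        s = small_fit["summary"]
        for name, blk in s.blocks.items():
            assert np.all(blk["q2.5"] <= blk["mean"] + 1e-12), name
            assert np.all(blk["mean"] <= blk["q97.5"] + 1e-12), name

    def test_draw_constraints_hold_in_summary(self, small_fit):
        s = small_fit["summary"]
        assert abs(s.mean("beta").sum() - 1.0) < 1e-8
        assert abs(s.mean("kappa").sum()) < 1e-8
        omega = s.mean("omega")
        for comp in small_fit["spec"].structure.components:
            if len(comp) > 1:
                idx = np.array(comp) - 1
                np.testing.assert_allclose(omega[idx].sum(axis=0), 0.0, atol=1e-8)

    def test_same_seed_bit_identical(self, small_fit):
        import warnings as W
        with W.catch_warnings():
            W.simplefilter("ignore")
            s2 = sl.fit(small_fit["dataset"], small_fit["graph"], small_fit["spec"],
                        small_fit["fit_config"])
        for name, blk in small_fit["summary"].blocks.items():
            for stat, arr in blk.items():
                np.testing.assert_array_equal(arr, s2.blocks[name][stat])

    def test_mismatched_graph_rejected(self, small_fit):
        bad = sl.AdjacencyGraph(4, {i: frozenset() for i in range(1, 5)})
        with pytest.raises(ValidationError, match="province"):
            sl.fit(small_fit["dataset"], bad, small_fit["spec"], small_fit["fit_config"])

    def test_convergence_warning_recorded(self, small_fit):
        # deliberately short chains: the Rhat check must speak up, not stay silent
        assert small_fit["summary"].warnings_
        assert "Rhat" in small_fit["summary"].warnings_[0]

    def test_period_split_single_period_reduces_to_fit(self, small_fit):
        import warnings as W
        with W.catch_warnings():
            W.simplefilter("ignore")
            s2 = sl.fit_period_split(small_fit["dataset"], small_fit["graph"],
                                     small_fit["spec"], small_fit["fit_config"])
        np.testing.assert_array_equal(s2.mean("kappa"), small_fit["summary"].mean("kappa"))
        np.testing.assert_array_equal(s2.mean("omega"), small_fit["summary"].mean("omega"))


class TestFitRelabelInvariance:
    def test_province_relabeling_equivariance_of_posterior_mode(self):
        """The fitted surface follows a relabeling of provinces (same seed)."""
        cfg = sl.SimConfig(seed=31, n_provinces=6, n_regions=2, n_island_provinces=0,
                           max_age=6, n_years=4)
        graph, spec, truth, ds = sl.simulate(cfg)
        post = _Posterior(ds, spec)
        x = post.initial_vector("map")
        om = post.state(x).omega()

        # relabel provinces by a rotation consistent with graph symmetry is hard
        # in general; instead check the *initialization* is permutation-stable:
        # permuting provinces of the dataset and graph permutes the latent mode.
        perm = np.array([3, 4, 5, 0, 1, 2])
        inv = np.argsort(perm)
        nbrs = {i + 1: frozenset(int(inv[j - 1]) + 1 for j in graph.neighbors[int(perm[i]) + 1])
                for i in range(6)}
        graph2 = sl.AdjacencyGraph(6, nbrs)
        region_of2 = {i + 1: ds.region_of[int(perm[i]) + 1] for i in range(6)}
        ds2 = sl.MortalityDataset(ds.deaths[:, :, perm], ds.exposures[:, :, perm],
                                  ds.age_values, ds.year_values, ds.province_ids,
                                  region_of2)
        spec2 = sl.ModelSpec(spec.grouping, spec.periods, sl.scaled_besag(graph2),
                             ds2.region_index(), ds2.age_values, spec.priors)
        post2 = _Posterior(ds2, spec2)
        om2 = post2.state(post2.initial_vector("map")).omega()
        np.testing.assert_allclose(om2, om[perm], atol=5e-3)


class TestFitConfigValidation:
    @pytest.mark.parametrize("kw", [{"draws": 0}, {"chains": 0}])
    def test_invalid(self, kw):
        with pytest.raises(ValidationError):
            sl.FitConfig(**kw)
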