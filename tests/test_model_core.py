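import numpy as np
import pytest
from scipy.special import gammaln
from scipy.optimize import brentq

import spatlc as sl
from spatlc.data_io import ValidationError
from spatlc.model_core import _structure_gammas


def _random_state(sim, seed, scale=0.5):
    """Perturb the simulated truth into a generic (unconstrained) state."""
    rng = np.random.default_rng(seed)
    st = sim["truth"].copy()
    st.alpha = st.alpha + scale * rng.normal(size=st.alpha.shape)
    st.beta = st.beta + scale * rng.normal(size=st.beta.shape) / len(st.beta)
    st.kappa = st.kappa + scale * rng.normal(size=st.kappa.shape)
    st.v = st.v + rng.normal(size=st.v.shape)
    st.u = st.u + 0.3 * rng.normal(size=st.u.shape)
    st.z = st.z + 0.05 * rng.normal(size=st.z.shape)
    return st


class TestLinearPredictor:
    def test_alpha_only(self, tiny_sim):
        st = tiny_sim["truth"].copy()
        st.beta[:] = 0.1  # irrelevant once kappa is zero
        st.kappa[:] = 0.0
        st.v[:] = 0.0
        st.u[:] = 0.0
        st.u_region[:] = 0.0
        st.z[:] = 0.0
        spec = tiny_sim["spec"]
        eta = sl.linear_predictor(st, spec.grouping, spec.periods, spec.region_index)
        np.testing.assert_allclose(eta, st.alpha[:, None, None] * np.ones_like(eta))

    def test_zero_beta_row_is_time_constant(self, tiny_sim):
        st = tiny_sim["truth"].copy()
        st.beta[3] = 0.0
        st.z[:] = 0.0
        spec = tiny_sim["spec"]
        eta = sl.linear_predictor(st, spec.grouping, spec.periods, spec.region_index)
        assert np.ptp(eta[3], axis=0).max() < 1e-12

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_naive_loop_oracle(self, tiny_sim, seed):
        st = _random_state(tiny_sim, seed)
        spec = tiny_sim["spec"]
        eta = sl.linear_predictor(st, spec.grouping, spec.periods, spec.region_index)
        omega = st.omega()
        years = list(spec.periods.years)
        for x in range(0, len(st.alpha), 5):
            for t in range(len(st.kappa)):
                for s in range(st.z.shape[2]):
                    g = spec.grouping.index_of(x)
                    p = spec.periods.period_of(years[t]) - 1
                    r = spec.region_index[s]
                    expect = (st.alpha[x] + st.beta[x] * st.kappa[t]
                              + omega[s, g, p] + st.u_region[r] + st.z[x, t, s])
                    assert abs(eta[x, t, s] - expect) < 1e-12


class TestBym2Effect:
    def test_phi_zero_is_unstructured_only(self):
        v, u = np.array([1.0, -2.0]), np.array([3.0, 4.0])
        np.testing.assert_allclose(sl.bym2_effect(v, u, 2.0, 0.0), 2.0 * v)

    def test_phi_one_is_structured_only(self):
        v, u = np.array([1.0, -2.0]), np.array([3.0, 4.0])
        np.testing.assert_allclose(sl.bym2_effect(v, u, 2.0, 1.0), 2.0 * u)

    def test_zero_scale(self):
        np.testing.assert_allclose(sl.bym2_effect(np.ones(3), np.ones(3), 0.0, 0.5), 0.0)

    def test_phi_outside_unit_interval(self):
        with pytest.raises(ValidationError):
            sl.bym2_effect(np.ones(2), np.ones(2), 1.0, 1.5)


class TestPoissonLoglik:
    def test_zero_count_unit_mean(self):
        assert abs(sl.poisson_loglik(np.array([0.0]), np.array([1.0]), np.array([0.0])) - (-1.0)) < 1e-14

    def test_closed_form_two_counts(self):
        # E=100, rate 0.01 -> Poisson(1); log pmf at 2 is -1 - log 2
        val = sl.poisson_loglik(np.array([2.0]), np.array([100.0]), np.array([np.log(0.01)]))
        assert abs(val - (-1.0 - np.log(2.0))) < 1e-12

    def test_matches_per_cell_oracle(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 30, size=(4, 3, 2)).astype(float)
        E = rng.uniform(10, 1e3, size=y.shape)
        eta = rng.normal(-3, 0.5, size=y.shape)
        expect = 0.0
        for idx in np.ndindex(y.shape):
            lam = E[idx] * np.exp(eta[idx])
            expect += y[idx] * np.log(lam) - lam - gammaln(y[idx] + 1)
        assert abs(sl.poisson_loglik(y, E, eta) - expect) < 1e-10

    def test_non_finite_eta_rejected(self):
        with pytest.raises(ValidationError):
            sl.poisson_loglik(np.array([1.0]), np.array([1.0]), np.array([np.inf]))


class TestRW2:
    def test_linear_kappa_attains_maximum(self):
        t = np.arange(6, dtype=float)
        val = sl.rw2_logdensity(3.0 - 0.7 * t, sigma_kappa=0.3)
        max_term = -np.log(0.3) - 0.5 * np.log(2 * np.pi)
        assert abs(val - 4 * max_term) < 1e-12

    def test_single_innovation(self):
        val = sl.rw2_logdensity(np.array([0.0, 0.0, 1.0]), 1.0)
        assert abs(val - (-0.5 - 0.5 * np.log(2 * np.pi))) < 1e-14

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        kappa = rng.normal(size=9)
        sk = 0.4
        expect = sum(
            -0.5 * ((kappa[t] - 2 * kappa[t - 1] + kappa[t - 2]) / sk) ** 2
            - np.log(sk) - 0.5 * np.log(2 * np.pi)
            for t in range(2, 9)
        )
        assert abs(sl.rw2_logdensity(kappa, sk) - expect) < 1e-12

    def test_invariant_to_linear_shift(self):
        rng = np.random.default_rng(2)
        kappa = rng.normal(size=7)
        shifted = kappa + 2.5 - 0.8 * np.arange(7)
        assert abs(sl.rw2_logdensity(kappa, 0.2) - sl.rw2_logdensity(shifted, 0.2)) < 1e-10

    def test_too_short(self):
        with pytest.raises(ValidationError):
            sl.rw2_logdensity(np.array([0.0, 1.0]), 1.0)


class TestPCSigma:
    def test_upper_tail_inversion(self):
        theta = sl.calibrate_pc_sigma(3.0, 0.05)
        assert abs(theta - (-np.log(0.05) / 3.0)) < 1e-15
        # CDF complement at upper equals prob
        assert abs(np.exp(-theta * 3.0) - 0.05) < 1e-12

    def test_unit_rate_case(self):
        assert abs(sl.calibrate_pc_sigma(1.0, np.exp(-1.0)) - 1.0) < 1e-12

    def test_lower_orientation(self):
        theta = sl.calibrate_pc_sigma(3.0, 0.05, orientation="lower")
        assert abs((1.0 - np.exp(-theta * 3.0)) - 0.05) < 1e-12


class TestPCPhi:
    def test_cdf_hits_requested_mass(self, tiny_sim):
        ss = tiny_sim["spec"].structure
        lam = sl.calibrate_pc_phi(ss, 0.5, 2.0 / 3.0)
        gammas = _structure_gammas(ss)
        assert abs(sl.pc_phi_cdf(0.5, lam, gammas) - 2.0 / 3.0) < 1e-8

    def test_more_mass_concentrates_near_zero(self, tiny_sim):
        ss = tiny_sim["spec"].structure
        lam_low = sl.calibrate_pc_phi(ss, 0.5, 0.7)
        lam_high = sl.calibrate_pc_phi(ss, 0.5, 0.95)
        assert lam_high > lam_low

    def test_unreachable_mass_is_error(self, tiny_sim):
        # below the lambda -> 0 limit d(0.5)/d(1) no positive rate works
        with pytest.raises(ValidationError, match="not bracketed"):
            sl.calibrate_pc_phi(tiny_sim["spec"].structure, 0.5, 1e-6)

    def test_cdf_matches_sampling_oracle(self, tiny_sim):
        """P(phi < 0.5) by simulating the distance construction directly."""
        ss = tiny_sim["spec"].structure
        gammas = _structure_gammas(ss)
        lam = sl.calibrate_pc_phi(ss, 0.5, 2.0 / 3.0)
        rng = np.random.default_rng(5)
        d = rng.exponential(1.0 / lam, size=200_000)
        dmax = float(sl.phi_distance(1.0, gammas))
        d = d[d <= dmax][:50_000]
        phis = np.array([
            brentq(lambda p: float(sl.phi_distance(p, gammas)) - di, 0.0, 1.0)
            for di in d[:5000]
        ])
        est = float(np.mean(phis < 0.5))
        se = float(np.std(phis < 0.5) / np.sqrt(len(phis)))
        assert abs(est - 2.0 / 3.0) < 3 * se + 1e-3

    def test_density_integrates_to_cdf(self, tiny_sim):
        from scipy.integrate import quad
        ss = tiny_sim["spec"].structure
        gammas = _structure_gammas(ss)
        lam = sl.calibrate_pc_phi(ss, 0.5, 2.0 / 3.0)
        val, _ = quad(lambda p: np.exp(sl.pc_phi_logpdf(p, lam, gammas)), 0.0, 0.5,
                      limit=200)
        assert abs(val - 2.0 / 3.0) < 1e-6


class TestConstraints:
    def test_idempotent_on_constrained_state(self, tiny_sim):
        st = tiny_sim["truth"]
        out = sl.apply_constraints(st, tiny_sim["spec"])
        for name in ("alpha", "beta", "kappa", "v", "u", "z"):
            np.testing.assert_allclose(getattr(out, name), getattr(st, name), atol=1e-12)

    def test_beta_rescale_preserves_products(self, tiny_sim):
        st = tiny_sim["truth"].copy()
        st.beta = np.full(len(st.beta), 2.0)
        st.kappa = np.linspace(1, -1, len(st.kappa))
        st.kappa -= st.kappa.mean()
        before = st.beta[:, None] * st.kappa[None, :]
        out = sl.apply_constraints(st, tiny_sim["spec"])
        assert abs(out.beta.sum() - 1.0) < 1e-12
        np.testing.assert_allclose(out.beta[:, None] * out.kappa[None, :], before, atol=1e-10)

    @pytest.mark.parametrize("seed", range(4))
    def test_projection_leaves_linear_predictor_invariant(self, tiny_sim, seed):
        st = _random_state(tiny_sim, seed)
        spec = tiny_sim["spec"]
        eta0 = sl.linear_predictor(st, spec.grouping, spec.periods, spec.region_index)
        out = sl.apply_constraints(st, spec)
        eta1 = sl.linear_predictor(out, spec.grouping, spec.periods, spec.region_index)
        np.testing.assert_allclose(eta0, eta1, atol=1e-10)
        # constraints hold
        assert abs(out.beta.sum() - 1.0) < 1e-10
        assert abs(out.kappa.sum()) < 1e-10
        omega = out.omega()
        for comp in spec.structure.components:
            if len(comp) > 1:
                idx = np.array(comp) - 1
                np.testing.assert_allclose(omega[idx].sum(axis=0), 0.0, atol=1e-10)

    def test_zero_beta_sum_is_error(self, tiny_sim):
        st = tiny_sim["truth"].copy()
        st.beta = np.zeros(len(st.beta))
        with pytest.raises(ValidationError):
            sl.apply_constraints(st, tiny_sim["spec"])


class TestJointDensity:
    def test_additivity_of_terms(self, tiny_sim):
        st = tiny_sim["truth"]
        ds, spec = tiny_sim["dataset"], tiny_sim["spec"]
        total = sl.joint_logdensity(st, ds, spec)
        eta = sl.linear_predictor(st, spec.grouping, spec.periods, spec.region_index)
        lik = sl.poisson_loglik(ds.deaths, ds.exposures, eta)
        # likelihood is one of the terms: removing it leaves the prior part,
        # which must not depend on the data
        prior_part = total - lik
        ds2 = sl.MortalityDataset(ds.deaths * 0, ds.exposures, ds.age_values,
                                  ds.year_values, ds.province_ids, ds.region_of)
        eta2 = eta
        lik2 = sl.poisson_loglik(ds2.deaths, ds2.exposures, eta2)
        total2 = sl.joint_logdensity(st, ds2, spec)
        assert abs((total2 - lik2) - prior_part) < 1e-8

    def test_more_discrepant_count_lowers_density(self, tiny_sim):
        st = tiny_sim["truth"]
        ds, spec = tiny_sim["dataset"], tiny_sim["spec"]
        base = sl.joint_logdensity(st, ds, spec)
        worse = ds.deaths.copy()
        worse[0, 0, 0] += 200
        ds2 = sl.MortalityDataset(worse, ds.exposures, ds.age_values, ds.year_values,
                                  ds.province_ids, ds.region_of)
        assert sl.joint_logdensity(st, ds2, spec) < base

    @pytest.mark.parametrize("seed", range(20))
    def test_finite_for_generated_states(self, seed):
        cfg = sl.SimConfig(seed=seed, n_provinces=6, n_regions=2, max_age=8, n_years=4,
                           n_island_provinces=1)
        graph, spec, truth, ds = sl.simulate(cfg)
        assert np.isfinite(sl.joint_logdensity(truth, ds, spec))


class TestBym2VarianceProperty:
    @pytest.mark.parametrize("phi", [0.0, 0.5, 1.0])
    def test_marginal_variance_is_sigma_squared(self, tiny_sim, phi):
        """Geometric-mean marginal variance of omega/sigma equals 1 for any phi."""
        ss = tiny_sim["spec"].structure
        B = sl.besag_basis(ss)
        rng = np.random.default_rng(9)
        n = ss.n_nodes
        ndraws = 40_000
        v = rng.standard_normal((ndraws, n))
        u = rng.standard_normal((ndraws, B.shape[1])) @ B.T
        om = np.sqrt(1 - phi) * v + np.sqrt(phi) * u
        var = om.var(axis=0)
        gm = np.exp(np.mean(np.log(var)))
        assert abs(gm - 1.0) < 0.05
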