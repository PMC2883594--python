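import numpy as np
import pytest
from scipy.optimize import brentq

from cisevolve.response_dynamics import (
    DynamicsParams,
    MarginalStabilityError,
    ResponsePolynomial,
    bistability_scan_rp,
    detect_bistability_rp,
    intrinsic_noise_sd_rp,
    response_surface,
    response_time_rp,
    steady_state_rp,
    steady_states_batch,
)
from cisevolve.thermodynamic_model import (
    SiteTable,
    ThermoParams,
    partition_polynomials,
    promoter_occupancy,
)

DYN = DynamicsParams()


def rp_for(table, c1=0.0, c2=0.0, dyn=DYN):
    return ResponsePolynomial.from_table(table, c1, c2, dyn)


def explicit(sites, q_r, l_cis=150, l_tf=9, **thermo):
    return SiteTable.explicit(l_cis, l_tf, sites, q_r=q_r, params=ThermoParams(**thermo))


@pytest.fixture(scope="module")
def autoactivator():
    """Cooperative auto-activator: proximal recruiting + distal TF3 sites.

    With a weak basal promoter this layout is bistable (tuned constants)."""
    return explicit([("TF3", 104, 5300.0), ("TF3", 85, 965.0)], q_r=0.0204)


@pytest.fixture(scope="module")
def autorepressor():
    """TF3 operator overlapping the footprint; q_r tuned for c3* = 500."""
    return explicit([("TF3", 122, 200.0)], q_r=3.5)


class TestSteadyState:
    def test_constant_occupancy_linear_fixed_point(self):
        # no TF3 sites: P_on is constant, c3* = c_max * q/(1+q)
        for q in (0.1, 1.0, 9.0):
            rp = rp_for(explicit([], q_r=q))
            assert steady_state_rp(rp, 0.0) == pytest.approx(
                1000.0 * q / (1 + q), rel=1e-6
            )

    def test_silent_promoter_settles_at_zero(self):
        rp = rp_for(explicit([], q_r=0.0))
        assert steady_state_rp(rp, 0.0) == 0.0
        assert steady_state_rp(rp, 1000.0) == pytest.approx(0.0, abs=DYN.eps_ss)

    def test_autoactivator_matches_bisection_oracle(self, models):
        # independent oracle: brentq on beta*P_on(c) - mu*c via the scalar
        # occupancy query, bracketing the low branch
        t = explicit([("TF3", 104, 2000.0)], q_r=0.5)

        def f(c):
            return DYN.beta * promoter_occupancy(t, 0.0, 0.0, c) - DYN.mu * c

        oracle = brentq(f, 0.0, 1000.0, xtol=1e-9)
        rp = rp_for(t)
        assert steady_state_rp(rp, 0.0) == pytest.approx(oracle, rel=1e-6)

    def test_residual_contract(self, rng):
        from _oracles import random_toy_table

        for _ in range(20):
            t = random_toy_table(rng)
            rp = ResponsePolynomial.from_table(t, 300.0, 300.0, DYN)
            c_star = steady_state_rp(rp, 0.0)
            assert abs(rp.velocity(c_star)) < DYN.mu * DYN.eps_ss

    def test_out_of_range_initial_condition(self):
        rp = rp_for(explicit([], q_r=1.0))
        with pytest.raises(ValueError):
            steady_state_rp(rp, -5.0)


class TestBistability:
    def test_constitutive_gene_monostable(self):
        rp = rp_for(explicit([], q_r=1.0))
        lo, hi, pen = detect_bistability_rp(rp)
        assert lo == pytest.approx(hi, abs=DYN.eps_ss)
        assert pen == 0.0

    def test_cooperative_autoactivator_bistable(self, autoactivator):
        rp = rp_for(autoactivator)
        lo, hi, pen = detect_bistability_rp(rp)
        assert hi - lo > 100.0
        assert pen == pytest.approx((hi - lo) ** 2)
        # the two states must appear in a dense root scan as well
        roots = bistability_scan_rp(rp, n_grid=512)
        assert len(roots) >= 2
        assert roots[0] == pytest.approx(lo, abs=1e-3)
        assert roots[-1] == pytest.approx(hi, abs=1e-3)

    def test_autorepressor_monostable(self, autorepressor):
        rp = rp_for(autorepressor)
        _, _, pen = detect_bistability_rp(rp)
        assert pen == 0.0

    def test_scan_contains_detected_states(self, rng):
        from _oracles import random_toy_table

        for _ in range(10):
            rp = ResponsePolynomial.from_table(random_toy_table(rng), 200.0, 800.0, DYN)
            lo, hi, _ = detect_bistability_rp(rp)
            roots = bistability_scan_rp(rp)
            assert min(abs(r - lo) for r in roots) < 1e-3
            assert min(abs(r - hi) for r in roots) < 1e-3

    def test_scan_grid_floor(self):
        rp = rp_for(explicit([], q_r=1.0))
        with pytest.raises(ValueError):
            bistability_scan_rp(rp, n_grid=50)


class TestResponseTime:
    def test_zero_at_steady_state(self):
        rp = rp_for(explicit([], q_r=1.0))
        c_star = steady_state_rp(rp, 0.0)
        assert response_time_rp(rp, c_star) == 0.0

    def test_constitutive_exponential_relaxation(self):
        # linear ODE: t = ln(|c0 - c*| / eps_rt) / mu
        q = 1.0
        rp = rp_for(explicit([], q_r=q))
        c_star = 1000.0 * q / (1 + q)
        for c0 in (0.0, 1000.0):
            expected = np.log(abs(c0 - c_star) / DYN.eps_rt) / DYN.mu
            assert response_time_rp(rp, c0) == pytest.approx(expected, rel=1e-3)

    def test_autorepression_speeds_up_response(self, autorepressor):
        rp_rep = rp_for(autorepressor)
        c_star = steady_state_rp(rp_rep, 0.0)
        q_match = c_star / (1000.0 - c_star)
        rp_const = rp_for(explicit([], q_r=q_match))
        assert steady_state_rp(rp_const, 0.0) == pytest.approx(c_star, rel=1e-6)
        for c0 in (0.0, 1000.0):
            assert response_time_rp(rp_rep, c0) < response_time_rp(rp_const, c0)


class TestIntrinsicNoise:
    def test_poisson_limit_for_constitutive_gene(self):
        for q in (0.2, 1.0, 4.0):
            rp = rp_for(explicit([], q_r=q))
            c_star = steady_state_rp(rp, 0.0)
            sigma = intrinsic_noise_sd_rp(rp)
            assert sigma == pytest.approx(np.sqrt(c_star / DYN.volume), rel=1e-3)

    def test_autoactivation_amplifies_noise(self):
        # monostable auto-activation (single weak site, f' > 0) vs a
        # constitutive gene matched to the same steady state
        t = explicit([("TF3", 104, 5000.0)], q_r=0.5)
        rp = rp_for(t)
        c_star = steady_state_rp(rp, 0.0)
        sigma_auto = intrinsic_noise_sd_rp(rp)
        rp_const = rp_for(explicit([], q_r=c_star / (1000.0 - c_star)))
        assert steady_state_rp(rp_const, 0.0) == pytest.approx(c_star, rel=1e-6)
        assert sigma_auto > intrinsic_noise_sd_rp(rp_const)

    def test_noise_diverges_toward_marginal_stability(self):
        # strengthening auto-activation raises f' toward mu: sigma grows
        sigmas = []
        for kd in (8000.0, 5000.0, 3500.0):
            rp = rp_for(explicit([("TF3", 104, kd)], q_r=0.5))
            sigmas.append(intrinsic_noise_sd_rp(rp))
        assert sigmas[0] < sigmas[1] < sigmas[2]

    def test_autorepression_reduces_noise(self, autorepressor):
        rp_rep = rp_for(autorepressor)
        c_star = steady_state_rp(rp_rep, 0.0)
        rp_const = rp_for(explicit([], q_r=c_star / (1000.0 - c_star)))
        assert intrinsic_noise_sd_rp(rp_rep) < intrinsic_noise_sd_rp(rp_const)


class TestResponseSurface:
    def test_constitutive_surface_constant(self, models):
        t = explicit([], q_r=2.0)
        c = np.array([125.0, 375.0, 625.0, 875.0])
        c1, c2 = np.meshgrid(c, c, indexing="ij")
        surf = response_surface(t, models, c1.ravel(), c2.ravel())
        assert surf.output.shape == (16,)
        assert np.allclose(surf.output, surf.output[0])
        assert not surf.bistable.any()

    def test_batch_matches_scalar_path(self, rng):
        from _oracles import random_toy_table

        t = random_toy_table(rng)
        c1 = np.array([0.0, 125.0, 500.0, 1000.0])
        c2 = np.array([1000.0, 500.0, 125.0, 0.0])
        zon, zoff = partition_polynomials(t, c1, c2)
        low, high, pen = steady_states_batch(zon, zoff, DYN)
        for g in range(4):
            rp = ResponsePolynomial(zon[g], zoff[g], DYN)
            lo_s, hi_s, pen_s = detect_bistability_rp(rp)
            assert low[g] == pytest.approx(lo_s, abs=1e-6)
            assert high[g] == pytest.approx(hi_s, abs=1e-6)
            assert pen[g] == pytest.approx(pen_s, rel=1e-6, abs=1e-9)

    def test_empty_grid_rejected(self, models):
        with pytest.raises(ValueError):
            response_surface(explicit([], q_r=1.0), models, [], [])
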