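import numpy as np
import pytest

from cisevolve.gates_and_fitness import GateSpec
from cisevolve.minimal_models import (
    LAYOUTS,
    MinimalModelSpec,
    linear_repression_derivative_check,
    max_sensitivity,
    minimal_e_rf,
    minimal_response,
    minimal_response_all,
    minimal_site_table,
    optimize_affinities,
    sensitivity,
)
from cisevolve.response_dynamics import DynamicsParams, ResponsePolynomial, steady_state_rp

DYN = DynamicsParams()


class TestMinimalResponse:
    def test_every_layout_matches_full_engine(self, rng):
        """The closed forms are special cases of the general machinery."""
        for layout in LAYOUTS:
            worst = 0.0
            for _ in range(10):
                spec = MinimalModelSpec(
                    layout=layout,
                    k1=10 ** rng.uniform(1, 4),
                    k1b=10 ** rng.uniform(1, 4),
                    k3=10 ** rng.uniform(1.5, 4),
                    p=10 ** rng.uniform(-2, 1),
                    omega=10 ** rng.uniform(0, 2),
                )
                c1 = float(10 ** rng.uniform(0, 3))
                rp = ResponsePolynomial.from_table(minimal_site_table(spec), c1, 0.0, DYN)
                engine = steady_state_rp(rp, 0.0)
                closed = minimal_response(spec, c1)
                worst = max(worst, abs(engine - closed) / max(abs(engine), 1e-6))
            assert worst < 1e-4, layout

    def test_removing_feedback_site_recovers_single_site_activation(self):
        base = dict(k1=500.0, p=0.5, omega=50.0)
        cond = MinimalModelSpec("cond_auto_act", k3=1e12, **base)
        act = MinimalModelSpec("act_1site", **base)
        for c1 in (0.0, 50.0, 400.0, 1000.0):
            assert minimal_response(cond, c1) == pytest.approx(
                minimal_response(act, c1), rel=1e-6
            )

    def test_unrepressed_basal_fixed_point(self):
        spec = MinimalModelSpec("rep_2site_coop", k1=300.0, k1b=300.0, p=2.0)
        assert minimal_response(spec, 0.0) == pytest.approx(
            1000.0 * 2.0 / 3.0, rel=1e-9
        )

    def test_activation_monotone_repression_antitone(self):
        cs = np.linspace(1.0, 1000.0, 12)
        act = MinimalModelSpec("cond_auto_act", k1=500.0, k3=2000.0, p=0.2)
        rep = MinimalModelSpec("rep_2site_coop_plus_autoact", k1=500.0,
                               k1b=500.0, k3=500.0, p=1.0)
        r_act = [minimal_response(act, c) for c in cs]
        r_rep = [minimal_response(rep, c) for c in cs]
        assert np.all(np.diff(r_act) >= -1e-9)
        assert np.all(np.diff(r_rep) <= 1e-9)

    def test_single_auto_site_layouts_are_monostable(self, rng):
        # with one auto-regulatory site the feedback production is a
        # concave (Moebius) function of the output, so the fixed point is
        # unique; the branch-reporting machinery must find exactly one
        for layout in ("cond_auto_act", "rep_2site_coop_plus_autoact"):
            for _ in range(10):
                spec = MinimalModelSpec(
                    layout, k1=10 ** rng.uniform(1, 4), k1b=10 ** rng.uniform(1, 4),
                    k3=10 ** rng.uniform(1, 4), p=10 ** rng.uniform(-2, 1),
                    omega=10 ** rng.uniform(0, 2),
                )
                roots = minimal_response_all(spec, float(10 ** rng.uniform(0, 3)))
                assert len(roots) == 1

    def test_invalid_layout_rejected(self):
        with pytest.raises(ValueError):
            MinimalModelSpec("no_such_layout")


class TestSensitivity:
    def test_hill_coefficient_bounds_hill_response(self):
        # n = 2 Hill activation: S approaches 2 from below at low input
        hill = lambda c: 1000.0 * c**2 / (c**2 + 300.0**2)  # noqa: E731
        s_values = [sensitivity(hill, float(c)) for c in np.geomspace(0.1, 1000, 60)]
        assert max(s_values) <= 2.0 + 1e-6
        assert max(s_values) > 1.98

    def test_linear_response_has_unit_sensitivity(self):
        lin = lambda c: 3.5 * c  # noqa: E731
        for c in (1.0, 10.0, 500.0):
            assert sensitivity(lin, c) == pytest.approx(1.0, abs=1e-9)

    def test_constant_response_has_zero_sensitivity(self):
        assert sensitivity(lambda c: 123.0, 10.0) == pytest.approx(0.0, abs=1e-12)

    def test_zero_response_rejected(self):
        with pytest.raises(ValueError):
            sensitivity(lambda c: 0.0, 10.0)

    def test_repression_sensitivity_bounded_by_site_count_small_sweep(self):
        res = max_sensitivity(
            "rep_2site_coop", k_range=(10.0, 1000.0), omega_range=(10.0, 100.0),
            p_range=(0.1, 10.0), points_per_decade=8, c1_points=101,
        )
        assert res["s_max"] <= 2.0 + 1e-3

    def test_autoactivation_lifts_sensitivity_above_site_count(self):
        res = max_sensitivity(
            "rep_2site_coop_plus_autoact", k_range=(50.0, 500.0),
            omega_range=(50.0, 100.0), p_range=(10.0, 100.0), k3=100.0,
            points_per_decade=4, c1_points=60,
        )
        assert res["s_max"] > 2.0

    def test_conditional_autoactivation_sensitivity_grows_as_rnap_weight_falls(self):
        """Lowering the promoter weight keeps raising the attainable
        steepness of conditional auto-activation (no Hill-type ceiling)."""
        s_best = []
        for p in (1.0, 0.1, 0.01, 0.001):
            best = -np.inf
            for k3 in np.geomspace(3, 3000, 7):
                res = max_sensitivity(
                    "cond_auto_act", k_range=(10.0, 1e4),
                    omega_range=(50.0, 50.0), p_range=(p, p), k3=float(k3),
                    points_per_decade=4, c1_points=50,
                )
                best = max(best, res["s_max"])
            s_best.append(best)
        assert all(b > a for a, b in zip(s_best, s_best[1:]))


class TestOptimizeAffinities:
    def test_cooperative_activation_beats_single_site(self):
        gate = GateSpec("ACT")
        _, e1 = optimize_affinities(MinimalModelSpec("act_1site", p=0.1), gate, seed=1)
        _, e2 = optimize_affinities(
            MinimalModelSpec("act_2site_coop", p=0.1), gate, seed=1
        )
        assert e2 < e1

    def test_feedback_gives_no_advantage_for_linear_activation(self):
        """Replacing the auto-regulatory site by an input-TF site does at
        least as well on the linear-activation goal, so auto-regulation is
        not helpful for this response shape."""
        gate = GateSpec("LACT")
        _, e_auto = optimize_affinities(
            MinimalModelSpec("cond_auto_act", p=1.0), gate, seed=1
        )
        _, e_plain = optimize_affinities(
            MinimalModelSpec("act_2site_coop", p=1.0), gate, seed=1
        )
        assert e_plain <= e_auto * 1.001

    def test_autoactivation_straightens_linear_repression(self):
        gate = GateSpec("LIN")
        _, e_plain = optimize_affinities(
            MinimalModelSpec("rep_2site_coop", p=1.0), gate, seed=1
        )
        _, e_auto = optimize_affinities(
            MinimalModelSpec("lin_rep_unequal_sites", p=1.0), gate, seed=1
        )
        assert e_auto < e_plain

    def test_no_regression_from_an_optimized_point(self):
        gate = GateSpec("ACT")
        spec, e_best = optimize_affinities(
            MinimalModelSpec("act_1site", p=0.1), gate, seed=1
        )
        again, e_again = optimize_affinities(spec, gate, n_restarts=2, seed=2)
        assert e_again <= e_best * (1 + 1e-9)

    def test_two_input_gates_rejected(self):
        with pytest.raises(ValueError):
            optimize_affinities(MinimalModelSpec("act_1site"), GateSpec("AND"))


class TestLinearRepressionIdentity:
    def test_identity_residual_small_along_branch(self):
        spec = MinimalModelSpec(
            "lin_rep_unequal_sites", k1=300.0, k1b=9000.0, k3=400.0, p=1.0
        )
        assert linear_repression_derivative_check(spec) < 1e-6

    def test_denominator_is_unity_without_feedback(self):
        spec = MinimalModelSpec("rep_2site_coop", k1=300.0, k1b=9000.0, p=1.0)
        assert linear_repression_derivative_check(spec) < 1e-6

    def test_non_repression_layout_rejected(self):
        with pytest.raises(ValueError):
            linear_repression_derivative_check(MinimalModelSpec("act_1site"))
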