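import numpy as np
import pytest

from cisevolve.gates_and_fitness import (
    GATES,
    EvaluationGrid,
    FitnessWeights,
    GateSpec,
    fitness_noise,
    fitness_rf,
    fitness_rt,
    fitness_total,
    goal_function,
    lambda_ramp,
)
from cisevolve.response_dynamics import (
    DynamicsParams,
    ResponsePolynomial,
    ResponseSurface,
    intrinsic_noise_sd_rp,
    steady_state_rp,
)
from cisevolve.thermodynamic_model import SiteTable, ThermoParams

DYN = DynamicsParams()


def surface_from(outputs, gate, penalty=None):
    grid = EvaluationGrid()
    c1, c2 = grid.points(gate)
    outputs = np.asarray(outputs, dtype=float)
    return ResponseSurface(
        c1=c1, c2=c2, output=outputs, output_high=outputs.copy(),
        penalty=np.zeros_like(outputs) if penalty is None else np.asarray(penalty),
    )


class TestGoalFunctions:
    def test_and_truth_table_rows(self):
        gate = GateSpec("AND")
        assert goal_function(gate, 875.0, 875.0) == 1000.0
        assert goal_function(gate, 125.0, 875.0) == 0.0

    @pytest.mark.parametrize(
        "name,expected",
        [
            ("AND", [0, 0, 0, 1000]),
            ("OR", [0, 1000, 1000, 1000]),
            ("NOR", [1000, 0, 0, 0]),
            ("NAND", [1000, 1000, 1000, 0]),
            ("ACT", [0, 0, 1000, 1000]),
            ("IN", [1000, 1000, 0, 0]),
        ],
    )
    def test_logic_truth_tables_at_corners(self, name, expected):
        gate = GateSpec(name)
        corners = [(125, 125), (125, 875), (875, 125), (875, 875)]
        got = [float(goal_function(gate, a, b)) for a, b in corners]
        assert got == [float(v) for v in expected]

    def test_linear_gate_forms(self):
        assert goal_function(GateSpec("LIN"), 0.0) == 1000.0
        assert goal_function(GateSpec("LIN"), 1000.0) == 0.0
        assert goal_function(GateSpec("LACT"), 250.0) == 250.0
        assert goal_function(GateSpec("MEAN"), 125.0, 875.0) == 500.0
        assert goal_function(GateSpec("NMEAN"), 125.0, 875.0) == 500.0

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            goal_function(GateSpec("AND"), 1500.0, 0.0)

    def test_grid_shapes(self):
        grid = EvaluationGrid()
        for gate in GATES:
            c1, c2 = grid.points(gate)
            assert len(c1) == (16 if gate.arity == 2 else 7)
        assert len(grid.corners()[0]) == 4


class TestFitnessRF:
    def test_perfect_surface_scores_zero(self):
        gate = GateSpec("NAND")
        goal = goal_function(gate, *EvaluationGrid().points(gate))
        assert fitness_rf(surface_from(goal, gate), gate) == 0.0

    def test_uniform_deviation_arithmetic(self):
        gate = GateSpec("MEAN")
        goal = goal_function(gate, *EvaluationGrid().points(gate))
        surf = surface_from(goal + 100.0, gate)
        assert fitness_rf(surf, gate) == pytest.approx(16 * 1e4)

    def test_matches_direct_summation_oracle(self, rng):
        gate = GateSpec("OR")
        c1, c2 = EvaluationGrid().points(gate)
        outputs = rng.uniform(0, 1000, size=16)
        penalty = rng.uniform(0, 100, size=16)
        surf = surface_from(outputs, gate, penalty)
        goal = goal_function(gate, c1, c2)
        expected = float(np.sum((outputs - goal) ** 2) + penalty.sum())
        assert fitness_rf(surf, gate) == pytest.approx(expected, rel=1e-9)

    def test_failed_point_gives_worst_score(self):
        gate = GateSpec("AND")
        outputs = np.zeros(16)
        outputs[3] = np.nan
        assert fitness_rf(surface_from(outputs, gate), gate) == float("inf")


@pytest.fixture(scope="module")
def constitutive(models):
    return SiteTable.explicit(150, 9, [], q_r=1.0, params=ThermoParams())


@pytest.fixture(scope="module")
def autorepressor(models):
    return SiteTable.explicit(150, 9, [("TF3", 122, 200.0)], q_r=3.5,
                              params=ThermoParams())


class TestDynamicFitnessComponents:
    def test_constitutive_response_times_closed_form(self, models, constitutive):
        gate = GateSpec("AND")
        e_rt = fitness_rt(constitutive, models, gate, EvaluationGrid())
        c_star = 500.0
        expected = 16 * (
            np.log(c_star / DYN.eps_rt) + np.log((1000 - c_star) / DYN.eps_rt)
        )
        assert e_rt == pytest.approx(expected, rel=1e-3)

    def test_autorepressor_beats_matched_constitutive(self, models, autorepressor):
        gate = GateSpec("AND")
        grid = EvaluationGrid()
        rp = ResponsePolynomial.from_table(autorepressor, 0, 0, DYN)
        c_star = steady_state_rp(rp, 0.0)
        matched = SiteTable.explicit(150, 9, [], q_r=c_star / (1000 - c_star),
                                     params=ThermoParams())
        assert fitness_rt(autorepressor, models, gate, grid) < fitness_rt(
            matched, models, gate, grid
        )
        assert fitness_noise(autorepressor, models, gate, grid) < fitness_noise(
            matched, models, gate, grid
        )

    def test_constitutive_noise_is_poisson_sum(self, models, constitutive):
        gate = GateSpec("AND")
        e_n = fitness_noise(constitutive, models, gate, EvaluationGrid())
        assert e_n == pytest.approx(16 * np.sqrt(500.0 / DYN.volume), rel=1e-3)

    def test_silent_gene_zero_noise(self, models):
        silent = SiteTable.explicit(150, 9, [], q_r=0.0, params=ThermoParams())
        e_n = fitness_noise(silent, models, GateSpec("AND"), EvaluationGrid())
        assert e_n == 0.0


class TestTotalFitness:
    def test_lambda_ramp_schedule(self):
        assert lambda_ramp(0, 2.0, 100) == 0.0
        assert lambda_ramp(50, 2.0, 100) == pytest.approx(1.0)
        assert lambda_ramp(100, 2.0, 100) == 2.0
        assert lambda_ramp(500, 2.0, 100) == 2.0
        with pytest.raises(ValueError):
            lambda_ramp(-1, 2.0, 100)

    def test_composite_arithmetic(self):
        w = FitnessWeights(s0=1e7)
        assert fitness_total(0.0, 0.0, 0.0, w, 0) == 1e7
        assert fitness_total(160000.0, 0.0, 0.0, w, 0) == pytest.approx(9840000.0)

    def test_offset_preserves_ranking(self, rng):
        e_rfs = rng.uniform(0, 1e6, size=20)
        for s0 in (1e7, 1e8):
            w = FitnessWeights(s0=s0)
            scores = [fitness_total(e, 0, 0, w, 0) for e in e_rfs]
            assert list(np.argsort(scores)) == list(np.argsort(-e_rfs))

    def test_misconfigured_offset_raises(self):
        w = FitnessWeights(s0=1.0)
        with pytest.raises(ValueError):
            fitness_total(5.0, 0.0, 0.0, w, 0)

    def test_error_flag_propagates_to_worst_score(self):
        w = FitnessWeights(lambda_rt_max=1.0, t_ramp=1)
        assert fitness_total(0.0, float("inf"), 0.0, w, 5) == float("-inf")
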