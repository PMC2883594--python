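import numpy as np
import pytest

from cisevolve.gates_and_fitness import EvaluationGrid, GateSpec
from cisevolve.promoter_analysis import (
    FootprintProfile,
    call_binding_sites,
    degree_stats,
    feedback_from_surfaces,
    feedback_measure,
    footprint,
    simplify_and_verify,
)
from cisevolve.response_dynamics import response_surface
from cisevolve.thermodynamic_model import SiteTable, ThermoParams

from _oracles import enumerate_configurations


def explicit(sites, q_r, l_cis=150, l_tf=9):
    return SiteTable.explicit(l_cis, l_tf, sites, q_r=q_r, params=ThermoParams())


class TestFeedbackMeasure:
    def test_uniform_shift_forced_by_definition(self):
        n = np.full(16, 600.0)
        assert feedback_from_surfaces(n, n - 100.0) == pytest.approx(1e4)

    def test_no_tf3_sites_gives_zero(self, models):
        t = explicit([("TF1", 104, 500.0)], q_r=0.5)
        assert feedback_measure(t, models, EvaluationGrid(), GateSpec("AND")) == 0.0

    def test_autoactivator_matches_two_surface_recomputation(self, models):
        t = explicit([("TF3", 104, 2000.0)], q_r=0.5)
        grid = EvaluationGrid()
        gate = GateSpec("AND")
        f = feedback_measure(t, models, grid, gate)
        c1, c2 = grid.points(gate)
        full = response_surface(t, models, c1, c2).output
        reduced = response_surface(t.without_tf3(), models, c1, c2).output
        assert f == pytest.approx(float(np.mean((full - reduced) ** 2)), rel=1e-9)
        assert f > 1e3

    def test_symmetric_genotype_invariant_under_input_relabeling(self, models):
        from dataclasses import replace

        t = explicit([("TF1", 104, 800.0), ("TF2", 85, 800.0),
                      ("TF3", 67, 3000.0)], q_r=0.3)
        swapped = replace(t, inv_kd=t.inv_kd[[1, 0, 2]])
        # swapping the TF1/TF2 rows and the input axes leaves F unchanged
        f_a = feedback_measure(t, models, EvaluationGrid(), GateSpec("AND"))
        f_b = feedback_measure(swapped, models, EvaluationGrid(), GateSpec("AND"))
        assert f_a == pytest.approx(f_b, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            feedback_from_surfaces(np.zeros(16), np.zeros(7))


class TestFootprint:
    def test_species_without_sites_has_zero_profile(self, models):
        t = explicit([("TF1", 104, 300.0)], q_r=0.5)
        profile = footprint(t, models)
        assert np.all(profile.o_max[1] == 0.0)  # TF2 binds nowhere
        assert np.all(profile.o_max[2] == 0.0)

    def test_engineered_saturated_site(self, models):
        t = explicit([("TF1", 50, 1.0)], q_r=0.5)
        profile = footprint(t, models)
        assert profile.o_max[0, 50] >= 0.99

    def test_profile_matches_per_corner_enumeration(self, models):
        from cisevolve.response_dynamics import ResponsePolynomial, steady_state_rp

        t = SiteTable.explicit(
            40, 6, [("TF1", 3, 60.0), ("TF2", 11, 200.0), ("TF3", 20, 400.0)],
            q_r=0.8, params=ThermoParams(),
        )
        profile = footprint(t, models)
        o_max = np.zeros_like(profile.o_max)
        for c1 in (0.0, 1000.0):
            for c2 in (0.0, 1000.0):
                rp = ResponsePolynomial.from_table(t, c1, c2, models.dynamics)
                c3 = steady_state_rp(rp, 0.0)
                _, _, occ, _ = enumerate_configurations(t, c1, c2, c3)
                o_max = np.maximum(o_max, occ)
        assert np.allclose(profile.o_max, o_max, atol=1e-9)


class TestSiteCalls:
    def test_empty_profile_yields_no_calls(self):
        profile = FootprintProfile(l_tf=9, o_max=np.zeros((3, 142)))
        t = explicit([], q_r=1.0)
        assert call_binding_sites(profile, t) == []

    def test_single_saturated_site_one_call(self, models):
        t = explicit([("TF1", 50, 1.0)], q_r=0.5)
        calls = call_binding_sites(footprint(t, models), t)
        assert len(calls) == 1
        assert (calls[0].tf_id, calls[0].start, calls[0].end) == ("TF1", 50, 59)
        assert calls[0].role == "distal"

    def test_threshold_above_one_yields_nothing(self, models):
        t = explicit([("TF1", 50, 1.0)], q_r=0.5)
        assert call_binding_sites(footprint(t, models), t, threshold=1.01) == []

    def test_calls_monotone_in_threshold(self, models):
        t = explicit(
            [("TF1", 50, 1.0), ("TF2", 70, 500.0), ("TF3", 104, 2000.0)], q_r=0.5
        )
        profile = footprint(t, models)
        counts = [
            len(call_binding_sites(profile, t, thr))
            for thr in (0.05, 0.3, 0.5, 0.9, 1.01)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_role_annotation(self, models):
        t = explicit(
            [("TF1", 122, 5.0),    # inside the footprint
             ("TF3", 104, 5.0),    # recruiting distance
             ("TF2", 10, 5.0)],    # far upstream
            q_r=0.5,
        )
        calls = call_binding_sites(footprint(t, models), t)
        roles = {c.tf_id: c.role for c in calls}
        assert roles["TF1"] == "repressor"
        assert roles["TF3"] == "auto-activator"
        assert roles["TF2"] == "distal"


class TestSimplification:
    def test_explicit_layout_simplifies_exactly(self, models):
        t = explicit([("TF1", 104, 100.0), ("TF3", 85, 500.0)], q_r=0.5)
        calls = call_binding_sites(footprint(t, models), t)
        assert len(calls) == 2
        _, dev, ok = simplify_and_verify(t, calls, models)
        assert dev == pytest.approx(0.0, abs=1e-6)
        assert ok

    def test_conditional_autoactivation_fixture_reduces_to_called_sites(self, models):
        """The engineered conditional-auto-activation AND gate reduces to
        its three called sites; the remaining deviation (~100 nM) comes
        from the diffuse weak-site background of the sequence model."""
        from cisevolve.fixtures import reference_design

        g = reference_design("AND_cond_autoact", models=models)
        calls = call_binding_sites(footprint(g, models), models.site_table(g))
        assert {(c.tf_id, c.start) for c in calls} == {
            ("TF1", 97), ("TF2", 86), ("TF3", 67)
        }
        _, dev, _ = simplify_and_verify(g, calls, models, EvaluationGrid(),
                                        GateSpec("AND"), tol=150.0)
        assert dev <= 150.0

    def test_dropping_a_called_strong_site_breaks_the_surface(self, models):
        from cisevolve.fixtures import reference_design

        g = reference_design("AND_cond_autoact", models=models)
        calls = call_binding_sites(footprint(g, models), models.site_table(g))
        pruned = [c for c in calls if not (c.tf_id == "TF2" and c.start == 86)]
        _, dev, ok = simplify_and_verify(g, pruned, models, EvaluationGrid(),
                                         GateSpec("AND"))
        assert dev > 150.0 and not ok

    def test_no_calls_rejected(self, models):
        with pytest.raises(ValueError):
            simplify_and_verify(explicit([], q_r=1.0), [], models)


class TestDegreeStats:
    def test_regulon_in_degree_means(self):
        records = [("auto-activator", 0)] * 7 + [("auto-activator", 1)] * 18
        # 25 auto-activators with 52 inputs in total
        extra = 52 - 18
        records = [("auto-activator", 0)] * 7 + [("auto-activator", 1)] * (18 - 1)
        records += [("auto-activator", 1 + extra)]
        stats = degree_stats(records)["auto-activator"]
        assert stats["n"] == 25
        assert stats["mean_in_degree"] == pytest.approx(2.08)

    def test_single_regulator_without_inputs(self):
        stats = degree_stats([("auto-repressor", 0)])["auto-repressor"]
        assert stats["fraction_with_input"] == 0.0
        assert stats["mean_in_degree"] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            degree_stats([])
        with pytest.raises(ValueError):
            degree_stats([("unknown-class", 1)])
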