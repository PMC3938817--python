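"""Topology, parameter templates, and right-hand-side evaluation."""

import numpy as np
import pytest

from floranet import (
    build_parameter_template,
    count_parameters,
    evaluate_rhs,
    instantiate_model,
)
from floranet.models import KINETIC_ORDER_BOUNDS

from literal_rhs import LITERAL_RHS, random_parameters


class TestFloweringTopology:
    def test_species_roles(self, topology):
        deps = topology.dependent_indices
        indeps = topology.independent_indices
        assert len(deps) == 7 and deps == tuple(range(1, 8))
        assert indeps == (8, 9)
        assert topology.species_by_index(8).name == "FD"
        assert topology.species_by_index(9).name == "PHYB"

    def test_production_wiring(self, topology):
        flat = {
            d: tuple(sorted(j for fac in topology.production[d] for j in fac))
            for d in topology.dependent_indices
        }
        assert flat == {1: (9,), 2: (1,), 3: (2, 8), 4: (3, 6), 5: (3,), 6: (4,), 7: (6,)}

    def test_every_dependent_self_degrades(self, topology):
        for d in topology.dependent_indices:
            assert topology.degradation[d][0] == d
        # FT decay additionally carries FD, and only FT
        assert topology.degradation[2] == (2, 8)
        assert all(topology.degradation[d] == (d,) for d in (1, 3, 4, 5, 6, 7))

    def test_soc1_agl24_is_the_only_feedback_loop(self, topology):
        import networkx as nx

        g = nx.DiGraph()
        for d in topology.dependent_indices:
            for fac in topology.production[d]:
                for j in fac:
                    g.add_edge(j, d)
        cycles = list(nx.simple_cycles(g))
        assert cycles == [[4, 6]] or cycles == [[6, 4]]


class TestParameterTemplates:
    @pytest.mark.parametrize(
        "formalism, expected",
        [("s_system", 31), ("michaelis_menten", 23), ("mass_action", 15)],
    )
    def test_parameter_counts(self, topology, formalism, expected):
        model = instantiate_model(topology, formalism)
        assert count_parameters(model) == expected

    def test_unknown_formalism_names_valid_options(self, topology):
        with pytest.raises(ValueError, match="s_system.*michaelis_menten.*mass_action"):
            instantiate_model(topology, "hill")

    def test_kinetic_order_bounds(self, topology):
        t = build_parameter_template(topology, "s_system")
        for name, lo, hi in zip(t.names, t.lower, t.upper):
            if name[0] in "gh":
                assert (lo, hi) == KINETIC_ORDER_BOUNDS
            else:
                assert lo > 0 and hi > lo

    def test_ordering_is_deterministic(self, topology):
        a = build_parameter_template(topology, "michaelis_menten")
        b = build_parameter_template(topology, "michaelis_menten")
        assert a.names == b.names
        assert a.names[:8] == ("Vm1", "Vm2", "Vm3", "Vm4a", "Vm4b", "Vm5", "Vm6", "Vm7")


class TestEvaluateRHS:
    def test_balanced_s_system_is_stationary(self, models):
        m = models["s_system"]
        p = m.parameter_template.copy()
        for i in range(1, 8):
            p.set(f"alpha{i}", 1.3)
            p.set(f"beta{i}", 1.3)
        derivs = evaluate_rhs(m, np.ones(9), p)
        assert np.allclose(derivs, 0.0, atol=1e-14)

    def test_single_line_hand_evaluation(self, models):
        # dX1/dt = alpha1*X9^g19 - beta1*X1^h11 = 1*2 - 0.5*2 = 1
        m = models["s_system"]
        p = m.parameter_template.copy()
        p.set("alpha1", 1.0)
        p.set("g19", 1.0)
        p.set("beta1", 0.5)
        p.set("h11", 0.5)
        state = np.ones(9)
        state[0] = 4.0  # X1
        state[8] = 2.0  # X9
        derivs = evaluate_rhs(m, state, p)
        assert derivs[0] == pytest.approx(1.0, abs=1e-12)

    def test_pure_decay_mass_action(self, models):
        m = models["mass_action"]
        p = m.parameter_template.copy()
        for n in p.names:
            p.set(n, 0.0 if n.startswith("kr") else p[n], relax_bounds=True)
        state = np.arange(1.0, 10.0)
        derivs = evaluate_rhs(m, state, p)
        dep = list(m.dependent_positions)
        dks = np.array([p[f"dk{d+1}"] for d in dep])
        assert np.allclose(derivs[dep], -dks * state[dep])

    def test_independent_derivatives_are_zero(self, models):
        rng = np.random.default_rng(0)
        for m in models.values():
            _, vals = random_parameters(m.parameter_template, rng)
            derivs = evaluate_rhs(m, rng.random(9) + 0.1, vals)
            assert derivs[7] == 0.0 and derivs[8] == 0.0

    def test_negative_state_rejected(self, models):
        m = models["mass_action"]
        state = np.ones(9)
        state[3] = -0.5
        with pytest.raises(ValueError, match="non-negative"):
            evaluate_rhs(m, state, m.parameter_template)

    def test_zero_state_fractional_exponent_is_finite(self, models):
        m = models["s_system"]
        p = m.parameter_template  # all kinetic orders default to 1.0
        p = p.with_values(p.values)
        p.values[p.index("h11")] = 0.5
        derivs = evaluate_rhs(m, np.zeros(9), p)
        assert np.all(np.isfinite(derivs))

    @pytest.mark.parametrize("formalism", ["s_system", "michaelis_menten", "mass_action"])
    def test_matches_literal_transcription(self, models, formalism):
        """Spot check against the independently coded printed equations."""
        m = models[formalism]
        oracle = LITERAL_RHS[formalism]
        rng = np.random.default_rng(42)
        for _ in range(200):
            pdict, vals = random_parameters(m.parameter_template, rng)
            state = rng.random(9) * 5 + 0.05
            got = evaluate_rhs(m, state, vals)
            want = oracle(state, pdict)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-12)


class TestLimits:
    def test_s_system_zero_orders_degenerates_to_constant_rates(self, models):
        m = models["s_system"]
        p = m.parameter_template.copy()
        for n in p.names:
            if n[0] in "gh":
                p.set(n, 0.0)
        rng = np.random.default_rng(7)
        state = rng.random(9) + 0.1
        derivs = evaluate_rhs(m, state, p)
        expected = np.array([p[f"alpha{d}"] - p[f"beta{d}"] for d in range(1, 8)])
        np.testing.assert_allclose(derivs[:7], expected, rtol=1e-12)

    def test_mm_saturates_to_vmax_as_km_vanishes(self, models):
        m = models["michaelis_menten"]
        p = m.parameter_template.copy()
        for n in p.names:
            if n.startswith("Km"):
                p.set(n, 1e-12, relax_bounds=True)
            elif n.startswith("dk"):
                p.set(n, 0.0, relax_bounds=True)
        state = np.full(9, 2.0)
        derivs = evaluate_rhs(m, state, p)
        expected = [p["Vm1"], p["Vm2"], p["Vm3"], p["Vm4a"] * p["Vm4b"],
                    p["Vm5"], p["Vm6"], p["Vm7"]]
        np.testing.assert_allclose(derivs[:7], expected, rtol=1e-9)
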