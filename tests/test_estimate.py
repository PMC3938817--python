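"""Objective function and the three optimizers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from floranet import Objective, fit_hooke_jeeves, fit_pso, weighted_sse
from floranet.estimate import (
    EPSettings,
    HJSettings,
    PSOSettings,
    SIMULATION_PENALTY,
    ep_minimize,
    hooke_jeeves_minimize,
    pso_minimize,
)


class TestObjective:
    def test_hand_evaluation(self):
        # one gene, X = (1, 2), Y = (1, 3): mean 1.5, w = 1/2.25, O = 1/2.25
        obs = np.array([[1.0], [2.0]])
        pred = np.array([[1.0], [3.0]])
        assert weighted_sse(obs, pred) == pytest.approx(0.4444444444, abs=1e-9)

    def test_zero_at_generating_parameters(self, models, ma_truth, ma_dense_panel):
        _, data = ma_dense_panel
        obj = Objective(models["mass_action"], data)
        assert obj(ma_truth) < 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(c=st.floats(0.01, 100.0))
    def test_per_gene_scale_invariance(self, c):
        rng = np.random.default_rng(0)
        obs = rng.random((5, 3)) + 0.5
        pred = obs + rng.normal(0, 0.1, obs.shape)
        scaled_obs, scaled_pred = obs.copy(), pred.copy()
        scaled_obs[:, 1] *= c
        scaled_pred[:, 1] *= c
        assert weighted_sse(scaled_obs, scaled_pred) == pytest.approx(
            weighted_sse(obs, pred), rel=1e-9
        )

    def test_failed_simulation_returns_finite_penalty(self, models, ma_dense_panel):
        _, data = ma_dense_panel
        obj = Objective(models["mass_action"], data)
        bad = np.full(15, 100.0)
        bad[8:] = 1e-6  # explosive synthesis, no decay
        assert obj(bad) == SIMULATION_PENALTY

    def test_species_mismatch_rejected(self, models, ma_dense_panel):
        _, data = ma_dense_panel
        with pytest.raises(ValueError, match="not present"):
            Objective(models["mass_action"], data, observed_species=("CO", "XYZ"))

    def test_needs_two_timepoints(self, models, ma_dense_panel):
        from floranet import TimeCourse

        _, data = ma_dense_panel
        single = TimeCourse(data.times[:1], data.species_labels,
                            data.values[:1], data.genotype)
        with pytest.raises(ValueError, match="2 time points"):
            Objective(models["mass_action"], single)


def _quadratic3():
    target = np.array([1.0, 2.0, 0.5])
    return (lambda x: float(np.sum((x - target) ** 2)),
            np.zeros(3), np.full(3, 5.0), target)


class TestPSO:
    def test_seeded_determinism_and_trace(self):
        f, lo, hi, _ = _quadratic3()
        a = pso_minimize(f, lo, hi, 5, PSOSettings(iterations=60))
        b = pso_minimize(f, lo, hi, 5, PSOSettings(iterations=60))
        np.testing.assert_array_equal(a[0], b[0])
        assert np.all(np.diff(a[2]) <= 0)  # trace non-increasing

    def test_refines_a_smooth_minimum(self):
        f, lo, hi, target = _quadratic3()
        best, fbest, *_ = pso_minimize(f, lo, hi, 1, PSOSettings(iterations=300))
        assert fbest < 1e-6
        assert np.all(best >= lo) and np.all(best <= hi)

    def test_empty_box_rejected(self):
        f, lo, hi, _ = _quadratic3()
        with pytest.raises(ValueError, match="empty bounds box"):
            pso_minimize(f, hi, lo, 0)

    def test_fit_result_contract(self, models, ma_dense_panel):
        _, data = ma_dense_panel
        m = models["mass_action"]
        r = fit_pso(m, data, seed=2, settings=PSOSettings(n_particles=10, iterations=15))
        assert r.optimizer == "pso" and r.seed == 2
        assert r.best_params.within_bounds()
        assert r.objective == pytest.approx(r.trace[-1])
        assert np.all(np.diff(r.trace) <= 0)
        assert r.evaluations == 10 * 16


class TestEP:
    def test_quadratic_to_analytic_minimum(self):
        f = lambda x: float((x[0] - 1.3) ** 2)
        best, fbest, *_ = ep_minimize(f, np.array([0.0]), np.array([5.0]), 3)
        assert abs(f(best) ) < 1e-6

    def test_seeded_determinism(self):
        f, lo, hi, _ = _quadratic3()
        a = ep_minimize(f, lo, hi, 4, EPSettings(generations=40))
        b = ep_minimize(f, lo, hi, 4, EPSettings(generations=40))
        np.testing.assert_array_equal(a[0], b[0])
        assert np.all(np.diff(a[2]) <= 0)

    def test_boundary_minimum_stays_in_box(self):
        # minimum outside the box: reflection must keep offspring inside
        f = lambda x: float(np.sum((x + 1.0) ** 2))
        lo, hi = np.zeros(2), np.ones(2)
        best, fbest, *_ = ep_minimize(f, lo, hi, 0, EPSettings(generations=60))
        assert np.all(best >= lo) and np.all(best <= hi)
        assert fbest == pytest.approx(2.0, rel=1e-3)


class TestHookeJeeves:
    def test_separable_quadratic(self):
        f, lo, hi, target = _quadratic3()
        best, fbest, _, _, converged, reason = hooke_jeeves_minimize(
            f, lo, hi, np.full(3, 2.5)
        )
        assert converged and "tolerance" in reason
        np.testing.assert_allclose(best, target, atol=1e-4)

    def test_start_at_minimum_returns_start(self):
        f, lo, hi, target = _quadratic3()
        best, fbest, *_ = hooke_jeeves_minimize(f, lo, hi, target)
        np.testing.assert_array_equal(best, target)
        assert fbest == 0.0

    def test_deterministic_without_seed(self):
        f, lo, hi, _ = _quadratic3()
        a = hooke_jeeves_minimize(f, lo, hi, np.full(3, 1.0))
        b = hooke_jeeves_minimize(f, lo, hi, np.full(3, 1.0))
        np.testing.assert_array_equal(a[0], b[0])

    def test_start_outside_bounds_rejected(self):
        f, lo, hi, _ = _quadratic3()
        with pytest.raises(ValueError, match="outside"):
            hooke_jeeves_minimize(f, lo, hi, np.full(3, 9.0))

    def test_fit_wrapper_defaults_to_box_center(self, models, ma_dense_panel):
        _, data = ma_dense_panel
        m = models["mass_action"]
        r = fit_hooke_jeeves(m, data, settings=HJSettings(max_evaluations=300))
        assert r.optimizer == "hooke_jeeves" and r.seed is None
        assert r.best_params.within_bounds()
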