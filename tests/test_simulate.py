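"""Forward integration and knockout perturbations."""

import numpy as np
import pytest

from floranet import (
    SimulationError,
    apply_knockout,
    integrate,
    knockout_initial_state,
)
from floranet.synthetic import default_initial_state


def _zeroed(template, prefixes):
    p = template.copy()
    for n in p.names:
        if any(n.startswith(pre) for pre in prefixes):
            p.set(n, 0.0, relax_bounds=True)
    return p


class TestIntegrate:
    def test_zero_rates_give_constant_trajectories(self, models):
        m = models["mass_action"]
        p = _zeroed(m.parameter_template, ("kr", "dk"))
        x0 = np.linspace(0.5, 4.5, 9)
        tc = integrate(m, p, x0, np.linspace(0, 7, 8))
        assert np.allclose(tc.values, x0[None, :])

    def test_single_gene_decay_matches_exponential(self, models):
        m = models["mass_action"]
        p = _zeroed(m.parameter_template, ("kr",))
        for d in range(1, 8):
            p.set(f"dk{d}", 1.0)
        t = np.linspace(0, 5, 11)
        tc = integrate(m, p, np.ones(9), t)
        for d0 in m.dependent_positions:
            np.testing.assert_allclose(tc.values[:, d0], np.exp(-t), rtol=1e-6, atol=1e-9)

    def test_matches_tighter_tolerance_reintegration(self, models, ss_truth):
        m = models["s_system"]
        x0 = default_initial_state()
        t = np.linspace(0, 7, 21)
        coarse = integrate(m, ss_truth, x0, t, rtol=1e-8, atol=1e-10)
        fine = integrate(m, ss_truth, x0, t, rtol=1e-9, atol=1e-11)
        np.testing.assert_allclose(coarse.values, fine.values, rtol=1e-6, atol=1e-9)

    def test_halving_tolerance_changes_little(self, models, ma_truth):
        m = models["mass_action"]
        x0 = default_initial_state()
        t = np.linspace(0, 7, 21)
        a = integrate(m, ma_truth, x0, t, rtol=1e-8, atol=1e-10)
        b = integrate(m, ma_truth, x0, t, rtol=5e-9, atol=5e-11)
        assert np.max(np.abs(a.values - b.values)) < 1e-6

    def test_independent_species_frozen(self, models, ss_truth):
        m = models["s_system"]
        x0 = default_initial_state()
        x0[7], x0[8] = 0.6, 1.7
        tc = integrate(m, ss_truth, x0, np.linspace(0, 7, 5))
        assert np.all(tc.values[:, 7] == 0.6)
        assert np.all(tc.values[:, 8] == 1.7)

    def test_blowup_reported_with_params(self, models):
        m = models["mass_action"]
        p = m.parameter_template.copy()
        for n in p.names:
            p.set(n, 100.0 if n.startswith("kr") else 1e-6)
        with pytest.raises(SimulationError) as err:
            integrate(m, p, np.ones(9), np.linspace(0, 7, 5), mxstep=2000)
        assert err.value.params is not None and len(err.value.params) == 15

    def test_input_validation(self, models):
        m = models["mass_action"]
        p = m.parameter_template
        with pytest.raises(ValueError, match="strictly increasing"):
            integrate(m, p, np.ones(9), [0.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="non-negative"):
            integrate(m, p, -np.ones(9), [0.0, 1.0])


class TestKnockout:
    def test_ft_knockout_silences_ft(self, models, ma_truth):
        m = models["mass_action"]
        _, ko, mask = apply_knockout(m, ma_truth, "FT")
        assert ko["kr2"] == 0.0
        x0 = knockout_initial_state(default_initial_state(), mask)
        tc = integrate(m, ko, x0, np.linspace(0, 7, 9))
        assert np.all(tc.column("FT") <= 1e-12)  # positivity floor

    def test_ft_knockout_lowers_complex_peak(self, models, ma_truth):
        m = models["mass_action"]
        x0 = default_initial_state()
        t = np.linspace(0, 7, 21)
        wt = integrate(m, ma_truth, x0, t)
        _, ko, mask = apply_knockout(m, ma_truth, "FT")
        kt = integrate(m, ko, knockout_initial_state(x0, mask), t)
        assert kt.column("FTFD_complex").max() < wt.column("FTFD_complex").max()

    def test_co_knockout_leaves_inputs_untouched(self, models, ma_truth):
        m = models["mass_action"]
        x0 = default_initial_state()
        t = np.linspace(0, 7, 9)
        wt = integrate(m, ma_truth, x0, t)
        _, ko, mask = apply_knockout(m, ma_truth, "CO")
        kt = integrate(m, ko, knockout_initial_state(x0, mask), t)
        np.testing.assert_array_equal(wt.column("PHYB"), kt.column("PHYB"))
        np.testing.assert_array_equal(wt.column("FD"), kt.column("FD"))

    def test_independent_knockout_rejected(self, models, ma_truth):
        with pytest.raises(ValueError, match="independent"):
            apply_knockout(models["mass_action"], ma_truth, "PHYB")

    @pytest.mark.parametrize("gene", ["CO", "FT"])
    def test_knockout_never_increases_downstream(self, models, ss_truth, gene):
        """All interactions are activating, so removing a gene can only lower
        every trajectory."""
        m = models["s_system"]
        x0 = default_initial_state()
        t = np.linspace(0, 7, 21)
        wt = integrate(m, ss_truth, x0, t)
        _, ko, mask = apply_knockout(m, ss_truth, gene)
        kt = integrate(m, ko, knockout_initial_state(x0, mask), t)
        assert np.all(kt.values <= wt.values + 1e-7)
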