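"""Cascade closed forms against hand-derived oracles and a numeric integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hostresponse import (ActivationParameters, EmaxLink, ValidationError,
                          activation_effect, emax_effect, pk_concentrations,
                          simulate_global, simulate_independent,
                          solve_linear_cascade, solve_linear_cascade_numeric)
from hostresponse.dynamics import cascade_stage2, cascade_stage3

rates = st.floats(min_value=0.01, max_value=10.0, allow_nan=False)


class TestClosedForms:
    def test_zero_initial_state_gives_zero_series(self, time_grid):
        traj = solve_linear_cascade(2.0, 0.5, 0.1, 0.0, time_grid)
        for s in traj.states.values():
            assert np.all(s == 0.0)

    def test_stage2_matches_biexponential_oracle(self, time_grid):
        # hand integration: C1 = A*k01/(k10-k01)*(e^{-k01 t} - e^{-k10 t})
        a, b, A = 3.0, 0.4, 2.5
        traj = solve_linear_cascade(a, b, 0.1, A, time_grid)
        oracle = A * a / (b - a) * (np.exp(-a * time_grid) - np.exp(-b * time_grid))
        np.testing.assert_allclose(traj.states["C1"], oracle, atol=1e-12)

    def test_equal_rates_stage3_is_quadratic_gamma_form(self, time_grid):
        # triple conv of identical exponentials: A*k*t^2/2*e^{-k t}, peak at 2/k
        k, A = 0.04, 1.7
        traj = solve_linear_cascade(k, k, k, A, time_grid)
        oracle = A * k * time_grid**2 / 2 * np.exp(-k * time_grid)
        np.testing.assert_allclose(traj.states["C2"], oracle, atol=1e-12)
        assert time_grid[np.argmax(traj.states["C2"])] == pytest.approx(2 / k, abs=1.0)

    @pytest.mark.parametrize("k01,k10,k20", [
        (6.0, 0.6, 0.06),      # all distinct
        (0.04, 0.04, 0.04),    # fully repeated eigenvalue
        (0.5, 0.5, 0.1),       # first pair repeated
        (0.5, 0.1, 0.5),       # outer pair repeated
        (0.1, 0.5, 0.5),       # last pair repeated
    ])
    def test_closed_form_agrees_with_numeric_integrator(self, k01, k10, k20, time_grid):
        a = solve_linear_cascade(k01, k10, k20, 1.0, time_grid)
        b = solve_linear_cascade_numeric(k01, k10, k20, 1.0, time_grid)
        for name in ("C0", "C1", "C2"):
            np.testing.assert_allclose(a.states[name], b.states[name], atol=1e-6)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(a=rates, b=rates, c=rates)
    def test_cascade_is_nonnegative_and_matches_numeric(self, a, b, c):
        t = np.linspace(0.0, 50.0, 26)
        closed = solve_linear_cascade(a, b, c, 1.0, t)
        assert np.all(closed.states["C2"] >= -1e-12)
        num = solve_linear_cascade_numeric(a, b, c, 1.0, t)
        np.testing.assert_allclose(closed.states["C2"], num.states["C2"], atol=1e-6)

    def test_stage_functions_continuous_at_rate_coincidence(self):
        t = np.linspace(0.0, 100.0, 51)
        near = cascade_stage3(0.1, 0.1 * (1 + 5e-8), 0.3, t)
        exact = cascade_stage3(0.1, 0.1, 0.3, t)
        np.testing.assert_allclose(near, exact, atol=1e-7)
        np.testing.assert_allclose(cascade_stage2(0.2, 0.2 * (1 + 5e-8), t),
                                   cascade_stage2(0.2, 0.2, t), atol=1e-7)


class TestPKConcentrations:
    def test_zero_dose_gives_zero_concentrations(self, truth, time_grid):
        traj = pk_concentrations(truth.pk, 0.06, 0.0, time_grid)
        for s in traj.states.values():
            assert np.all(s == 0.0)

    def test_linearity_in_dose(self, truth, time_grid):
        lo = pk_concentrations(truth.pk, 0.06, 5.0, time_grid)
        hi = pk_concentrations(truth.pk, 0.06, 10.0, time_grid)
        np.testing.assert_allclose(hi.states["C2"], 2 * lo.states["C2"], rtol=1e-9)

    def test_initial_condition_is_dose_over_vd(self, truth):
        traj = pk_concentrations(truth.pk, 0.06, 25.0, np.array([0.0, 1.0]))
        assert traj.states["C0"][0] == pytest.approx(25.0 / truth.pk.vd)

    def test_delegates_to_cascade(self, truth, time_grid):
        traj = pk_concentrations(truth.pk, 0.06, 25.0, time_grid)
        ref = solve_linear_cascade(truth.pk.k01, truth.pk.k10, 0.06,
                                   25.0 / truth.pk.vd, time_grid)
        np.testing.assert_allclose(traj.states["C2"], ref.states["C2"], rtol=1e-12)


class TestEffectLinks:
    link = EmaxLink(epsilon=1.0, emax=3.0, ec50=2.0, gamma=1.0)

    def test_zero_driver_returns_baseline_exactly(self):
        assert emax_effect(self.link, np.array([0.0]))[0] == 1.0

    def test_half_effect_at_ec50(self):
        # Hill midpoint: eps=1, emax=3, C=EC50 -> (1+3)/2 = 2
        assert emax_effect(self.link, np.array([2.0]))[0] == pytest.approx(2.0)

    def test_larger_hill_coefficient_sharpens_saturation(self):
        sharp = EmaxLink(1.0, 3.0, 2.0, 8.0)
        at2x = lambda l: emax_effect(l, np.array([4.0]))[0]
        assert at2x(sharp) > at2x(self.link)

    def test_effect_bounded_and_monotone(self):
        driver = np.linspace(0, 50, 200)
        e = emax_effect(self.link, driver)
        assert np.all(e >= 1.0) and np.all(e < 3.0)
        assert np.all(np.diff(e) >= 0)

    def test_negative_driver_rejected(self):
        with pytest.raises(ValidationError):
            emax_effect(self.link, np.array([-0.1]))


class TestActivationEffect:
    act = ActivationParameters(ed50=7.0, gamma=4.0, efficacy=3.7, epsilon=8.0,
                               k2=0.04)

    def test_zero_dose_flat_baseline(self, time_grid):
        e = activation_effect(self.act, 0.0, time_grid)
        np.testing.assert_allclose(e, 8.0)

    def test_dose_time_separability(self, time_grid):
        # (E(t,D) - eps) factorizes: ratio across doses constant over time
        e1 = activation_effect(self.act, 10.0, time_grid[1:]) - 8.0
        e2 = activation_effect(self.act, 25.0, time_grid[1:]) - 8.0
        ratio = e1 / e2
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_peak_time_is_2_over_k2_for_any_dose(self):
        t = np.linspace(0, 200, 2001)
        for dose in (5.0, 10.0, 25.0):
            e = activation_effect(self.act, dose, t)
            assert t[np.argmax(e)] == pytest.approx(2 / 0.04, abs=0.2)

    def test_independent_form_starts_at_zero(self):
        ind = ActivationParameters(ed50=7.0, gamma=4.0, efficacy=2.0,
                                   epsilon=1.0, emax=5.0,
                                   k01=6.0, k10=0.6, k20=0.05)
        e = activation_effect(ind, 25.0, np.array([0.0, 24.0]))
        assert e[0] == 0.0 and e[1] > 0.0


class TestSimulateFamilies:
    def test_pk_based_zero_dose_flat_baseline(self, truth, time_grid):
        e = simulate_independent("pk_based",
                                 (truth.pk, truth.migration_link, truth.k20_m),
                                 0.0, time_grid)
        np.testing.assert_allclose(e, truth.migration_link.epsilon)

    def test_activation_saturates_above_threshold(self, truth, time_grid):
        # doses far above ED50 with a steep Hill give near-identical curves
        a = simulate_independent("activation_based", truth.invasion, 50.0, time_grid)
        b = simulate_independent("activation_based", truth.invasion, 100.0, time_grid)
        assert np.max(np.abs(a - b)) < 1e-3 * np.max(a - truth.invasion.epsilon)

    def test_pk_based_duration_grows_with_dose(self, truth):
        # time above a fixed level keeps growing with dose (no saturation of
        # duration), unlike the activation family
        t = np.linspace(0, 200, 2001)
        level = 0.5 * (truth.migration_link.emax + truth.migration_link.epsilon)
        durations = []
        for dose in (10.0, 25.0, 50.0):
            e = simulate_independent(
                "pk_based", (truth.pk, truth.migration_link, truth.k20_m), dose, t)
            durations.append(np.count_nonzero(e > level))
        assert durations[0] < durations[1] < durations[2]

    def test_unknown_family_rejected(self, truth, time_grid):
        with pytest.raises(ValidationError):
            simulate_independent("kinetic", truth.invasion, 1.0, time_grid)


class TestSimulateGlobal:
    def test_zero_dose_gives_all_baselines(self, truth, time_grid):
        traj = simulate_global(truth, 0.0, time_grid)
        np.testing.assert_allclose(traj.effects["migration"], 10.0)
        np.testing.assert_allclose(traj.effects["cep"], 55.0)
        np.testing.assert_allclose(traj.effects["invasion"], 8.0)

    def test_matches_independent_submodels(self, truth, time_grid):
        traj = simulate_global(truth, 25.0, time_grid)
        mig = simulate_independent("pk_based",
                                   (truth.pk, truth.migration_link, truth.k20_m),
                                   25.0, time_grid)
        cep = simulate_independent("pk_based",
                                   (truth.pk, truth.cep_link, truth.k20_c),
                                   25.0, time_grid)
        inv = simulate_independent("activation_based", truth.invasion, 25.0,
                                   time_grid)
        assert np.max(np.abs(traj.effects["migration"] - mig)) <= 1e-9
        assert np.max(np.abs(traj.effects["cep"] - cep)) <= 1e-9
        assert np.max(np.abs(traj.effects["invasion"] - inv)) <= 1e-9

    def test_m1_ties_make_migration_and_cep_share_hill_argument(self, time_grid):
        import dataclasses
        from hostresponse import default_true_params
        base = default_true_params()
        m1 = dataclasses.replace(base, k20_c=base.k20_m, variant="M1")
        traj = simulate_global(m1, 25.0, time_grid)
        # same driver and EC50: effects are affine transforms of each other
        h_m = (traj.effects["migration"] - 10.0) / (45.0 - 10.0)
        h_c = (traj.effects["cep"] - 55.0) / (260.0 - 55.0)
        np.testing.assert_allclose(h_m, h_c, atol=1e-12)

    def test_tie_violation_rejected(self, truth):
        import dataclasses
        with pytest.raises(ValidationError, match="M1"):
            dataclasses.replace(truth, variant="M1")
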