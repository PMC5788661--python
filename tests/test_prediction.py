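"""Effect surfaces, threshold diagnostics, rebaselining and point predictions."""

import numpy as np
import pytest

from hostresponse import (ValidationError, duration_above, effect_surface,
                          predict_condition, rebaseline,
                          separability_diagnostic, simulate_global,
                          threshold_profile)


@pytest.fixture(scope="module")
def surface(truth):
    return effect_surface(truth)  # default 26 x 201 grid


class TestEffectSurface:
    def test_zero_dose_row_is_flat_baseline(self, surface, truth):
        for r, eps in truth.baselines.items():
            np.testing.assert_allclose(surface.values[r][0], eps)

    def test_deterministic(self, truth, surface):
        again = effect_surface(truth)
        for r in surface.values:
            assert np.array_equal(surface.values[r], again.values[r])

    def test_negative_dose_range_rejected(self, truth):
        with pytest.raises(ValidationError):
            effect_surface(truth, dose_range=(-1.0, 25.0))


class TestThresholdProfile:
    def test_activation_threshold_is_duration_independent(self, surface):
        curve = threshold_profile(surface, 0.5, readout="invasion")
        vals = curve[np.isfinite(curve)]
        assert len(vals) > 100
        assert np.std(vals) / np.mean(vals) < 0.01

    def test_activation_threshold_sits_at_ed50(self, surface):
        # steep Hill on dose: half-max onset threshold ~ ED50 = 7 mg/kg
        curve = threshold_profile(surface, 0.5, readout="invasion")
        vals = curve[np.isfinite(curve)]
        assert np.median(vals) == pytest.approx(7.0, abs=1.0)

    def test_pk_threshold_drifts_with_time(self, surface):
        curve = threshold_profile(surface, 0.5, readout="migration")
        vals = curve[np.isfinite(curve)]
        assert np.std(vals) / np.mean(vals) > 0.05
        # monotone non-decreasing once past the concentration peak
        late = curve[np.isfinite(curve)][5:]
        assert np.all(np.diff(late) >= 0)

    def test_family_diagnostics_are_mutually_exclusive(self, surface):
        inv = separability_diagnostic(surface, "invasion")
        mig = separability_diagnostic(surface, "migration")
        assert inv["separable"] and not mig["separable"]

    def test_all_baseline_surface_gives_nan_curve(self, truth):
        flat = effect_surface(truth, dose_range=(0.0, 25.0),
                              time_range=(0.0, 200.0))
        for r in flat.values:
            flat.values[r][:] = truth.baselines[r]
        curve = threshold_profile(flat, 0.5)
        for r, c in curve.items():
            assert np.all(np.isnan(c))

    def test_level_outside_unit_interval_rejected(self, surface):
        with pytest.raises(ValidationError):
            threshold_profile(surface, 1.5)


class TestDurationAbove:
    def test_pk_duration_grows_with_dose(self, truth):
        d = duration_above(truth, "migration", [10.0, 17.0, 25.0])
        assert d[0] < d[1] < d[2]

    def test_activation_duration_dose_independent(self, truth):
        d = duration_above(truth, "invasion", [10.0, 17.0, 25.0])
        assert np.ptp(d) <= 0.5  # within grid resolution


class TestRebaseline:
    controls = {"cep": 60.0, "migration": 12.0, "invasion": 9.0}

    def test_identity_when_controls_equal_current(self, truth):
        same = {"cep": 55.0, "migration": 10.0, "invasion": 8.0}
        assert rebaseline(truth, same) == truth

    def test_only_baselines_change(self, truth):
        new = rebaseline(truth, self.controls)
        assert new.baselines == self.controls
        assert new.invasion.k2 == truth.invasion.k2
        assert new.migration_link.ec50 == truth.migration_link.ec50
        assert new.k20_c == truth.k20_c

    def test_invasion_effect_minus_baseline_invariant(self, truth, time_grid):
        new = rebaseline(truth, self.controls)
        before = simulate_global(truth, 15.0, time_grid).effects["invasion"] - 8.0
        after = simulate_global(new, 15.0, time_grid).effects["invasion"] - 9.0
        np.testing.assert_allclose(before, after, atol=1e-12)

    def test_emax_readouts_start_at_new_baseline(self, truth):
        new = rebaseline(truth, self.controls)
        pred = predict_condition(new, 0.0, 24.0)
        assert pred["migration"] == 12.0 and pred["cep"] == 60.0

    def test_missing_readout_rejected(self, truth):
        with pytest.raises(ValidationError, match="invasion"):
            rebaseline(truth, {"cep": 1.0, "migration": 2.0})


class TestPredictCondition:
    def test_zero_dose_returns_baselines(self, truth):
        assert predict_condition(truth, 0.0, 137.0) == truth.baselines

    def test_consistent_with_surface_grid_point(self, truth, surface):
        # (10 mg/kg, 50 h) is an exact grid point of the default surface
        pred = predict_condition(truth, 10.0, 50.0)
        i = np.where(surface.dose_grid == 10.0)[0][0]
        j = np.where(surface.time_grid == 50.0)[0][0]
        for r in pred:
            assert abs(pred[r] - surface.values[r][i, j]) <= 1e-9

    def test_validation_conditions_show_family_contrast(self, truth):
        # ED50 < 15 mg/kg while the PK-driven effects have decayed by 72 h:
        # invasion elevated at both conditions, Hill readouts only at (25, 24)
        early = predict_condition(truth, 25.0, 24.0)
        late = predict_condition(truth, 15.0, 72.0)
        eps = truth.baselines
        assert late["invasion"] - eps["invasion"] > 10.0
        assert early["invasion"] - eps["invasion"] > 10.0
        assert late["migration"] - eps["migration"] < 1.0
        assert late["cep"] - eps["cep"] < 1.0
        assert early["migration"] - eps["migration"] > 20.0
        assert early["cep"] - eps["cep"] > 100.0
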