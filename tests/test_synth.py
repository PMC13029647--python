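"""Synthetic-data generator: determinism, noise-free exactness, round-trip recovery."""

from dataclasses import replace

import numpy as np
import pytest

from coleach import (
    SyntheticScenario,
    fe2_depletion_time,
    fit_mu2_constant,
    lag_phase_duration,
    time_to_threshold,
)
from coleach.growth import CellCountSeries
from coleach.synth import (
    generate_batch_run,
    generate_constant_mu2_pair,
    generate_continuous_cascade,
    mu2_of_exposure,
)


class TestToxicityResponse:
    def test_benign_below_threshold(self, default_scenario):
        assert mu2_of_exposure(0.0, default_scenario) == default_scenario.mu_base
        assert mu2_of_exposure(default_scenario.X_tox, default_scenario) == 0.0

    def test_net_death_above_threshold(self, default_scenario):
        assert mu2_of_exposure(35.5, default_scenario) < -1.0

    def test_monotone_nonincreasing(self, default_scenario):
        vals = [mu2_of_exposure(x, default_scenario) for x in np.linspace(0, 40, 50)]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))


class TestContinuousCascade:
    def test_same_seed_identical_outputs(self):
        a = generate_continuous_cascade(SyntheticScenario(seed=5))
        b = generate_continuous_cascade(SyntheticScenario(seed=5))
        np.testing.assert_array_equal(a.experimental_counts.counts,
                                      b.experimental_counts.counts)
        assert a.abundance.data.equals(b.abundance.data)

    def test_different_seed_differs(self):
        a = generate_continuous_cascade(SyntheticScenario(seed=5))
        b = generate_continuous_cascade(SyntheticScenario(seed=6))
        assert not np.array_equal(a.experimental_counts.counts,
                                  b.experimental_counts.counts)

    def test_noise_free_counts_equal_closed_form(self):
        sc = SyntheticScenario(seed=0, count_noise_cv=0.0)
        bundle = generate_continuous_cascade(sc)
        np.testing.assert_array_equal(bundle.experimental_counts.counts, bundle.x2_true)
        np.testing.assert_array_equal(bundle.control_counts.counts,
                                      np.full(len(bundle.x2_true), sc.X1_steady))

    def test_series_invariants_hold(self, cascade_bundle):
        for series in (cascade_bundle.control_series, cascade_bundle.experimental_series):
            assert np.all(np.diff(series.times) > 0)
            np.testing.assert_allclose(series.fe_total, series.fe2 + series.fe3)

    def test_abundance_rows_sum_to_100(self, cascade_bundle):
        table = cascade_bundle.abundance
        totals = table.data[table.genera].sum(axis=1)
        np.testing.assert_allclose(totals, 100.0)

    def test_programmed_community_response_direction(self, cascade_bundle):
        """Suppressed genera fall and favoured genera rise with exposure."""
        df = cascade_bundle.abundance.data
        exp = df[df.reactor == "experimental"].sort_values("day")
        assert exp["Ferroplasma"].iloc[-1] < exp["Ferroplasma"].iloc[0]
        assert exp["Leptospirillum"].iloc[-1] > exp["Leptospirillum"].iloc[0]

    def test_stage3_window_fit_detects_net_death(self):
        """Fitting the final window recovers mu2 < 0 when X_tox is exceeded."""
        negatives = 0
        n_rep = 20
        for seed in range(n_rep):
            bundle = generate_continuous_cascade(SyntheticScenario(seed=seed))
            keep = bundle.experimental_counts.times >= 22
            exp = CellCountSeries(
                bundle.experimental_counts.times[keep],
                bundle.experimental_counts.counts[keep],
                "experimental",
            )
            ctrl = bundle.control_counts
            fit = fit_mu2_constant(ctrl, exp, 0.2, n_boot=0)
            negatives += fit.mu2 < 0
        assert negatives >= 0.95 * n_rep


class TestConstantMu2Pair:
    def test_deterministic(self):
        a = generate_constant_mu2_pair(-0.5, seed=9)
        b = generate_constant_mu2_pair(-0.5, seed=9)
        np.testing.assert_array_equal(a[1].counts, b[1].counts)

    def test_noise_free_matches_closed_form(self):
        sc = SyntheticScenario(seed=0, count_noise_cv=0.0)
        _, exp = generate_constant_mu2_pair(-1.07, scenario=sc)
        from coleach import CascadeParams, analytic_X2
        p = CascadeParams(D=sc.D, mu1=sc.D, mu2=-1.07, X1_0=sc.X1_steady, X2_0=sc.X2_0)
        np.testing.assert_array_equal(exp.counts, analytic_X2(exp.times, p))


class TestBatchRun:
    def test_programmed_lag_recovered(self, default_scenario):
        series = generate_batch_run(default_scenario)
        lag = lag_phase_duration(series)
        assert abs(lag - default_scenario.lag_days) <= default_scenario.batch_interval

    def test_programmed_fe2_depletion_recovered(self, default_scenario):
        series = generate_batch_run(default_scenario)
        t = fe2_depletion_time(series, lod=default_scenario.fe_lod)
        assert abs(t - default_scenario.fe2_depletion_day) <= default_scenario.batch_interval

    def test_programmed_threshold_crossings_recovered(self, default_scenario):
        series = generate_batch_run(default_scenario)
        t_ph = time_to_threshold(series, "pH", default_scenario.ph_reference, "falling")
        t_eh = time_to_threshold(series, "Eh", default_scenario.eh_reference, "rising")
        assert abs(t_ph - default_scenario.ph_cross_day) <= default_scenario.batch_interval
        assert abs(t_eh - default_scenario.eh_cross_day) <= default_scenario.batch_interval

    def test_plateau_reaches_carrying_capacity(self):
        sc = replace(SyntheticScenario(seed=2), batch_horizon=40.0)
        series = generate_batch_run(sc)
        assert series.cells[-1] == pytest.approx(sc.carrying_capacity, rel=0.3)

    def test_fe_total_enforced(self, default_scenario):
        series = generate_batch_run(default_scenario)
        np.testing.assert_allclose(series.fe_total, series.fe2 + series.fe3)

    def test_noise_free_mode_is_smooth(self, default_scenario):
        series = generate_batch_run(default_scenario, noise=False)
        assert series.pH[0] == default_scenario.ph_initial
        assert np.all(np.diff(series.pH) <= 1e-12)  # monotone decline


def test_invalid_scenario_rejected():
    with pytest.raises(ValueError):
        SyntheticScenario(count_noise_cv=-0.1)
    with pytest.raises(ValueError):
        SyntheticScenario(ph_cross_day=5.0, lag_days=12.0)
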