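"""Growth-rate estimation: pointwise balances and the global constant-mu2 fit."""

import numpy as np
import pytest

from coleach import (
    CellCountSeries,
    analytic_X2,
    estimate_mu1,
    estimate_mu2_pointwise,
    fit_mu2_constant,
)
from coleach.synth import generate_constant_mu2_pair


def make_series(times, counts, reactor="control"):
    return CellCountSeries(np.asarray(times, float), np.asarray(counts, float), reactor)


class TestMu1:
    def test_chemostat_steady_series_returns_D(self):
        s = make_series(np.arange(10) * 2.0, np.full(10, 180.0))
        np.testing.assert_allclose(estimate_mu1(s, 0.2), 0.2)

    def test_exponential_series_returns_D_plus_rate(self):
        g = 0.15
        t = np.arange(0, 10, 0.01)
        s = make_series(t, 50.0 * np.exp(g * t))
        np.testing.assert_allclose(estimate_mu1(s, 0.2), 0.2 + g, rtol=1e-4)

    def test_noisy_steady_series_mean_near_D(self):
        rng = np.random.default_rng(11)
        means = []
        for _ in range(20):
            counts = 200.0 * np.exp(rng.normal(0, 0.1, 14))
            s = make_series(np.arange(14) * 2.5, counts)
            means.append(np.mean(estimate_mu1(s, 0.2)))
        assert abs(np.mean(means) - 0.2) < 0.05

    def test_zero_count_rejected(self):
        s = make_series([0, 1, 2], [5.0, 0.0, 5.0])
        with pytest.raises(ValueError):
            estimate_mu1(s, 0.2)


class TestMu2Pointwise:
    def test_equal_constant_series_gives_zero(self):
        t = np.arange(8) * 2.0
        control = make_series(t, np.full(8, 120.0))
        exp = make_series(t, np.full(8, 120.0), "experimental")
        _, mu2 = estimate_mu2_pointwise(control, exp, 0.2)
        np.testing.assert_allclose(mu2, 0.0, atol=1e-12)

    def test_direct_substitution(self):
        # X2 constant = 50, X1 = 100, D = 0.2 -> mu2 = (0 - 20 + 10)/50 = -0.2
        t = np.arange(8) * 2.0
        control = make_series(t, np.full(8, 100.0))
        exp = make_series(t, np.full(8, 50.0), "experimental")
        _, mu2 = estimate_mu2_pointwise(control, exp, 0.2)
        np.testing.assert_allclose(mu2, -0.2)

    def test_recovers_constant_mu2_from_dense_trajectory(self, toxic_params, dense_times):
        """Noise-free dense sampling recovers the generating mu2 = -1.07."""
        x2 = analytic_X2(dense_times, toxic_params)
        control = make_series(dense_times, np.full_like(dense_times, toxic_params.X1_0))
        exp = make_series(dense_times, x2, "experimental")
        _, mu2 = estimate_mu2_pointwise(control, exp, toxic_params.D)
        assert np.max(np.abs(mu2 - toxic_params.mu2)) < 0.05

    def test_error_shrinks_with_step(self, toxic_params):
        errs = []
        for dt in (1.0, 0.5, 0.25):
            t = np.arange(0, 20 + 1e-9, dt)
            x2 = analytic_X2(t, toxic_params)
            control = make_series(t, np.full_like(t, toxic_params.X1_0))
            exp = make_series(t, x2, "experimental")
            _, mu2 = estimate_mu2_pointwise(control, exp, toxic_params.D)
            errs.append(np.max(np.abs(mu2 - toxic_params.mu2)))
        assert errs[2] < errs[1] < errs[0]

    def test_nonoverlapping_grids_rejected(self):
        control = make_series([0, 1, 2], [1, 1, 1])
        exp = make_series([10, 11, 12], [1, 1, 1], "experimental")
        with pytest.raises(ValueError, match="overlap"):
            estimate_mu2_pointwise(control, exp, 0.2)

    def test_zero_counts_floored_with_warning(self):
        t = np.arange(6) * 2.0
        control = make_series(t, np.full(6, 100.0))
        exp = make_series(t, [50, 20, 5, 1, 0, 0], "experimental")
        with pytest.warns(UserWarning, match="floored"):
            estimate_mu2_pointwise(control, exp, 0.2)


class TestMu2Fit:
    def test_noise_free_self_consistency(self, toxic_params):
        t = np.arange(12) * 2.5
        p = toxic_params
        for mu2_true in (-0.5, -1.07, 0.1):
            x2 = analytic_X2(t, type(p)(D=p.D, mu1=p.D, mu2=mu2_true,
                                        X1_0=p.X1_0, X2_0=p.X2_0))
            control = make_series(t, np.full_like(t, p.X1_0))
            exp = make_series(t, x2, "experimental")
            fit = fit_mu2_constant(control, exp, p.D, n_boot=0)
            assert fit.mu2 == pytest.approx(mu2_true, abs=1e-6)

    def test_identical_series_give_mu2_near_zero(self):
        t = np.arange(12) * 2.5
        control = make_series(t, np.full(12, 200.0))
        exp = make_series(t, np.full(12, 200.0), "experimental")
        fit = fit_mu2_constant(control, exp, 0.2, n_boot=0)
        assert fit.mu2 == pytest.approx(0.0, abs=1e-6)

    def test_sign_fidelity_under_noise(self):
        """Data generated below the upstream level yields a negative fit."""
        for seed in range(10):
            control, exp = generate_constant_mu2_pair(-1.07, seed=seed)
            fit = fit_mu2_constant(control, exp, 0.2, n_boot=0)
            assert fit.mu2 < 0

    def test_bootstrap_half_width_is_seeded_and_positive(self):
        control, exp = generate_constant_mu2_pair(-0.5, seed=3)
        fit_a = fit_mu2_constant(control, exp, 0.2, n_boot=50, seed=42)
        fit_b = fit_mu2_constant(control, exp, 0.2, n_boot=50, seed=42)
        assert fit_a.half_width == fit_b.half_width > 0

    def test_too_few_points_rejected(self):
        control = make_series([0, 1, 2], [1, 1, 1])
        exp = make_series([0, 1, 2], [1, 1, 1], "experimental")
        with pytest.raises(ValueError, match="4"):
            fit_mu2_constant(control, exp, 0.2)
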