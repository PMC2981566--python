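import numpy as np
import pytest

from tvorsim.chair_kinematics import StimulusProtocol, make_trapezoid_profile
from tvorsim.exceptions import InsufficientDataError
from tvorsim.linear_fit import (
    DEFAULT_LATENCY_GRID,
    LinearFitResult,
    compare_epochs,
    fit_linear_model,
    robust_regress,
)
from tvorsim.synthetic_data import EyeTrace, Trial


def constructed_trial(g_v=2.0, g_a=0.05, delta_t=0.030, mask=None, meta=None):
    """Trial whose eye velocity is exactly the delayed linear combination."""
    chair = make_trapezoid_profile(StimulusProtocol(), dt=0.002, pad_before=0.1, pad_after=0.4)
    te = np.arange(0.0, chair.time[-1], 0.001)
    v = np.interp(te - delta_t, chair.time, chair.velocity, left=0.0)
    a = np.interp(te - delta_t, chair.time, chair.acceleration, left=0.0)
    omega = g_v * v + g_a * a
    m = np.zeros(len(te), bool) if mask is None else mask
    eye = EyeTrace(te, np.cumsum(omega) * 0.001, omega, m)
    return Trial(chair, eye, meta=dict(meta or {}))


class TestFitLinearModel:
    def test_noiseless_recovery_to_machine_precision(self):
        fit = fit_linear_model([constructed_trial()])
        assert fit.g_v == pytest.approx(2.0, rel=1e-9)
        assert fit.g_a == pytest.approx(0.05, rel=1e-9)
        assert fit.delta_t == pytest.approx(0.030, abs=1e-12)
        assert fit.residual_ss < 1e-15

    def test_zero_response_gives_zero_coefficients(self):
        trial = constructed_trial(g_v=0.0, g_a=0.0)
        fit = fit_linear_model([trial])
        assert fit.g_v == 0.0
        assert fit.g_a == 0.0

    def test_both_terms_needed(self):
        """Velocity-only and acceleration-only fits leave strictly more
        residual than the full two-term model."""
        trial = constructed_trial()
        full = fit_linear_model([trial])
        vel_only = fit_linear_model([trial], regressors="velocity")
        acc_only = fit_linear_model([trial], regressors="acceleration")
        assert full.residual_ss < vel_only.residual_ss
        assert full.residual_ss < acc_only.residual_ss

    def test_best_latency_beats_all_other_grid_points(self, noiseless_trial):
        """On forward-model data the selected latency has the global minimum
        residual over the grid (the plant lag is partly absorbed by delta_t)."""
        best = fit_linear_model([noiseless_trial])
        for delta_t in DEFAULT_LATENCY_GRID:
            if delta_t == best.delta_t:
                continue
            other = fit_linear_model([noiseless_trial], latency_grid=[delta_t])
            assert best.residual_ss <= other.residual_ss

    def test_masking_saccades_reduces_per_sample_residual(self):
        trial = constructed_trial()
        # corrupt a window with a large pulse and flag it
        vel = trial.eye.velocity.copy()
        idx = slice(300, 340)
        vel[idx] += 150.0
        mask = np.zeros(len(vel), bool)
        mask[idx] = True
        corrupted = Trial(
            trial.chair, EyeTrace(trial.eye.time, trial.eye.position, vel, mask), meta={}
        )
        unmasked_variant = Trial(
            trial.chair,
            EyeTrace(trial.eye.time, trial.eye.position, vel, np.zeros(len(vel), bool)),
            meta={},
        )
        fit_masked = fit_linear_model([corrupted])
        fit_unmasked = fit_linear_model([unmasked_variant])
        assert fit_masked.residual_ss / fit_masked.n_samples <= (
            fit_unmasked.residual_ss / fit_unmasked.n_samples
        )

    def test_mixed_conditions_rejected(self):
        t1 = constructed_trial(meta={"direction": "left"})
        t2 = constructed_trial(meta={"direction": "right"})
        with pytest.raises(ValueError):
            fit_linear_model([t1, t2])

    def test_insufficient_unmasked_samples(self):
        trial = constructed_trial()
        mask = np.ones(len(trial.eye.time), bool)
        mask[:5] = False
        starved = Trial(
            trial.chair,
            EyeTrace(trial.eye.time, trial.eye.position, trial.eye.velocity, mask),
            meta={},
        )
        with pytest.raises(InsufficientDataError):
            fit_linear_model([starved])


class TestRobustRegress:
    def test_exact_linear_data_recovered_exactly(self, rng):
        X = rng.normal(size=(200, 2))
        beta = np.array([1.5, -0.7])
        out = robust_regress(X, X @ beta)
        np.testing.assert_allclose(out, beta, rtol=1e-12)

    def test_matches_ols_on_clean_gaussian_noise(self, rng):
        n = 10_000
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([2.0, 0.5])
        y = X @ beta + rng.normal(scale=1.0, size=n)
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rob = robust_regress(X, y)
        se = 1.0 / np.sqrt(n)  # unit-variance regressors, unit noise
        assert np.abs(rob - ols).max() < 2 * se

    def test_resists_gross_outliers(self, rng):
        """With 5% outliers at 10x the noise scale, the Huber estimate keeps
        <20% of the bias the outliers induce in OLS."""
        n = 10_000
        X = np.column_stack([rng.normal(size=n), rng.normal(size=n)])
        beta = np.array([2.0, 0.5])
        y = X @ beta + rng.normal(scale=1.0, size=n)
        bad = rng.choice(n, size=n // 20, replace=False)
        y[bad] += 10.0 * X[bad, 0]  # leverage-aligned gross errors
        ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        rob = robust_regress(X, y)
        ols_bias = np.abs(ols - beta)
        rob_bias = np.abs(rob - beta)
        assert rob_bias[0] < 0.2 * ols_bias[0]

    def test_singular_design_rejected(self, rng):
        x = rng.normal(size=100)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(np.linalg.LinAlgError):
            robust_regress(X, x)


class TestCompareEpochs:
    def _fit(self, g_v, g_a, direction="left"):
        return LinearFitResult(
            g_v, g_a, 0.03, 0.0, 100, meta={"animal": "M1", "direction": direction}
        )

    def test_identical_epochs_give_unit_ratios(self):
        pre = [self._fit(0.4, 0.02), self._fit(0.5, 0.03, "right")]
        post = [self._fit(0.4, 0.02), self._fit(0.5, 0.03, "right")]
        cmp = compare_epochs(pre, post)
        np.testing.assert_allclose(cmp.table["gv_ratio"], 1.0)
        assert cmp.summary["g_v"]["t"] == 0.0

    def test_mean_ratio_arithmetic(self):
        ratios = [0.4, 0.5, 0.45, 0.5]
        pre = [self._fit(1.0, 1.0, d) for d in ("a", "b", "c", "d")]
        post = [self._fit(r, r, d) for r, d in zip(ratios, ("a", "b", "c", "d"))]
        cmp = compare_epochs(pre, post)
        assert cmp.summary["g_v"]["mean_ratio"] == pytest.approx(0.4625)

    def test_halved_generating_gain_recovered_in_ratio(self):
        pre = [
            fit_linear_model([constructed_trial(g_v=2.0, g_a=0.05, meta={"direction": d})])
            for d in ("left", "right")
        ]
        post = [
            fit_linear_model([constructed_trial(g_v=1.0, g_a=0.05, meta={"direction": d})])
            for d in ("left", "right")
        ]
        cmp = compare_epochs(pre, post)
        assert cmp.summary["g_v"]["mean_ratio"] == pytest.approx(0.5, rel=1e-6)
        assert cmp.summary["g_a"]["mean_ratio"] == pytest.approx(1.0, rel=1e-6)

    def test_mismatched_conditions_rejected(self):
        with pytest.raises(ValueError):
            compare_epochs([self._fit(1, 1)], [self._fit(1, 1, direction="right")])
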