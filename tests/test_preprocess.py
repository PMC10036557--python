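"""Normalization, log transform, EB batch correction and QC estimators."""

import numpy as np
import pandas as pd
import pytest

import glycovar as gv
from glycovar.peaktable import PeakTable
from glycovar.preprocess import (apply_batch_model, correct_batch_effects, cv,
                                 log_transform, measurement_error_replicates,
                                 measurement_error_standards,
                                 normalize_total_area)


def _pt(arr, scale="raw_area", batches=None, cols=None):
    df = pd.DataFrame(np.asarray(arr, dtype=float))
    if cols is not None:
        df.columns = cols
    b = pd.Series(batches, index=df.index) if batches is not None else None
    return PeakTable(df, scale=scale, batches=b)


class TestNormalize:
    def test_simple_row(self):
        pct = normalize_total_area(_pt([[1, 1, 2]]))
        assert pct.values.iloc[0].tolist() == [25.0, 25.0, 50.0]

    def test_rows_sum_to_100(self, rng):
        pct = normalize_total_area(_pt(rng.uniform(0.1, 5.0, (40, 7))))
        assert np.allclose(pct.values.sum(axis=1), 100.0, atol=1e-9)

    def test_equal_areas_35_peaks(self):
        pct = normalize_total_area(_pt(np.ones((1, 35))))
        assert np.allclose(pct.values.to_numpy(), 100 / 35)

    def test_zero_row_excluded(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="glycovar.preprocess"):
            pct = normalize_total_area(_pt([[1, 2], [0, 0]]))
        assert pct.n_samples == 1
        assert "all-zero" in caplog.text


class TestLogTransform:
    def test_log_of_one_is_zero(self):
        pct = _pt([[1.0] + [99.0 / 2] * 2], scale="percent_area")
        assert log_transform(pct).values.iloc[0, 0] == 0.0

    def test_scale_invariance_of_composition(self, rng):
        raw = rng.uniform(0.5, 4.0, (10, 6))
        a = log_transform(normalize_total_area(_pt(raw)))
        b = log_transform(normalize_total_area(_pt(raw * 7.3)))
        assert np.allclose(a.values, b.values)

    def test_multiplicative_batch_becomes_additive_log_offset(self):
        """Scaling one peak by b on one plate adds exactly ln b to that
        (plate, peak) cell after normalization cancels in the ratio-free
        limit (checked on raw areas directly)."""
        raw = np.full((4, 3), 2.0)
        bumped = raw.copy()
        bumped[:2, 1] *= 1.7
        la = np.log(raw)
        lb = np.log(bumped)
        assert np.allclose(lb[:2, 1] - la[:2, 1], np.log(1.7))
        assert np.allclose(lb[2:], la[2:])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pct = _pt([[50.0, 50.0]], scale="percent_area")
            pct.values.iloc[0, 0] = -1.0
            log_transform(pct)


class TestBatchCorrection:
    def test_single_batch_is_identity(self, rng):
        pt = _pt(rng.normal(0, 1, (10, 4)), scale="log", batches=["p"] * 10)
        out, model = correct_batch_effects(pt)
        assert np.allclose(out.values, pt.values)

    def test_pure_shift_removed_at_large_n(self, rng):
        """Two batches offset by +-delta/2 with no biology: residual batch-
        mean difference after correction is below 1e-2 * delta."""
        n, delta = 2000, 1.0
        X = rng.normal(0, 0.1, (2 * n, 6))
        X[:n] += delta / 2
        X[n:] -= delta / 2
        pt = _pt(X, scale="log", batches=["a"] * n + ["b"] * n)
        out, _ = correct_batch_effects(pt)
        diff = out.values.iloc[:n].mean() - out.values.iloc[n:].mean()
        assert diff.abs().max() < 1e-2 * delta

    def test_diffuse_prior_limit_equals_mean_centering(self, rng):
        """With shrinkage off the correction is exactly per-batch mean
        centering (grand mean preserved) — the direct oracle."""
        X = pd.DataFrame(rng.normal(0, 1, (60, 5)))
        batches = pd.Series(["a"] * 20 + ["b"] * 25 + ["c"] * 15, index=X.index)
        pt = PeakTable(X, scale="log", batches=batches)
        out, _ = correct_batch_effects(pt, shrink=False)
        oracle = X.copy()
        for lbl in ("a", "b", "c"):
            idx = batches[batches == lbl].index
            oracle.loc[idx] = X.loc[idx] - X.loc[idx].mean() + X.mean()
        assert np.allclose(out.values, oracle, atol=1e-12)

    def test_shrinkage_pulls_toward_prior_mean(self, rng):
        """A 2-sample batch with an extreme apparent shift on one peak is
        shrunk toward the across-peak prior mean: |gamma*| < |gamma_hat|,
        and gamma* lies between gamma_hat and the prior mean."""
        X = pd.DataFrame(rng.normal(0, 1, (22, 4)))
        X.iloc[:2, 0] += 5.0
        batches = pd.Series(["tiny"] * 2 + ["big"] * 20, index=X.index)
        out, model = correct_batch_effects(PeakTable(X, scale="log", batches=batches))
        g_hat = model.gamma_hat.loc["tiny", 0]
        g_star = model.gamma_star.loc["tiny", 0]
        mu = model.prior_mean["tiny"]
        assert abs(g_star - mu) < abs(g_hat - mu)
        assert min(g_hat, mu) <= g_star <= max(g_hat, mu)

    def test_grand_mean_preserved(self, rng):
        X = rng.normal(0, 1, (90, 8)) + np.repeat(rng.normal(0, 0.5, (3, 8)), 30, axis=0)
        pt = _pt(X, scale="log", batches=np.repeat(["a", "b", "c"], 30))
        out, _ = correct_batch_effects(pt)
        assert np.abs(out.values.mean() - pt.values.mean()).max() < 1e-9

    def test_identifiability_weighted_mean_zero(self, rng):
        pt = _pt(rng.normal(0, 1, (50, 3)), scale="log",
                 batches=["a"] * 20 + ["b"] * 30)
        _, model = correct_batch_effects(pt)
        w = model.batch_sizes.reindex(model.gamma_hat.index).to_numpy()[:, None]
        assert np.abs((model.gamma_hat * w).sum(axis=0) / w.sum()).max() < 1e-12

    def test_correction_is_idempotent(self, rng):
        X = rng.normal(0, 1, (80, 5)) + np.repeat(rng.normal(0, 1, (4, 5)), 20, axis=0)
        pt = _pt(X, scale="log", batches=np.repeat(list("abcd"), 20))
        once, _ = correct_batch_effects(pt, shrink=False)
        twice, model2 = correct_batch_effects(once, shrink=False)
        assert np.abs(model2.gamma_hat.to_numpy()).max() < 1e-12
        assert np.allclose(once.values, twice.values)

    def test_offset_recovery_mse_shrinks_with_n(self, rng):
        """Recovered batch offsets converge to the injected ones as the
        per-batch sample size grows."""
        def mse(n):
            true = rng.normal(0, 0.5, (3, 6))
            X = rng.normal(0, 0.3, (3 * n, 6)) + np.repeat(true, n, axis=0)
            pt = _pt(X, scale="log", batches=np.repeat(list("abc"), n))
            _, model = correct_batch_effects(pt, shrink=False)
            centered = true - true.mean(axis=0)
            return float(((model.gamma_hat.to_numpy() - centered) ** 2).mean())

        assert mse(800) < mse(20)

    def test_standards_corrected_with_cohort_effects(self, rng):
        X = rng.normal(0, 0.2, (40, 3)) + np.repeat([[1.0], [-1.0]], 20, axis=0)
        pt = _pt(X, scale="log", batches=["a"] * 20 + ["b"] * 20)
        _, model = correct_batch_effects(pt, shrink=False)
        std = _pt([[1.0, 1.0, 1.0], [-1.0, -1.0, -1.0]], scale="log",
                  batches=["a", "b"])
        out = apply_batch_model(std, model)
        # the +-1 plate offsets are mostly removed
        assert np.abs(out.values.to_numpy()[0] - out.values.to_numpy()[1]).max() < 0.3


class TestMeasurementError:
    def test_constant_standards_zero_error(self, rng):
        std = _pt(np.full((5, 3), 2.0), scale="log")
        coh = _pt(rng.normal(2, 1, (50, 3)), scale="log")
        assert np.allclose(measurement_error_standards(std, coh), 0.0)

    def test_same_distribution_near_100(self, rng):
        std = _pt(rng.normal(0, 1, (500, 4)), scale="log")
        coh = _pt(rng.normal(0, 1, (500, 4)), scale="log")
        est = measurement_error_standards(std, coh)
        assert np.all(np.abs(est - 100.0) < 15.0)

    def test_variance_decomposition(self, rng):
        """Injected technical SD tau and biological SD sigma_b give
        100 * tau^2 / (sigma_b^2 + tau^2)."""
        tau, sig = 0.3, 0.8
        n = 4000
        std = _pt(rng.normal(0, tau, (n, 2)), scale="log")
        coh = _pt(rng.normal(0, np.sqrt(sig ** 2 + tau ** 2), (n, 2)), scale="log")
        est = measurement_error_standards(std, coh)
        expected = 100 * tau ** 2 / (sig ** 2 + tau ** 2)
        assert np.all(np.abs(est - expected) < 0.15 * expected)

    def test_identical_replicates_zero(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (20, 3)))
        assert np.allclose(measurement_error_replicates(a, a.copy()), 0.0)

    def test_independent_replicates_near_100(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (500, 3)))
        b = pd.DataFrame(rng.normal(0, 1, (500, 3)))
        est = measurement_error_replicates(a, b)
        assert np.all(np.abs(est - 100.0) < 15.0)

    def test_shared_variance_attenuation(self, rng):
        """Pairs sharing a fraction rho of variance give ~100*(1-rho)."""
        rho = 0.7
        n = 3000
        shared = rng.normal(0, np.sqrt(rho), (n, 2))
        a = pd.DataFrame(shared + rng.normal(0, np.sqrt(1 - rho), (n, 2)))
        b = pd.DataFrame(shared + rng.normal(0, np.sqrt(1 - rho), (n, 2)))
        est = measurement_error_replicates(a, b)
        assert np.all(np.abs(est - 100 * (1 - rho)) < 5.0)

    def test_too_few_pairs_rejected(self, rng):
        a = pd.DataFrame(rng.normal(0, 1, (2, 2)))
        with pytest.raises(ValueError, match="at least 3"):
            measurement_error_replicates(a, a.copy())


class TestCV:
    def test_constant_vector(self):
        assert cv([5.0, 5.0, 5.0]) == 0.0

    def test_hand_example(self):
        assert cv([90.0, 110.0]) == pytest.approx(14.14, abs=0.01)

    def test_lognormal_formula(self, rng):
        x = np.exp(rng.normal(0, 0.1, 10_000))
        expected = np.sqrt(np.exp(0.01) - 1) * 100
        assert cv(x) == pytest.approx(expected, abs=0.5)

    def test_zero_mean_undefined(self):
        with pytest.raises(ValueError):
            cv([-1.0, 1.0])
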