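"""RINT, OLS association, adjusted correlation, smoother, meta, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

import glycovar as gv
from glycovar.stats import (AssociationRecord, FixedEffectsMeta,
                            GlycanAssociationModel, adjusted_correlation,
                            bh_adjust, fit_association, meta_fixed, rint,
                            sex_stratified_smoother)


class TestRint:
    def test_three_values_quantiles(self):
        out = rint([10.0, 30.0, 20.0])
        expect = norm.ppf([1 / 6, 5 / 6, 3 / 6])
        assert np.allclose(out, [expect[0], expect[1], expect[2]], atol=1e-12)
        assert out[0] == pytest.approx(-0.9674, abs=1e-4)

    def test_median_maps_to_zero(self):
        out = rint([5.0, 1.0, 9.0, 3.0, 7.0])
        assert out[0] == 0.0

    def test_moments_at_n_1000(self, rng):
        out = rint(rng.normal(10, 3, 1000))
        assert abs(out.mean()) < 1e-12
        assert 0.98 <= out.std(ddof=0) <= 1.00

    def test_missing_preserved_in_place(self):
        out = rint([1.0, np.nan, 3.0, 2.0])
        assert np.isnan(out[1])
        assert np.argsort(out[[0, 2, 3]]).tolist() == [0, 2, 1]

    def test_idempotent_on_continuous_data(self, rng):
        x = rng.normal(0, 5, 400)
        once = rint(x)
        assert np.allclose(rint(once), once, atol=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            rint([2.0, 2.0, 2.0])


class TestAssociation:
    def test_ols_consistency_untransformed(self, rng):
        n = 2000
        x = rng.normal(0, 1, n)
        y = 0.3 * x + rng.normal(0, 0.05, n)
        rec = fit_association(y, x, transform=False)
        assert 0.27 <= rec.effect <= 0.33
        assert rec.p_value < 1e-10

    def test_rint_effect_is_correlation_scale(self, rng):
        """After RINT standardization of outcome and predictor the fitted
        effect estimates the latent correlation."""
        n = 2000
        x = rng.normal(0, 1, n)
        y = 0.3 * x + np.sqrt(1 - 0.09) * rng.normal(0, 1, n)
        rec = fit_association(y, x)
        assert 0.25 <= rec.effect <= 0.35

    def test_type_one_error_control(self):
        hits = 0
        for seed in range(100):
            r = np.random.default_rng(seed)
            rec = fit_association(r.normal(0, 1, 500), r.normal(0, 1, 500))
            hits += abs(rec.effect) < 3 * rec.se
        assert hits >= 99

    def test_df_arithmetic(self, rng):
        n = 100
        cov = pd.DataFrame(rng.normal(0, 1, (n, 3)))
        rec = fit_association(rng.normal(0, 1, n), rng.normal(0, 1, n), cov)
        assert rec.df == 95

    def test_complete_case_df(self, rng):
        y = rng.normal(0, 1, 50)
        x = rng.normal(0, 1, 50)
        y[:5] = np.nan
        rec = fit_association(y, x)
        assert rec.df == 45 - 2 + 0  # 45 complete cases, intercept + x

    def test_collinear_design_named(self, rng):
        n = 50
        x = rng.normal(0, 1, n)
        cov = pd.DataFrame({"dup": x})
        with pytest.raises(ValueError, match="collinear"):
            fit_association(rng.normal(0, 1, n), x, cov, transform=False)

    def test_matches_statsmodels_ols(self, rng):
        """Effect, SE, residual DF and p agree with statsmodels OLS on the
        same RINT-transformed design (independent implementation)."""
        import statsmodels.api as sm

        n = 300
        x = rng.normal(0, 1, n)
        cov = pd.DataFrame({"age": rng.uniform(18, 90, n),
                            "sex": (rng.random(n) < 0.5).astype(float)})
        y = 0.2 * x + 0.01 * cov["age"].to_numpy() + rng.normal(0, 1, n)
        rec = fit_association(y, x, cov)
        X = sm.add_constant(np.column_stack([rint(x), cov.to_numpy()]))
        fit = sm.OLS(rint(y), X).fit()
        assert rec.effect == pytest.approx(fit.params[1], abs=1e-10)
        assert rec.se == pytest.approx(fit.bse[1], abs=1e-10)
        assert rec.p_value == pytest.approx(fit.pvalues[1], abs=1e-12)
        assert rec.df == int(fit.df_resid)

    def test_binary_predictor_not_transformed(self, rng):
        x = (rng.random(300) < 0.4).astype(float)
        y = 0.5 * x + rng.normal(0, 1, 300)
        rec = fit_association(y, x)
        assert rec.p_value < 0.05


class TestAdjustedCorrelation:
    def test_perfect_correlation(self, rng):
        x = rng.normal(0, 1, 100)
        r, p = adjusted_correlation(x, x)
        assert r == pytest.approx(1.0)

    def test_known_partial_correlation(self, rng):
        """Trivariate Gaussian with partial corr 0.4 given the covariate."""
        n = 5000
        rho = 0.4
        c = rng.normal(0, 1, n)
        x = 0.5 * c + rng.normal(0, 1, n)
        ex = (x - 0.5 * c)
        y = 0.5 * c + rho * ex + np.sqrt(1 - rho ** 2) * rng.normal(0, 1, n)
        r, _ = adjusted_correlation(y, x, pd.DataFrame({"c": c}))
        assert 0.37 <= r <= 0.43

    def test_confounder_removed(self, rng):
        n = 2000
        age = rng.uniform(18, 90, n)
        y = 0.02 * age + rng.normal(0, 0.5, n)
        x = 0.05 * age + rng.normal(0, 1.0, n)
        r, _ = adjusted_correlation(y, x, pd.DataFrame({"age": age}))
        assert abs(r) < 0.05


class TestSmoother:
    def test_reproduces_line_exactly(self):
        rng = np.random.default_rng(0)
        age = rng.uniform(20, 80, 200)
        sex = np.array(["F", "M"] * 100)
        value = 2.0 + 0.01 * age
        out = sex_stratified_smoother(age, value, sex)
        for s, df in out.items():
            interior = df.iloc[5:-5]
            assert np.allclose(interior["fit"],
                               2.0 + 0.01 * interior["age"], atol=1e-6)
            assert np.all(interior["se"] < 1e-6)

    def test_ci_shrinks_with_n(self):
        def width(n, seed=3):
            r = np.random.default_rng(seed)
            age = r.uniform(20, 80, n)
            val = 0.01 * age + r.normal(0, 0.5, n)
            out = sex_stratified_smoother(age, val, np.array(["F"] * n))
            df = out["F"]
            return float((df["hi"] - df["lo"]).iloc[10:-10].mean())

        assert width(3200) < width(200) / 2.0

    def test_stratification_contract(self):
        rng = np.random.default_rng(4)
        n = 400
        age = rng.uniform(20, 80, n)
        sex = np.where(np.arange(n) % 2 == 0, "F", "M")
        value = np.where(sex == "F", 1.0 + 0.02 * age, 5.0 - 0.02 * age)
        out = sex_stratified_smoother(age, value, sex)
        f, m = out["F"], out["M"]
        assert f["fit"].iloc[-1] > f["fit"].iloc[0]
        assert m["fit"].iloc[-1] < m["fit"].iloc[0]

    def test_small_stratum_skipped(self):
        rng = np.random.default_rng(5)
        age = rng.uniform(20, 80, 40)
        sex = np.array(["F"] * 35 + ["M"] * 5)
        with pytest.warns(UserWarning, match="skipped"):
            out = sex_stratified_smoother(age, rng.normal(0, 1, 40), sex)
        assert "M" not in out


class TestMetaFixed:
    def _rec(self, e, s, cohort="K"):
        return AssociationRecord("g", "t", cohort, 900, e, s, 0.5)

    def test_printed_two_cohort_example(self):
        """Combining (-0.106, 0.035) and (-0.150, 0.033) gives -0.129 (0.024)."""
        out = meta_fixed([self._rec(-0.106, 0.035, "K"), self._rec(-0.150, 0.033, "V")])
        assert round(out.effect, 3) == -0.129
        assert round(out.se, 3) == 0.024

    def test_single_cohort_passthrough(self):
        out = meta_fixed([self._rec(0.248, 0.034, "V")])
        assert out.effect == 0.248 and out.se == 0.034

    def test_missing_cohort_dropped(self):
        missing = AssociationRecord("g", "t", "K", 0, np.nan, np.nan, np.nan)
        out = meta_fixed([missing, self._rec(-0.178, 0.036, "V")])
        assert out.effect == -0.178 and out.se == 0.036
        assert out.cohorts == ("V",)

    def test_equal_inputs_identity(self):
        out = meta_fixed([self._rec(0.2, 0.05, "K"), self._rec(0.2, 0.05, "V")])
        assert out.effect == pytest.approx(0.2)
        assert out.se == pytest.approx(0.05 / np.sqrt(2))

    def test_se_below_min_and_effect_convex(self, rng):
        for _ in range(25):
            e1, e2 = rng.normal(0, 1, 2)
            s1, s2 = rng.uniform(0.01, 0.5, 2)
            out = meta_fixed([self._rec(e1, s1, "K"), self._rec(e2, s2, "V")])
            assert out.se < min(s1, s2)
            assert min(e1, e2) - 1e-12 <= out.effect <= max(e1, e2) + 1e-12

    def test_zero_se_rejected(self):
        with pytest.raises(ValueError):
            meta_fixed([self._rec(0.1, 0.0)])


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.042]).tolist() == [0.042]

    def test_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                           [0.04, 0.04, 0.04, 0.04])

    def test_monotone_and_dominating(self, rng):
        p = rng.uniform(1e-6, 1, 200)
        q = bh_adjust(p)
        assert np.all(q >= p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(1e-6, 1, 97)
        q = bh_adjust(p)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(q, q_sm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])

    def test_nan_restored(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


class TestModelObjects:
    def test_model_results_summary_and_meta(self, rng):
        n = 400
        idx = pd.Index([f"s{i}" for i in range(n)])
        cov = pd.DataFrame({"age": rng.uniform(18, 90, n),
                            "sex": (rng.random(n) < 0.5).astype(float)}, index=idx)
        glycans = pd.DataFrame({
            "T1": 0.3 * cov["age"] / 20 + rng.normal(0, 1, n),
            "T2": rng.normal(0, 1, n)}, index=idx)
        phenos = pd.DataFrame({"ph": rng.normal(0, 1, n)}, index=idx)
        res = GlycanAssociationModel(glycans, phenos, cov, cohort="A").fit()
        assert set(res.table["glycan"]) == {"T1", "T2"}
        assert (res.table["p_adjusted"] >= res.table["p_value"] - 1e-15).all()
        assert "Glycan trait associations" in res.summary()
        res_b = GlycanAssociationModel(glycans, phenos, cov, cohort="B").fit()
        meta = FixedEffectsMeta([res, res_b]).fit()
        assert len(meta.table) == 2
        merged = meta.table.merge(res.table, on=["glycan", "trait"],
                                  suffixes=("_m", "_a"))
        assert (merged["se_m"] <= merged["se_a"] + 1e-12).all()
        assert "meta" in meta.summary().lower()
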