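import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rwwfit.phenotype_stats import (
    PhenotypeTable,
    anova_partial_eta2,
    auroc_from_residuals,
    bca_ci,
    deconfound,
    fdr_by,
    mass_univariate,
    ols_effect,
)


def _pheno(n, rng, **planted):
    df = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "gender": rng.choice(["f", "m"], n),
        "age": rng.normal(40, 10, n),
        "bmi": rng.normal(24, 3, n),
        "yos": rng.normal(13, 3, n),
        "iq": rng.normal(100, 15, n),
        "site": rng.choice(["a", "b"], n),
    })
    for k, v in planted.items():
        df[k] = v
    return PhenotypeTable(df)


class TestOLS:
    def test_self_prediction_gives_unit_beta(self, rng):
        x = rng.standard_normal(50)
        beta, p = ols_effect(x, x)
        assert beta == pytest.approx(1.0)
        assert p < 1e-20

    def test_orthogonal_predictor_gives_zero_beta(self, rng):
        x = rng.standard_normal(64)
        y = rng.standard_normal(64)
        y -= x * (x @ y) / (x @ x)  # exactly orthogonal
        y -= y.mean()
        x_c = x - x.mean()
        y -= x_c * (x_c @ y) / (x_c @ x_c)
        beta, _ = ols_effect(y, x)
        assert abs(beta) < 1e-10

    def test_matches_normal_equations_on_hand_dataset(self):
        x = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12], dtype=float)
        cov = np.array([2, 1, 4, 3, 6, 5, 8, 7, 10, 9, 12, 11], dtype=float)
        y = 0.7 * x - 0.3 * cov + np.array(
            [0.1, -0.2, 0.05, 0.3, -0.1, 0.2, -0.3, 0.1, 0.0, -0.05, 0.15, -0.1])
        beta, _ = ols_effect(y, x, covariates=cov)
        zy = (y - y.mean()) / y.std(ddof=1)
        zx = (x - x.mean()) / x.std(ddof=1)
        X = np.column_stack([np.ones(12), cov, zx])
        coef = np.linalg.solve(X.T @ X, X.T @ zy)
        assert beta == pytest.approx(coef[-1])

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.1, 100), shift=st.floats(-50, 50))
    def test_standardized_beta_affine_invariant(self, scale, shift):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        b1, _ = ols_effect(y, x)
        b2, _ = ols_effect(scale * y + shift, scale * x - shift)
        assert b1 == pytest.approx(b2, rel=1e-9)


class TestANOVA:
    def test_equal_group_means_give_zero_effect(self):
        grp = np.array([0, 1] * 10)
        y = np.tile([1.0, 1.0], 10)
        eta2, p = anova_partial_eta2(grp, y)
        assert eta2 == pytest.approx(0.0)

    def test_perfect_separation_gives_full_effect(self):
        grp = np.repeat([0, 1], 10)
        y = np.repeat([0.0, 5.0], 10)
        eta2, p = anova_partial_eta2(grp, y)
        assert eta2 == pytest.approx(1.0)
        assert p < 1e-10

    def test_matches_hand_anova_table(self):
        grp = np.repeat(["a", "b"], 6)
        y = np.array([3.0, 4.0, 5.0, 4.0, 3.0, 5.0, 6.0, 7.0, 8.0, 7.0, 6.0, 8.0])
        eta2, p = anova_partial_eta2(grp, y)
        ss_between = 6 * ((4.0 - 5.5) ** 2 + (7.0 - 5.5) ** 2)
        ss_within = float(((y[:6] - 4.0) ** 2).sum() + ((y[6:] - 7.0) ** 2).sum())
        assert eta2 == pytest.approx(ss_between / (ss_between + ss_within))


class TestFDR:
    def test_single_test_unchanged(self):
        p_corr, reject = fdr_by(np.array([0.03]), q=0.05)
        assert p_corr[0] == pytest.approx(0.03)
        assert reject[0]

    def test_all_unit_pvalues_never_reject(self):
        p_corr, reject = fdr_by(np.ones(10), q=0.05)
        assert not reject.any()

    def test_matches_direct_stepup_enumeration(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        q = 0.05
        m = len(p)
        c_m = np.sum(1.0 / np.arange(1, m + 1))
        order = np.argsort(p)
        k_max = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= rank * q / (m * c_m):
                k_max = rank
        expected = np.zeros(m, dtype=bool)
        expected[order[:k_max]] = True
        _, reject = fdr_by(p, q=q)
        np.testing.assert_array_equal(reject, expected)

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_by_rejections_subset_of_bh(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 12) ** 2
        _, by_rej = fdr_by(p, q=0.05)
        bh_rej = multipletests(p, alpha=0.05, method="fdr_bh")[0]
        assert np.all(~by_rej | bh_rej)

    def test_corrected_never_below_raw(self, rng):
        p = rng.uniform(0, 1, 30)
        p_corr, _ = fdr_by(p)
        assert np.all(p_corr >= p - 1e-12)
        assert np.all(p_corr <= 1.0)


class TestDeconfound:
    def test_residuals_orthogonal_to_covariates(self, rng):
        cov = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        resid = deconfound(y, cov)
        assert np.abs(resid @ cov).max() < 1e-10
        assert abs(resid.sum()) < 1e-10

    def test_orthogonal_covariates_only_center(self, rng):
        y = rng.standard_normal(50)
        cov = rng.standard_normal(50)
        cov -= cov.mean()
        cov -= y * (y @ cov) / (y @ y)
        yc = y - y.mean()
        cov -= yc * (yc @ cov) / (yc @ yc)
        resid = deconfound(y, cov)
        np.testing.assert_allclose(resid, y - y.mean(), atol=1e-10)

    def test_hand_projection_case(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        cov = np.array([1.0, 1.0, 2.0, 2.0, 3.0, 3.0])
        X = np.column_stack([np.ones(6), cov])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(deconfound(y, cov), y - X @ beta, atol=1e-12)


class TestAUROC:
    def test_perfect_separation_gives_one(self):
        x = np.concatenate([np.zeros(10), np.ones(10) + 1])
        y = np.repeat([0, 1], 10)
        assert auroc_from_residuals(x, y) == pytest.approx(1.0)

    def test_equals_bruteforce_concordance(self, rng):
        # genuine positive association: the logistic slope is positive, so the
        # probability ordering equals the raw-score ordering
        y = np.repeat([0, 1], 12)
        x = y + 0.8 * rng.standard_normal(24)
        auroc = auroc_from_residuals(x, y)
        pos = x[y == 1]
        neg = x[y == 0]
        conc = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert auroc == pytest.approx(conc)

    def test_label_independent_predictor_near_half(self, rng):
        """Null predictors give AUROC near chance.

        The in-sample logistic AUROC folds the concordance about 1/2 (the
        fitted slope's sign tracks the sample concordance), so the null mean
        sits slightly above 0.5 by the folded sampling error, about
        0.5 + 0.8 / sqrt(n); the raw-score concordance itself is unbiased.
        """
        x = rng.standard_normal(60)
        y = np.repeat([0, 1], 30)
        vals, concs = [], []
        for _ in range(50):
            xp = rng.permutation(x)
            vals.append(auroc_from_residuals(xp, y))
            pos, neg = xp[y == 1], xp[y == 0]
            concs.append(np.mean([(p > n) for p in pos for n in neg]))
        assert 0.48 <= np.mean(vals) <= 0.60
        assert np.mean(concs) == pytest.approx(0.5, abs=0.03)


class TestBCa:
    def test_constant_data_degenerate_interval(self):
        lo, hi = bca_ci(np.mean, np.full(20, 3.0), n_boot=100, seed=0)
        assert lo == hi == pytest.approx(3.0)

    def test_close_to_scipy_bca_on_symmetric_data(self, rng):
        from scipy.stats import bootstrap

        x = rng.standard_normal(60)
        lo, hi = bca_ci(np.mean, x, n_boot=5000, seed=1)
        ref = bootstrap((x,), np.mean, n_resamples=5000, method="BCa",
                        random_state=2).confidence_interval
        assert lo == pytest.approx(ref.low, abs=0.06)
        assert hi == pytest.approx(ref.high, abs=0.06)

    def test_stratified_resampling_preserves_group_sizes(self, rng):
        x = np.concatenate([rng.normal(0, 1, 15), rng.normal(5, 1, 25)])
        grp = np.repeat([0, 1], [15, 25])

        def stat(v, g):
            # within-stratum resampling keeps both groups populated
            # (the jackknife pass removes at most one row)
            assert (g == 0).sum() >= 14 and (g == 1).sum() >= 24
            return v[g == 1].mean() - v[g == 0].mean()

        lo, hi = bca_ci(stat, (x, grp), n_boot=200, seed=3, stratify_by=grp)
        assert lo < 5 < hi

    def test_reproducible_from_seed(self, rng):
        x = rng.standard_normal(30)
        assert bca_ci(np.mean, x, n_boot=500, seed=7) == \
            bca_ci(np.mean, x, n_boot=500, seed=7)


class TestMassUnivariate:
    def test_planted_signal_is_top_ranked(self):
        rng = np.random.default_rng(0)
        n, p = 120, 30
        X = rng.standard_normal((n, p))
        iq = 100 + 15 * (0.6 * X[:, 7] + np.sqrt(1 - 0.36) * rng.standard_normal(n))
        pheno = _pheno(n, rng, iq=iq)
        res = mass_univariate(X, pheno, targets=("iq",), n_boot=200, seed=1)
        effects = [abs(r.effect_size) for r in res["iq"]]
        assert int(np.argmax(effects)) == 7
        best = res["iq"][7]
        assert best.effect_ci is not None and best.effect_ci[0] < best.effect_size
        assert {"mae", "mad", "spearman", "pearson"} <= set(best.extras)

    def test_null_features_rarely_rejected(self):
        rng = np.random.default_rng(1)
        n, p = 80, 20
        X = rng.standard_normal((n, p))
        pheno = _pheno(n, rng)
        res = mass_univariate(X, pheno, targets=("bmi",), n_boot=50, seed=2)
        rejected = sum(r.extras["rejected"] for r in res["bmi"])
        assert rejected <= 1

    def test_single_feature_reduces_to_ols_effect(self):
        rng = np.random.default_rng(2)
        n = 60
        X = rng.standard_normal((n, 1))
        pheno = _pheno(n, rng)
        res = mass_univariate(X, pheno, targets=("age",), n_boot=50, seed=3)
        cov = np.column_stack([
            pd.factorize(pheno.data["gender"])[0],
            pd.factorize(pheno.data["site"])[0],
        ]).astype(float)
        beta, p = ols_effect(pheno.data["age"].to_numpy(), X[:, 0], cov)
        assert res["age"][0].effect_size == pytest.approx(beta)
        assert res["age"][0].p_uncorrected == pytest.approx(p)

    def test_gender_target_reports_auroc(self):
        rng = np.random.default_rng(3)
        n = 80
        X = rng.standard_normal((n, 3))
        pheno = _pheno(n, rng)
        res = mass_univariate(X, pheno, targets=("gender",), n_boot=50, seed=4)
        best = max(res["gender"], key=lambda r: abs(r.effect_size))
        assert 0.0 <= best.extras["auroc"] <= 1.0
        assert all(r.effect_kind == "partial_eta2" for r in res["gender"])


class TestPhenotypeTable:
    def test_missing_column_rejected(self, rng):
        df = _pheno(5, rng).data.drop(columns=["iq"])
        with pytest.raises(ValueError, match="iq"):
            PhenotypeTable(df)

    def test_duplicate_subject_timepoint_rejected(self, rng):
        df = _pheno(4, rng).data
        df.loc[3, "subject_id"] = df.loc[0, "subject_id"]
        df["timepoint"] = 1
        with pytest.raises(ValueError, match="duplicated"):
            PhenotypeTable(df)

    def test_first_timepoint_filter_deduplicates(self, rng):
        df = _pheno(4, rng).data
        df2 = df.copy()
        df["timepoint"] = 1
        df2["timepoint"] = 2
        both = PhenotypeTable(pd.concat([df, df2], ignore_index=True))
        first = both.first_timepoint()
        assert len(first) == 4
        assert set(first.data["timepoint"]) == {1}
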