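"""Agreement estimators against independent brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from calcquant.agreement import (
    AgreementAnalysis,
    agreement_report,
    bland_altman,
    icc_agreement,
    interpret_coefficient,
    pearson_ci,
    stratified_agreement,
    weighted_kappa,
)

# ---------------------------------------------------------------------------
# brute-force oracles: explicit sums / ANOVA tables / contingency tables
# ---------------------------------------------------------------------------


def oracle_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sx = sum((a - mx) ** 2 for a in x) ** 0.5
    sy = sum((b - my) ** 2 for b in y) ** 0.5
    return cov / (sx * sy)


def oracle_icc21(x, y):
    n, k = len(x), 2
    rows = [(x[i], y[i]) for i in range(n)]
    grand = sum(x) / n / 2 + sum(y) / n / 2
    row_means = [sum(r) / k for r in rows]
    col_means = [sum(x) / n, sum(y) / n]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((v - grand) ** 2 for r in rows for v in r)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def oracle_bland_altman(mr, cta):
    n = len(mr)
    d = [a - b for a, b in zip(mr, cta)]
    bias = sum(d) / n
    sd = (sum((v - bias) ** 2 for v in d) / (n - 1)) ** 0.5
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def oracle_weighted_kappa(r1, r2, k=5):
    n = len(r1)
    obs = [[0.0] * k for _ in range(k)]
    for a, b in zip(r1, r2):
        obs[a - 1][b - 1] += 1.0 / n
    pr = [sum(obs[i]) for i in range(k)]
    pc = [sum(obs[i][j] for i in range(k)) for j in range(k)]
    w = [[1.0 - abs(i - j) / (k - 1) for j in range(k)] for i in range(k)]
    po = sum(w[i][j] * obs[i][j] for i in range(k) for j in range(k))
    pe = sum(w[i][j] * pr[i] * pc[j] for i in range(k) for j in range(k))
    return (po - pe) / (1 - pe)


class TestPearson:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, ci = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert ci == (1.0, 1.0)

    def test_hand_computed_example(self):
        r, _ = pearson_ci([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2, 3, 4])
        r, _ = pearson_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_ci_shrinks_with_n_at_fixed_r(self):
        x = np.array([1.0, 2, 3, 4, 6])
        y = np.array([1.2, 1.9, 3.4, 3.8, 6.3])
        r1, ci1 = pearson_ci(x, y)
        r2, ci2 = pearson_ci(np.tile(x, 4), np.tile(y, 4))
        assert r2 == pytest.approx(r1)
        assert (ci2[1] - ci2[0]) < (ci1[1] - ci1[0])

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_ci([1, 1, 1], [1, 2, 3])


class TestICC:
    def test_perfect_agreement(self):
        x = np.array([1.0, 2, 3, 4])
        icc, _ = icc_agreement(x, x)
        assert icc == pytest.approx(1.0)

    def test_offset_penalized_unlike_pearson(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = x + 2.0
        icc, _ = icc_agreement(x, y)
        r, _ = pearson_ci(x, y)
        assert r == pytest.approx(1.0)
        assert icc < 1.0

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        x = rng.normal(100, 30, 20)
        y = x + rng.normal(-5, 10, 20)
        icc, ci = icc_agreement(x, y)
        long = pd.DataFrame(
            {
                "target": np.r_[np.arange(20), np.arange(20)],
                "rater": ["a"] * 20 + ["b"] * 20,
                "score": np.r_[x, y],
            }
        )
        ref = pg.intraclass_corr(long, "target", "rater", "score")
        ref = ref.set_index("Type")
        row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
        ci_col = "CI95" if "CI95" in ref.columns else "CI95%"
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        # pingouin rounds its CI to 2 decimals
        assert ci[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert ci[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_equals_pearson_asymptotically_for_equal_moments(self):
        # same multiset in both positions -> equal means and variances;
        # the ANOVA ICC converges to Pearson r as n grows
        rng = np.random.default_rng(5)
        x = rng.normal(100, 30, 2000)
        y = x.copy()
        rng.shuffle(y)
        icc, _ = icc_agreement(x, y)
        r, _ = pearson_ci(x, y)
        assert icc == pytest.approx(r, abs=5e-3)


class TestBlandAltman:
    def test_identical_measurements(self):
        x = np.array([1.0, 5, 9])
        assert bland_altman(x, x) == (0.0, 0.0, 0.0)

    def test_hand_computed_example(self):
        bias, lo, hi = bland_altman([0.0, 0.0], [10.0, 20.0])
        assert bias == pytest.approx(-15.0)
        assert lo == pytest.approx(-15 - 1.96 * 7.0710678, abs=1e-4)
        assert hi == pytest.approx(-15 + 1.96 * 7.0710678, abs=1e-4)

    def test_translation_equivariance(self, rng):
        mr = rng.normal(100, 20, 15)
        cta = rng.normal(100, 20, 15)
        b0, lo0, hi0 = bland_altman(mr, cta)
        b1, lo1, hi1 = bland_altman(mr + 7.0, cta)
        assert b1 == pytest.approx(b0 + 7.0)
        assert (hi1 - lo1) == pytest.approx(hi0 - lo0)


class TestWeightedKappa:
    def test_perfect_agreement(self):
        r = np.array([1, 2, 3, 4, 5, 3, 4])
        kappa, _ = weighted_kappa(r, r)
        assert kappa == pytest.approx(1.0)

    def test_crossed_example_matches_oracle(self):
        r1 = np.array([1, 1, 2, 2])
        r2 = np.array([2, 2, 1, 1])
        kappa, _ = weighted_kappa(r1, r2)
        assert kappa == pytest.approx(oracle_weighted_kappa(list(r1), list(r2)))

    def test_independent_raters_near_zero(self):
        rng = np.random.default_rng(12)
        p = np.array([0.1, 0.15, 0.25, 0.3, 0.2])
        r1 = rng.choice(np.arange(1, 6), 100_000, p=p)
        r2 = rng.choice(np.arange(1, 6), 100_000, p=p)
        kappa, _ = weighted_kappa(r1, r2)
        assert abs(kappa) < 0.02

    def test_matches_sklearn(self):
        sk = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(7)
        r1 = rng.integers(1, 6, 60)
        r2 = np.clip(r1 + rng.integers(-1, 2, 60), 1, 5)
        kappa, _ = weighted_kappa(r1, r2)
        ref = sk.cohen_kappa_score(r1, r2, weights="linear", labels=[1, 2, 3, 4, 5])
        assert kappa == pytest.approx(ref, abs=1e-10)

    def test_shift_invariance_linear_weights(self):
        rng = np.random.default_rng(8)
        r1 = rng.integers(1, 5, 80)   # categories 1..4
        r2 = np.clip(r1 + rng.integers(-1, 2, 80), 1, 4)
        k0, _ = weighted_kappa(r1, r2)
        k1, _ = weighted_kappa(r1 + 1, r2 + 1)  # order-preserving relabel
        assert k1 == pytest.approx(k0, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="1..5"):
            weighted_kappa([1, 6], [1, 2])

    def test_ci_brackets_estimate_and_shrinks(self):
        rng = np.random.default_rng(9)
        r1 = rng.choice([3, 4, 5], 50, p=[0.25, 0.4, 0.35])
        r2 = np.where(rng.random(50) < 0.8, r1, np.clip(r1 + 1, 1, 5))
        k_small, ci_small = weighted_kappa(r1, r2)
        assert ci_small[0] <= k_small <= ci_small[1]
        k_big, ci_big = weighted_kappa(np.tile(r1, 8), np.tile(r2, 8))
        assert (ci_big[1] - ci_big[0]) < (ci_small[1] - ci_small[0])


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.39, "poor"),
            (-0.2, "poor"),
            (0.40, "fair"),
            (0.59, "fair"),
            (0.60, "good"),
            (0.67, "good"),
            (0.74, "good"),
            (0.75, "excellent"),
            (0.80, "excellent"),
            (0.98, "excellent"),
        ],
    )
    def test_printed_scale(self, value, label):
        assert interpret_coefficient(value) == label


class TestOracleEquivalence:
    def test_all_estimators_match_brute_force(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 51))
            x = rng.normal(100, 40, n)
            y = 0.9 * x + rng.normal(0, 15, n)
            r, _ = pearson_ci(x, y)
            assert r == pytest.approx(oracle_pearson(list(x), list(y)), abs=1e-10)
            icc, _ = icc_agreement(x, y)
            assert icc == pytest.approx(oracle_icc21(list(x), list(y)), abs=1e-10)
            ba = bland_altman(x, y)
            ref = oracle_bland_altman(list(x), list(y))
            assert np.allclose(ba, ref, atol=1e-9)
            r1 = rng.integers(1, 6, n)
            r2 = np.clip(r1 + rng.integers(-1, 2, n), 1, 5)
            if len(set(r1)) > 1 or len(set(r2)) > 1:
                kappa, _ = weighted_kappa(r1, r2)
                assert kappa == pytest.approx(
                    oracle_weighted_kappa(list(r1), list(r2)), abs=1e-10
                )


class TestStratifiedAgreement:
    def _pairs(self, rng, n=24):
        cta = rng.uniform(10, 400, n)
        mr = 0.9 * cta + rng.normal(0, 12, n)
        return pd.DataFrame(
            {
                "mr_mm3": np.abs(mr),
                "cta_mm3": cta,
                "field": ["1.5T"] * (n // 2) + ["3T"] * (n - n // 2),
            }
        )

    def test_single_stratum_equals_pooled(self, rng):
        pairs = self._pairs(rng)
        pairs["field"] = "3T"
        reports = stratified_agreement(pairs, by="field")
        assert reports["field=3T"].pearson_r == pytest.approx(
            reports["pooled"].pearson_r
        )
        assert reports["field=3T"].bias_mm3 == pytest.approx(
            reports["pooled"].bias_mm3
        )

    def test_strata_partition_pooled_n(self, rng):
        pairs = self._pairs(rng)
        reports = stratified_agreement(pairs, by="field")
        n_strata = sum(r.n for k, r in reports.items() if k != "pooled")
        assert n_strata == reports["pooled"].n

    def test_unknown_stratum_key(self, rng):
        with pytest.raises(ValueError, match="stratum"):
            stratified_agreement(self._pairs(rng), by="nope")

    def test_small_stratum_reports_n_only(self, rng):
        pairs = self._pairs(rng, n=10)
        pairs.loc[:1, "field"] = "0.5T"
        pairs.loc[2:, "field"] = "3T"
        reports = stratified_agreement(pairs, by="field")
        assert reports["field=0.5T"].n == 2
        assert np.isnan(reports["field=0.5T"].pearson_r)

    def test_model_results_summary(self, rng):
        results = AgreementAnalysis.from_dataframe(self._pairs(rng)).fit(by="field")
        text = results.summary()
        assert "pooled" in text and "field=3T" in text
        assert results.pooled.n == 24
        d = results.to_dict()
        assert set(d) == {"pooled", "field=1.5T", "field=3T"}
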