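"""Group tests, logistic regression, ROC/AUC, DeLong comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from vatprofiler import (
    DiscriminationModel,
    auc_mann_whitney,
    chi_square,
    compare_three,
    compare_two,
    delong_compare,
    logistic_fit,
    proportion,
    roc,
)


def brute_force_auc(labels, scores):
    """Exhaustive positive-negative pair enumeration, ties counted 1/2."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


class TestCompareTwo:
    def test_identical_groups_mann_whitney_p_one(self):
        r = compare_two([1, 2, 3, 4, 5], [1, 2, 3, 4, 5], method="nonparametric")
        assert r.p_value == pytest.approx(1.0)
        assert not r.significant

    def test_zero_t_statistic_on_equal_groups(self):
        r = compare_two([1, 2, 3], [1, 2, 3], method="parametric")
        assert r.statistic == pytest.approx(0.0)
        assert r.test_name == "t-test"

    def test_chi_square_matches_hand_formula(self):
        # printed 2x2 perianal table: 129/215 vs 18/219
        table = np.array([[129.0, 215.0], [18.0, 219.0]])
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        hand = ((table - expected) ** 2 / expected).sum()
        r = chi_square(table)
        assert r.statistic == pytest.approx(hand)
        assert r.significant

    def test_categorical_from_label_arrays(self):
        a = ["yes"] * 129 + ["no"] * 215
        b = ["yes"] * 18 + ["no"] * 219
        r = compare_two(a, b, scale="categorical")
        assert r.test_name.startswith("chi-square")
        assert r.p_value < 0.001

    def test_auto_picks_nonparametric_for_skewed_data(self, rng):
        a = rng.lognormal(0, 1.5, 80)
        b = rng.lognormal(0.2, 1.5, 80)
        r = compare_two(a, b, method="auto")
        assert r.test_name == "Mann-Whitney U"
        assert "(" in next(iter(r.summaries.values()))  # median (IQR) summary

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_two([], [1, 2], method="parametric")


class TestCompareThree:
    def test_identical_groups_not_flagged(self):
        g = [1.0, 2.0, 3.0, 4.0, 5.0]
        r = compare_three([g, g, g])
        assert r.p_value > 0.99
        assert not any(sub.significant for sub in r.pairwise.values())

    def test_overwhelming_shift_flags_the_right_pairs(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(0, 1, 50)
        c = rng.normal(10, 1, 50)  # shifted by 10 SDs
        r = compare_three([a, b, c])
        assert r.p_value < 1e-6
        assert not r.pairwise["P1"].significant  # A vs B
        assert r.pairwise["P2"].significant  # A vs C
        assert r.pairwise["P3"].significant  # B vs C

    def test_pairwise_threshold_is_corrected_alpha(self):
        # fixed arrays whose t-test p falls between 0.0167 and 0.05:
        # significant at 0.05 but NOT at the Bonferroni-corrected level
        a = np.arange(10, dtype=float)
        b = a + 0.98 * np.std(a, ddof=1)
        p = sps.ttest_ind(a, b).pvalue
        assert 0.0167 < p < 0.05
        r = compare_two(a, b, method="parametric", alpha=0.0167)
        assert r.alpha_used == 0.0167
        assert not r.significant

    def test_requires_three_groups(self):
        with pytest.raises(ValueError):
            compare_three([[1, 2], [3, 4]])


class TestProportion:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(129, 344, 37.5), (18, 237, 7.6), (85, 344, 24.7), (129, 272, 47.4), (0, 100, 0.0)],
    )
    def test_printed_percentages(self, num, den, expected):
        assert proportion(num, den) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            proportion(1, 0)

    def test_numerator_bounds(self):
        with pytest.raises(ValueError):
            proportion(5, 4)


class TestLogisticFit:
    def test_null_covariate_ci_covers_one(self, rng):
        y = rng.integers(0, 2, 10_000)
        x = rng.normal(size=10_000)
        r = logistic_fit(y, pd.DataFrame({"x": x}))
        lo, hi = r.table.loc["x", ["ci_low", "ci_high"]]
        assert lo < 1.0 < hi
        assert r.converged

    def test_intercept_only_balanced_outcome(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        r = logistic_fit(y, None)
        assert r.table.loc["const", "odds_ratio"] == pytest.approx(1.0, abs=1e-6)

    def test_coefficient_recovery_low_bias(self, rng):
        # mean estimate over replicates within 5% of the true log-odds
        true_beta = np.log(2.0)
        estimates = []
        for _ in range(40):
            x = rng.normal(size=5000)
            p = 1 / (1 + np.exp(-true_beta * x))
            y = (rng.random(5000) < p).astype(int)
            r = logistic_fit(y, pd.DataFrame({"x": x}))
            estimates.append(np.log(r.table.loc["x", "odds_ratio"]))
        assert abs(np.mean(estimates) - true_beta) < 0.05 * true_beta

    def test_separation_flagged(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        x_jit = x + np.linspace(0, 0.01, 40)  # not constant, still separating
        r = logistic_fit(y, pd.DataFrame({"x": x_jit}))
        assert r.separation
        assert not r.converged

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            logistic_fit(np.ones(10), pd.DataFrame({"x": np.arange(10.0)}))

    def test_constant_covariate_rejected(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="constant"):
            logistic_fit(y, pd.DataFrame({"x": np.ones(10)}))


class TestRoc:
    def test_perfect_separation(self):
        r = roc([1, 1, 1, 0, 0, 0], [5.0, 4.0, 3.0, 2.0, 1.0, 0.0])
        assert r.auc == 1.0
        assert r.sensitivity_pct == 100.0 and r.specificity_pct == 100.0

    def test_uninformative_scores(self):
        r = roc([1, 1, 0, 0], [3.0, 3.0, 3.0, 3.0])
        assert r.auc == pytest.approx(0.5)

    def test_binary_predictor_auc_is_mean_of_sens_spec(self):
        labels = np.r_[np.ones(344), np.zeros(237)]
        scores = np.r_[np.ones(129), np.zeros(215), np.ones(18), np.zeros(219)]
        r = roc(labels, scores)
        assert r.auc == pytest.approx((r.sensitivity_pct + r.specificity_pct) / 200.0)

    def test_youden_ties_break_toward_specificity(self):
        # two cutoffs reach the same J; the more specific one must win
        labels = [1, 1, 0, 0]
        scores = [2.0, 1.0, 1.0, 0.0]
        r = roc(labels, scores)
        assert r.cutoff == 2.0
        assert r.specificity_pct == 100.0

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc([1, 1, 1], [1.0, 2.0, 3.0])

    @settings(deadline=None, max_examples=60)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rank_auc_equals_pair_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = rng.integers(0, 2, n)
        labels[0], labels[1] = 0, 1  # both classes present
        scores = rng.integers(0, 6, n).astype(float)  # many ties
        assert auc_mann_whitney(labels, scores) == pytest.approx(
            brute_force_auc(labels, scores)
        )

    @pytest.mark.parametrize("transform", [lambda s: 3 * s + 1, np.exp, lambda s: s**3])
    def test_auc_invariant_under_monotone_transform(self, transform, rng):
        labels = rng.integers(0, 2, 100)
        labels[:2] = [0, 1]
        scores = rng.normal(size=100)
        assert auc_mann_whitney(labels, transform(scores)) == pytest.approx(
            auc_mann_whitney(labels, scores)
        )


class TestDeLong:
    def test_identical_classifiers(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        s = rng.normal(size=80)
        r = delong_compare(labels, s, s)
        assert r.difference == 0.0 and r.p_value == 1.0

    def test_monotone_transform_gives_zero_difference(self, rng):
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        s = rng.normal(size=80)
        r = delong_compare(labels, s, np.exp(s))
        assert r.difference == pytest.approx(0.0)

    def test_variance_matches_stratified_bootstrap(self):
        # small frozen fixture; oracle = stratified bootstrap at 1e5 resamples
        pos = np.array([2.1, 0.7, 1.4, 3.0, 0.9])
        neg = np.array([0.2, 1.1, -0.5, 0.8, 1.6])
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        r = roc(labels, np.r_[pos, neg])
        rng = np.random.default_rng(1234)
        B = 100_000
        ps = pos[rng.integers(0, 5, (B, 5))]
        ns = neg[rng.integers(0, 5, (B, 5))]
        psi = (ps[:, :, None] > ns[:, None, :]) + 0.5 * (ps[:, :, None] == ns[:, None, :])
        boot_var = psi.mean(axis=(1, 2)).var(ddof=1)
        assert r.auc_variance == pytest.approx(boot_var, rel=0.15)

    def test_null_p_values_roughly_uniform(self, rng):
        # independent, identically distributed classifiers on the same
        # subjects: DeLong p should be approximately U(0,1)
        pvals = []
        for _ in range(2000):
            labels = np.r_[np.ones(50), np.zeros(50)].astype(int)
            s1 = rng.normal(size=100)
            s2 = rng.normal(size=100)
            pvals.append(delong_compare(labels, s1, s2).p_value)
        ks = sps.kstest(pvals, "uniform").statistic
        assert ks < 0.05

    def test_unpaired_lengths_rejected(self):
        with pytest.raises(ValueError):
            delong_compare([1, 0], [1.0, 2.0], [1.0, 2.0, 3.0])


class TestDiscriminationModel:
    def test_recovers_cv_effect_from_simulated_cohort(self, rng):
        n = 400
        cv = np.r_[rng.normal(29.4, 15.5, n), rng.normal(25.7, 12.6, n)]
        age = rng.normal(40, 12, 2 * n)
        group = np.r_[["CD"] * n, ["UC"] * n]
        df = pd.DataFrame({"group": group, "cv_pct": cv, "age_years": age})
        model = DiscriminationModel.from_dataframe(df, covariates=["age_years"])
        res = model.fit()
        or_cv, lo, hi, p = res.logistic.odds_ratio("cv_pct")
        assert or_cv > 1.0 and p < 0.05
        assert res.roc_combined.auc > 0.5
        assert "cv_pct" in res.summary()

    def test_compare_with_reduced_model(self, rng):
        n = 300
        cv = np.r_[rng.normal(29.4, 15.5, n), rng.normal(23.7, 12.6, n)]
        age = np.r_[rng.normal(34, 12, n), rng.normal(45, 13, n)]
        df = pd.DataFrame(
            {"group": np.r_[["CD"] * n, ["UC"] * n], "cv_pct": cv, "age_years": age}
        )
        full = DiscriminationModel.from_dataframe(df, covariates=["age_years"]).fit()
        comparison = full.compare_with(df["age_years"].to_numpy() * -1.0)
        assert 0 <= comparison.p_value <= 1
        assert comparison.auc_1 == pytest.approx(full.roc_combined.auc)
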