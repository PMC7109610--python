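"""Validation statistics against independent oracles.

ICC is checked against a hand ANOVA-table computation and pingouin;
Guttman lambdas against direct evaluation of their defining formulas on a
known covariance structure; rank tests against exhaustive permutation
enumeration; Spearman against a rank-then-Pearson hand computation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mshrs import (
    RetestRecord,
    UndefinedStatisticError,
    completer_comparison,
    convergent_discriminant,
    exact_kruskal_p,
    exact_mannwhitney_p,
    filter_stable,
    guttman_lambda2,
    guttman_lambda6,
    icc_band,
    icc_oneway_random,
    known_group_analysis,
    reliability_report,
)


def exact_cov_data(cov: np.ndarray, n: int = 60, seed: int = 0) -> np.ndarray:
    """Data matrix whose *sample* covariance equals ``cov`` exactly."""
    rng = np.random.default_rng(seed)
    k = cov.shape[0]
    x = rng.standard_normal((n, k))
    x -= x.mean(axis=0)
    # whiten to exact identity sample covariance, then colour by chol(cov)
    s = np.cov(x, rowvar=False, ddof=1)
    x = x @ np.linalg.inv(np.linalg.cholesky(s)).T
    return x @ np.linalg.cholesky(cov).T


# ---------------------------------------------------------------------------
# stability filter


class TestFilterStable:
    def _rec(self, **kw):
        base = dict(
            respondent_id="r", total_cost_w1=1.0, total_cost_w2=2.0,
            edss_pre=2.0, edss_w1=2.0, edss_w2=2.0,
            relapses_pre_window=0, relapses_retest_window=0,
        )
        base.update(kw)
        return RetestRecord(**base)

    def test_stable_record_retained(self):
        assert len(filter_stable([self._rec()])) == 1

    def test_edss_increase_in_retest_window_excluded(self):
        assert filter_stable([self._rec(edss_w2=2.5)]) == []

    def test_edss_increase_before_baseline_excluded(self):
        assert filter_stable([self._rec(edss_pre=1.5)]) == []

    def test_relapse_in_prior_window_excluded(self):
        assert filter_stable([self._rec(relapses_pre_window=1)]) == []

    def test_relapse_in_retest_window_excluded(self):
        assert filter_stable([self._rec(relapses_retest_window=1)]) == []

    def test_missing_history_excluded_without_error(self):
        assert filter_stable([self._rec(edss_pre=None)]) == []

    def test_edss_improvement_is_stable(self):
        assert len(filter_stable([self._rec(edss_w2=1.5)])) == 1


# ---------------------------------------------------------------------------
# ICC


def anova_icc_oracle(pairs):
    """Variance-components ICC(1,1) via an explicit ANOVA table."""
    data = np.asarray(pairs, float)
    n, k = data.shape
    grand = data.mean()
    msb = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msw = ((data - data.mean(axis=1, keepdims=True)) ** 2).sum() / (n * (k - 1))
    return (msb - msw) / (msb + (k - 1) * msw)


class TestICC:
    def test_identical_pairs_give_one(self):
        pairs = [(1, 1), (2, 2), (5, 5), (9, 9)]
        assert icc_oneway_random(pairs) == pytest.approx(1.0)

    def test_independent_pairs_near_zero(self):
        rng = np.random.default_rng(7)
        pairs = rng.standard_normal((10_000, 2))
        assert abs(icc_oneway_random(pairs)) < 0.05

    def test_matches_anova_oracle_on_hand_example(self):
        pairs = [(1, 1), (2, 2), (3, 3), (4, 5)]
        # MSB = 13.375/3, MSW = 0.5/4 -> ICC = 4.33333/4.58333
        assert icc_oneway_random(pairs) == pytest.approx(0.9454545, abs=1e-6)
        assert icc_oneway_random(pairs) == pytest.approx(anova_icc_oracle(pairs))

    def test_matches_pingouin_oneway(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        subj = rng.normal(0, 2, 40)
        data = subj[:, None] + rng.normal(0, 1, (40, 2))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(40), 2),
                "rater": np.tile([0, 1], 40),
                "y": data.ravel(),
            }
        )
        icc1 = pingouin.intraclass_corr(long, "subject", "rater", "y").set_index("Type")
        assert icc_oneway_random(data) == pytest.approx(
            icc1.loc["ICC(1,1)", "ICC"], abs=1e-9
        )

    def test_zero_variance_signalled(self):
        with pytest.raises(UndefinedStatisticError):
            icc_oneway_random([(1, 1), (1, 1), (1, 1)])

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        data = rng.normal(5, 2, (50, 2)) + rng.normal(0, 1, (50, 1))
        assert icc_oneway_random(data * 3.7 + 11) == pytest.approx(
            icc_oneway_random(data), abs=1e-10
        )

    @pytest.mark.parametrize(
        "icc,band",
        [(0.3, "poor"), (0.5, "moderate"), (0.74, "moderate"),
         (0.75, "good"), (0.828, "good"), (0.95, "excellent")],
    )
    def test_interpretation_bands(self, icc, band):
        assert icc_band(icc) == band


# ---------------------------------------------------------------------------
# Guttman lambdas


TOY_COV = np.array([[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]])


def lambda2_oracle(cov):
    k = cov.shape[0]
    off = cov - np.diag(np.diag(cov))
    return (off.sum() + np.sqrt(k / (k - 1) * (off**2).sum())) / cov.sum()


def lambda6_oracle(cov):
    smc_err = []
    k = cov.shape[0]
    for i in range(k):
        others = [j for j in range(k) if j != i]
        beta = np.linalg.solve(cov[np.ix_(others, others)], cov[np.ix_(others, [i])])
        explained = float((cov[np.ix_([i], others)] @ beta).item())
        smc_err.append(cov[i, i] - explained)
    return 1.0 - sum(smc_err) / cov.sum()


class TestGuttmanLambdas:
    def test_parallel_items_give_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        matrix = np.column_stack([x, x * 2.0 + 3.0])  # correlation exactly 1
        # perfectly collinear items: lambda2 = 1; lambda6 needs invertibility
        assert guttman_lambda2(matrix) == pytest.approx(1.0)

    def test_lambda2_toy_covariance_hand_value(self):
        data = exact_cov_data(TOY_COV)
        # hand evaluation: [3 + sqrt(1.5 * 1.5)] / 6 = 0.75
        assert guttman_lambda2(data) == pytest.approx(0.75, abs=1e-9)
        assert lambda2_oracle(TOY_COV) == pytest.approx(0.75)

    def test_lambda6_toy_covariance_hand_value(self):
        data = exact_cov_data(TOY_COV)
        # R^2_i = 1/3 for each item -> 1 - 3*(2/3)/6 = 2/3
        assert guttman_lambda6(data) == pytest.approx(2 / 3, abs=1e-9)
        assert lambda6_oracle(TOY_COV) == pytest.approx(2 / 3)

    def test_uncorrelated_items_near_zero(self):
        rng = np.random.default_rng(5)
        matrix = rng.standard_normal((20_000, 5))
        assert guttman_lambda2(matrix) < 0.1
        assert abs(guttman_lambda6(matrix)) < 0.1

    def test_lambda_bounds_and_alpha_order_on_random_matrices(self):
        """lambda2 <= 1 and lambda2 >= lambda3 (= Cronbach alpha)."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            k = rng.integers(3, 8)
            a = rng.standard_normal((k, k))
            cov = a @ a.T + np.eye(k) * 0.5
            data = exact_cov_data(cov, n=80, seed=int(rng.integers(1e6)))
            lam2 = guttman_lambda2(data, standardize=False)
            c = np.cov(data, rowvar=False, ddof=1)
            k_ = c.shape[0]
            alpha = k_ / (k_ - 1) * (1 - np.trace(c) / c.sum())
            assert lam2 <= 1 + 1e-9
            assert lam2 >= alpha - 1e-9

    def test_affine_invariance_of_standardized_lambdas(self):
        rng = np.random.default_rng(13)
        data = exact_cov_data(TOY_COV, seed=2)
        scaled = data * 250.0 + 17.0
        assert guttman_lambda2(scaled) == pytest.approx(guttman_lambda2(data), abs=1e-9)
        assert guttman_lambda6(scaled) == pytest.approx(guttman_lambda6(data), abs=1e-9)

    def test_single_item_rejected(self):
        with pytest.raises(ValueError):
            guttman_lambda2(np.ones((10, 1)))

    def test_zero_variance_item_named(self):
        matrix = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(UndefinedStatisticError, match="1"):
            guttman_lambda2(matrix)


# ---------------------------------------------------------------------------
# known groups


def permutation_kruskal_oracle(groups):
    """All n! orderings of the pooled sample (independent of the package)."""
    pooled = np.concatenate(groups)
    sizes = [len(g) for g in groups]

    def h_stat(values):
        ranks = stats.rankdata(values)
        n = len(values)
        h, start = 0.0, 0
        for s in sizes:
            h += ranks[start : start + s].sum() ** 2 / s
            start += s
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        _, counts = np.unique(values, return_counts=True)
        tie = 1 - ((counts**3 - counts).sum()) / (n**3 - n)
        return h / tie

    h_obs = h_stat(pooled)
    hits = total = 0
    for perm in itertools.permutations(pooled):
        if h_stat(np.array(perm)) >= h_obs - 1e-12:
            hits += 1
        total += 1
    return hits / total


def permutation_mannwhitney_oracle(a, b):
    pooled = np.concatenate([a, b])
    n1, n2 = len(a), len(b)

    def u_stat(values):
        ranks = stats.rankdata(values)
        return ranks[:n1].sum() - n1 * (n1 + 1) / 2

    u_obs = u_stat(pooled)
    ext = min(u_obs, n1 * n2 - u_obs)
    hits = total = 0
    for perm in itertools.permutations(pooled):
        u = u_stat(np.array(perm))
        if min(u, n1 * n2 - u) <= ext + 1e-12:
            hits += 1
        total += 1
    return hits / total


class TestKnownGroups:
    def test_identical_groups_no_signal(self):
        rng = np.random.default_rng(21)
        base = rng.normal(1000, 100, 200)
        costs = np.tile(base, 4)
        edss = np.repeat([0.5, 2.0, 3.5, 5.0], 200)
        report = known_group_analysis(costs, edss)
        assert report.kruskal_p > 0.5
        assert (report.pairwise["p_bonferroni"] == 1.0).all()

    def test_severity_gradient_detected(self):
        rng = np.random.default_rng(22)
        means = [1099, 2295, 3112, 4733]
        costs = np.concatenate(
            [rng.lognormal(np.log(m), 0.9, 500) for m in means]
        )
        edss = np.repeat([0.5, 2.0, 3.5, 5.0], 500)
        report = known_group_analysis(costs, edss)
        assert report.kruskal_p < 0.001
        assert (report.pairwise["p_bonferroni"] < 0.05).all()
        assert report.group_summaries["mean"].is_monotonic_increasing

    def test_between_bin_edss_excluded_and_counted(self):
        costs = np.array([1.0, 2.0, 3.0, 4.0] * 3 + [99.0])
        edss = np.array([0.5, 2.0, 3.5, 5.0] * 3 + [6.5])  # 6.5 outside all bins
        report = known_group_analysis(costs, edss)
        assert report.n_excluded == 1
        assert report.group_summaries["n"].sum() == 12

    def test_empty_bin_errors_with_label(self):
        with pytest.raises(ValueError, match="4.5-5.5"):
            known_group_analysis([1, 2, 3], [0.5, 2.0, 3.5])

    def test_bonferroni_is_capped_product(self):
        rng = np.random.default_rng(23)
        costs = rng.normal(0, 1, 80)
        edss = np.repeat([0.5, 2.0, 3.5, 5.0], 20)
        report = known_group_analysis(costs, edss)
        for _, row in report.pairwise.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, row["p_raw"] * 6))

    def test_exact_mode_matches_permutation_oracles_small_n(self):
        rng = np.random.default_rng(29)
        for trial in range(3):
            a = rng.normal(0, 1, 3)
            b = rng.normal(1, 1, 3)
            c = rng.normal(2, 1, 2)
            assert exact_kruskal_p([a, b, c]) == pytest.approx(
                permutation_kruskal_oracle([a, b, c]), abs=1e-12
            )
            assert exact_mannwhitney_p(a, b) == pytest.approx(
                permutation_mannwhitney_oracle(a, b), abs=1e-12
            )

    def test_exact_mannwhitney_separated_supports(self):
        # fully separated groups of 4: two-sided exact p = 2/C(8,4) = 1/35
        a = [1.0, 2.0, 3.0, 4.0]
        b = [10.0, 11.0, 12.0, 13.0]
        assert exact_mannwhitney_p(a, b) == pytest.approx(2 / 70, abs=1e-12)
        assert exact_mannwhitney_p(a, b) == pytest.approx(
            permutation_mannwhitney_oracle(np.array(a), np.array(b))
        )

    def test_exact_handles_ties_via_midranks(self):
        a = np.array([1.0, 1.0, 2.0])
        b = np.array([2.0, 3.0, 3.0])
        assert exact_mannwhitney_p(a, b) == pytest.approx(
            permutation_mannwhitney_oracle(a, b), abs=1e-12
        )


# ---------------------------------------------------------------------------
# correlations


class TestConvergentDiscriminant:
    def test_costs_vs_themselves(self):
        costs = np.arange(100.0)
        out = convergent_discriminant(costs, {"self": costs})
        assert out.loc[0, "spearman_r"] == pytest.approx(1.0)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(31)
        costs = rng.lognormal(7, 1, 10_000)
        out = convergent_discriminant(costs, {"noise": rng.standard_normal(10_000)})
        assert abs(out.loc[0, "spearman_r"]) < 0.05

    def test_small_vector_matches_rank_pearson_hand_computation(self):
        costs = np.array([10.0, 40.0, 20.0, 90.0, 50.0, 30.0, 70.0, 60.0, 80.0, 15.0])
        scores = np.array([1.0, 3.0, 2.0, 9.0, 4.0, 6.0, 5.0, 8.0, 7.0, 2.5])
        rx = stats.rankdata(costs)
        ry = stats.rankdata(scores)
        hand = np.corrcoef(rx, ry)[0, 1]
        out = convergent_discriminant(costs, {"pro": scores})
        assert out.loc[0, "spearman_r"] == pytest.approx(hand, abs=1e-12)

    def test_constant_vector_signalled(self):
        costs = np.arange(20.0)
        with pytest.raises(UndefinedStatisticError):
            convergent_discriminant(costs, {"flat": np.ones(20)})

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            convergent_discriminant(np.arange(5.0), {"x": np.arange(5.0)})


# ---------------------------------------------------------------------------
# completer comparison


def _cohort_frame(n=200, shift_duration=0.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    return pd.DataFrame(
        {
            "completed_survey": [True] * half + [False] * (n - half),
            "age": rng.normal(42, 10, n),
            "sex": rng.choice(["female", "male"], n, p=[0.73, 0.27]),
            "edss": rng.choice(np.arange(0, 6.5, 0.5), n),
            "disease_duration_years": np.concatenate(
                [rng.normal(7.5, 6, half), rng.normal(7.5 + shift_duration, 6, n - half)]
            ),
        }
    )


class TestCompleterComparison:
    def test_identical_groups_nonsignificant(self):
        out = completer_comparison(_cohort_frame(seed=41))
        assert (out["p"].dropna() > 0.05).all()

    def test_duration_shift_detected_in_most_replicates(self):
        hits = 0
        others_ok = 0
        for seed in range(20):
            out = completer_comparison(_cohort_frame(n=400, shift_duration=2.0, seed=seed))
            out = out.set_index("variable")
            hits += out.loc["disease_duration_years", "p"] < 0.05
            others_ok += (out.loc[["age", "edss"], "p"] > 0.05).all()
        assert hits >= 19
        assert others_ok >= 15

    def test_one_group_empty_errors(self):
        frame = _cohort_frame()
        frame["completed_survey"] = True
        with pytest.raises(ValueError):
            completer_comparison(frame)

    def test_single_noncompleter_flagged_degenerate(self):
        frame = _cohort_frame(n=50)
        frame["completed_survey"] = [False] + [True] * 49
        out = completer_comparison(frame)
        assert out["degenerate"].any()


# ---------------------------------------------------------------------------
# full reliability report


class TestReliabilityReport:
    def test_perfect_retest(self):
        recs = [
            RetestRecord(str(i), float(i), float(i), 2.0, 2.0, 2.0, 0, 0)
            for i in range(10)
        ]
        rep = reliability_report(recs)
        assert rep.icc == pytest.approx(1.0)
        assert rep.icc_band == "excellent"
        assert rep.n_stable == 10

    def test_too_few_stable_subjects_undefined(self):
        recs = [
            RetestRecord(str(i), 1.0, 2.0, 2.0, 2.0, 2.0, 1, 0) for i in range(10)
        ]
        with pytest.raises(UndefinedStatisticError):
            reliability_report(recs)
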