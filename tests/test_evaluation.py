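"""Metrics, agreement statistics, rates, regression and rank tests."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from radqc.evaluation import (
    ConfusionCounts,
    MatchCriterion,
    MetricUndefinedError,
    RateRecord,
    accuracy,
    bootstrap_ci,
    chi_square_2x2,
    cohen_kappa,
    error_rate,
    f1,
    gwet_ac1,
    match_detections,
    match_report,
    ols_regression,
    percent,
    precision,
    recall,
    wilcoxon_rank_sum,
    with_report_level_tn,
)


class Span:
    def __init__(self, start, end, error_type="spelling_mistake"):
        self.start, self.end, self.error_type = start, end, error_type


class TestMatching:
    def test_perfect_predictions(self):
        gold = {"r1": [Span(0, 2), Span(5, 8)]}
        counts = match_detections(gold, gold)
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)

    def test_empty_predictions(self):
        gold = {"r1": [Span(0, 2), Span(5, 8)], "r2": [Span(1, 3)]}
        preds = {"r1": [], "r2": []}
        counts = match_detections(preds, gold)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 3)

    def test_id_mismatch_raises(self):
        with pytest.raises(KeyError, match="r2"):
            match_detections({"r1": []}, {"r1": [], "r2": []})

    def test_matches_exhaustive_bipartite_oracle(self):
        rng = np.random.default_rng(5)
        criterion = MatchCriterion()
        for _ in range(100):
            golds = [Span(int(s), int(s + w)) for s, w in
                     zip(rng.integers(0, 20, 4), rng.integers(1, 8, 4))]
            preds = [Span(int(s), int(s + w)) for s, w in
                     zip(rng.integers(0, 20, 4), rng.integers(1, 8, 4))]
            counts = match_report(preds, golds, criterion)
            # oracle: try every injective assignment of golds to predictions
            best = 0
            overlap = [
                [max(g.start, p.start) < min(g.end, p.end) for p in preds]
                for g in golds
            ]
            for assignment in itertools.permutations(range(len(preds))):
                size = sum(
                    overlap[g][p]
                    for g, p in enumerate(assignment[: len(golds)])
                )
                best = max(best, size)
            assert counts.tp == best
            assert counts.fn == len(golds) - best
            assert counts.fp == len(preds) - best

    def test_type_match_criterion(self):
        gold = {"r": [Span(0, 2, "gender_error")]}
        preds = {"r": [Span(0, 2, "age_error")]}
        loose = match_detections(preds, gold, MatchCriterion(require_type_match=False))
        strict = match_detections(preds, gold, MatchCriterion(require_type_match=True))
        assert loose.tp == 1 and strict.tp == 0


class TestMetrics:
    COUNTS = with_report_level_tn(ConfusionCounts(tp=437, fp=58, fn=69), 1000)

    def test_reference_precision(self):
        assert percent(precision(self.COUNTS)) == 88.3

    def test_reference_recall(self):
        assert percent(recall(self.COUNTS)) == 86.4

    def test_reference_f1(self):
        assert f1(self.COUNTS) == 2 * 437 / (2 * 437 + 58 + 69)
        assert percent(f1(self.COUNTS)) == 87.3

    def test_reference_accuracy_report_level(self):
        assert percent(accuracy(self.COUNTS)) == 87.3

    def test_zero_denominators_raise(self):
        empty = ConfusionCounts()
        for metric in (precision, recall, f1, accuracy):
            with pytest.raises(MetricUndefinedError):
                metric(empty)

    def test_f1_harmonic_mean_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            c = ConfusionCounts(*(int(v) for v in rng.integers(1, 50, 3)))
            p, r, f = precision(c), recall(c), f1(c)
            assert 0 <= min(p, r) <= f <= max(p, r) <= 1

    def test_half_up_rounding(self):
        assert percent(0.87350) == 87.4  # half rounds up, not to even
        assert percent(0.004185, 2) == 0.42


class TestBootstrap:
    def test_constant_outcomes_zero_width(self):
        ci = bootstrap_ci(lambda s: float(np.mean(s)), [0.7] * 40, rng_seed=1)
        assert ci.ci_low == ci.point == ci.ci_high == pytest.approx(0.7)

    def test_endpoints_within_unit_interval(self):
        rng = np.random.default_rng(3)
        outcomes = rng.random(60)
        ci = bootstrap_ci(lambda s: float(np.mean(s)), outcomes, rng_seed=4)
        assert 0 <= ci.ci_low <= ci.ci_high <= 1

    def test_deterministic_under_seed(self):
        outcomes = list(np.random.default_rng(0).random(30))
        a = bootstrap_ci(lambda s: float(np.mean(s)), outcomes, rng_seed=9)
        b = bootstrap_ci(lambda s: float(np.mean(s)), outcomes, rng_seed=9)
        assert a == b

    def test_width_shrinks_like_root_n(self):
        rng = np.random.default_rng(11)
        widths = {}
        for n in (100, 400, 1600):
            data = rng.binomial(1, 0.3, size=n).astype(float)
            ci = bootstrap_ci(lambda s: float(np.mean(s)), data,
                              resamples=500, rng_seed=n)
            widths[n] = ci.ci_high - ci.ci_low
        assert 0.3 < widths[400] / widths[100] < 0.75
        assert 0.3 < widths[1600] / widths[400] < 0.75

    def test_mostly_undefined_metric_raises(self):
        def metric(sample):
            raise MetricUndefinedError("always")

        with pytest.raises(MetricUndefinedError):
            bootstrap_ci(metric, [1.0] * 10, resamples=50, rng_seed=0)


class TestAgreement:
    def test_perfect_agreement(self):
        table = [[30, 0], [0, 20]]
        assert cohen_kappa(table) == pytest.approx(1.0)
        assert gwet_ac1(table) == pytest.approx(1.0)

    def test_kappa_hand_example(self):
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        assert cohen_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_kappa_near_zero_for_independent_raters(self):
        rng = np.random.default_rng(21)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        table = np.zeros((2, 2))
        np.add.at(table, (a, b), 1)
        assert abs(cohen_kappa(table)) < 0.05

    def test_kappa_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(8)
        for _ in range(25):
            table = rng.integers(1, 40, size=(3, 3))
            ours = cohen_kappa(table)
            reference = cohens_kappa(table, return_results=False)
            assert ours == pytest.approx(reference)

    def test_ac1_matches_direct_formula(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            table = rng.integers(0, 30, size=(2, 2)) + 1
            total = table.sum()
            p_o = (table[0, 0] + table[1, 1]) / total
            pi0 = (table[0].sum() + table[:, 0].sum()) / (2 * total)
            pi1 = (table[1].sum() + table[:, 1].sum()) / (2 * total)
            p_e = pi0 * (1 - pi0) + pi1 * (1 - pi1)  # K - 1 == 1
            expected = (p_o - p_e) / (1 - p_e)
            assert gwet_ac1(table) == pytest.approx(expected)

    def test_ac1_exceeds_kappa_on_skewed_marginals(self):
        rng = np.random.default_rng(17)
        for _ in range(40):
            # heavy prevalence on one category (the kappa paradox direction)
            table = np.array([
                [int(rng.integers(200, 400)), int(rng.integers(0, 6))],
                [int(rng.integers(0, 6)), int(rng.integers(1, 8))],
            ])
            assert gwet_ac1(table) >= cohen_kappa(table)

    def test_degenerate_marginals_raise(self):
        with pytest.raises(MetricUndefinedError):
            cohen_kappa([[10, 0], [0, 0]])


class TestChiSquareAndRates:
    def test_identical_rates(self):
        statistic, p = chi_square_2x2(10, 90, 20, 180)
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_before_after_comparison_significant(self):
        statistic, p = chi_square_2x2(
            23_909, 571_264 - 23_909, 7_408, 873_030 - 7_408
        )
        assert p < 0.001

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(31)
        for _ in range(30):
            a, b, c, d = (int(v) for v in rng.integers(1, 200, 4))
            statistic, _ = chi_square_2x2(a, b, c, d)
            table = np.array([[a, b], [c, d]], dtype=float)
            expected_counts = np.outer(table.sum(1), table.sum(0)) / table.sum()
            oracle = ((table - expected_counts) ** 2 / expected_counts).sum()
            assert statistic == pytest.approx(oracle)
            assert chi_square_2x2(a, c, b, d)[0] == pytest.approx(statistic)  # transpose

    def test_zero_margin_raises(self):
        with pytest.raises(MetricUndefinedError):
            chi_square_2x2(0, 0, 5, 5)

    @pytest.mark.parametrize(
        "numerator, denominator, expected",
        [
            (23_909, 571_264, 4.19),
            (7_408, 873_030, 0.85),
            (7_656, 101_190, 7.57),
            (7_614, 873_030, 0.87),
            (0, 1_000, 0.0),
        ],
    )
    def test_reference_error_rates(self, numerator, denominator, expected):
        records = [RateRecord(numerator, denominator, modality="CT")]
        assert error_rate(records) == expected

    def test_rate_pooling_and_empty_stratum(self):
        records = [
            RateRecord(10, 100, modality="CT"),
            RateRecord(30, 100, modality="MRI"),
        ]
        assert error_rate(records) == 20.0
        assert error_rate(records, modality="CT") == 10.0
        with pytest.raises(MetricUndefinedError):
            error_rate(records, modality="DR")


class TestRegression:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(41)
        x1, x2 = rng.random(30), rng.random(30)
        y = 2.0 - 1.5 * x1 + 0.5 * x2
        result = ols_regression({"x1": x1, "x2": x2}, y)
        assert result.coefficient("intercept") == pytest.approx(2.0)
        assert result.coefficient("x1") == pytest.approx(-1.5)
        assert result.coefficient("x2") == pytest.approx(0.5)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(43)
        X = rng.random((40, 3))
        y = rng.random(40)
        result = ols_regression({f"x{i}": X[:, i] for i in range(3)}, y)
        design = np.column_stack([np.ones(40), X])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert np.allclose(result.coefficients, beta)
        residuals = y - design @ beta
        sigma2 = residuals @ residuals / (40 - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
        assert np.allclose(result.standard_errors, se)
        t = beta / se
        p = 2 * sps.t.sf(np.abs(t), df=40 - 4)
        assert np.allclose(result.p_values, p)

    def test_recovers_simulated_intervention_effect(self):
        # 28 monthly rates with a true deployment effect of -1.0
        rng = np.random.default_rng(47)
        months = 28
        deployed = np.array([0.0] * 12 + [1.0] * 16)
        total = rng.normal(50, 5, months)
        mri = rng.normal(18, 2, months)
        night = rng.normal(14, 2, months)
        senior = rng.normal(30, 3, months)
        rate = 4.0 - 1.0 * deployed + 0.02 * total + rng.normal(0, 0.1, months)
        result = ols_regression(
            {"deployed": deployed, "total": total, "mri": mri,
             "night": night, "senior": senior},
            rate,
        )
        beta = result.coefficient("deployed")
        se = result.standard_error("deployed")
        assert beta - 1.96 * se <= -1.0 <= beta + 1.96 * se
        assert result.p_value("deployed") < 0.001

    def test_rank_deficiency_named(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="rank"):
            ols_regression({"a": x, "b": 2 * x}, x)


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        w, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_scipy_for_small_tie_free_samples(self):
        rng = np.random.default_rng(53)
        for _ in range(20):
            x = rng.permutation(np.arange(1.0, 9.0))[:4]
            y = rng.permutation(np.arange(9.0, 21.0))[:4] + rng.random(4)
            w, p = wilcoxon_rank_sum(x, y)
            reference = sps.mannwhitneyu(x, y, alternative="two-sided",
                                         method="exact")
            assert w == pytest.approx(reference.statistic + len(x) * (len(x) + 1) / 2)
            assert p == pytest.approx(reference.pvalue)

    def test_large_sample_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(59)
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.5, 1, 45)
        _, p = wilcoxon_rank_sum(x, y)
        reference = sps.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic", use_continuity=False)
        assert p == pytest.approx(reference.pvalue)

    def test_p_decreases_with_shift(self):
        rng = np.random.default_rng(61)
        x = rng.normal(0, 1, 60)
        noise = rng.normal(0, 1, 60)
        ps = [wilcoxon_rank_sum(x, noise + shift)[1] for shift in (0.2, 0.6, 1.2)]
        assert ps[0] > ps[1] > ps[2]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])
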