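"""Fisher exact, diagnostic performance, Spearman, ICC, t-test."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, rankdata

from _oracles import fisher_two_sided_enumeration
from dcewash.errors import UndefinedStatisticError
from dcewash.stats import (
    AgreementCategory,
    ConfusionMatrix,
    ContingencyTable2x2,
    diagnostic_performance,
    fisher_exact_two_sided,
    icc_agreement,
    icc_category,
    spearman_rho,
    two_sample_t,
)


class TestFisherExact:
    def test_balanced_unit_table(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_perfect_diagonal(self):
        # only the two extreme tables have probability <= observed: 2/C(10,5)
        p = fisher_exact_two_sided(ContingencyTable2x2(5, 0, 0, 5))
        assert p == pytest.approx(2 / math.comb(10, 5), rel=1e-12)

    def test_published_curve_mid_table(self):
        p = fisher_exact_two_sided(ContingencyTable2x2(2, 12, 24, 19))
        assert round(p, 4) == 0.0118

    def test_degenerate_margin_gives_one(self):
        assert fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 5)) == 1.0

    @pytest.mark.parametrize("a,b,c,d", [(3, 5, 2, 9), (0, 7, 6, 1), (4, 4, 4, 4)])
    def test_symmetries(self, a, b, c, d):
        p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
        for t in [(c, d, a, b), (b, a, d, c), (a, c, b, d)]:
            assert fisher_exact_two_sided(ContingencyTable2x2(*t)) == pytest.approx(p)

    def test_agrees_with_full_enumeration_up_to_n40(self):
        rng = np.random.default_rng(7)
        checked = 0
        for _ in range(300):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
                continue
            p = fisher_exact_two_sided(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            q = fisher_two_sided_enumeration(int(a), int(b), int(c), int(d))
            assert p == pytest.approx(q, rel=1e-9), (a, b, c, d)
            checked += 1
        assert checked > 100


class TestDiagnosticPerformance:
    def test_perfect_classifier(self):
        perf = diagnostic_performance(ConfusionMatrix(1, 0, 0, 1))
        assert (
            perf.sensitivity,
            perf.specificity,
            perf.ppv,
            perf.npv,
            perf.accuracy,
        ) == (100.0, 100.0, 100.0, 100.0, 100.0)

    def test_degenerate_predictor_has_undefined_ppv(self):
        with pytest.warns(UserWarning, match="PPV"):
            perf = diagnostic_performance(ConfusionMatrix(0, 0, 5, 5))
        assert perf.sensitivity == 0.0
        assert perf.specificity == 100.0
        assert math.isnan(perf.ppv)

    def test_published_row_counts(self):
        perf = diagnostic_performance(ConfusionMatrix(tp=23, fp=7, fn=5, tn=24))
        assert round(perf.sensitivity, 1) == 82.1
        assert round(perf.specificity, 1) == 77.4
        assert round(perf.ppv, 1) == 76.7
        assert round(perf.npv, 1) == 82.8
        assert round(perf.accuracy, 1) == 79.7

    @pytest.mark.filterwarnings("ignore::UserWarning")
    @settings(derandomize=True, max_examples=200)
    @given(
        tp=st.integers(0, 50), fp=st.integers(0, 50),
        fn=st.integers(0, 50), tn=st.integers(0, 50),
    )
    def test_accuracy_identity_in_count_space(self, tp, fp, fn, tn):
        if tp + fn == 0 or tn + fp == 0 or tp + fp + fn + tn == 0:
            return
        perf = diagnostic_performance(ConfusionMatrix(tp, fp, fn, tn))
        lhs = perf.accuracy * (tp + fp + fn + tn)
        rhs = perf.sensitivity * (tp + fn) + perf.specificity * (tn + fp)
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]).rho == pytest.approx(1.0)
        assert spearman_rho([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_tied_data_matches_rank_then_pearson_oracle(self, rng):
        x = rng.integers(0, 5, size=40).astype(float)
        y = x + rng.integers(0, 3, size=40)
        r = spearman_rho(x, y)
        expected = pearsonr(rankdata(x), rankdata(y))[0]
        assert r.rho == pytest.approx(expected, abs=1e-12)

    def test_constant_sequence_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            spearman_rho([1, 1, 1, 1], [1, 2, 3, 4])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(-1000, 1000), min_size=5, max_size=30, unique=True))
    def test_monotone_transform_invariance(self, xs):
        rng = np.random.default_rng(0)
        ys = rng.normal(size=len(xs))
        r1 = spearman_rho(xs, ys).rho
        r2 = spearman_rho(np.exp(np.asarray(xs) / 1000), ys).rho  # strictly monotone
        assert r1 == pytest.approx(r2, abs=1e-12)
        assert -1 <= r1 <= 1


class TestIcc:
    def test_identical_ratings_are_excellent(self):
        r = icc_agreement([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert r.icc == pytest.approx(1.0)
        assert r.category is AgreementCategory.EXCELLENT

    @pytest.mark.parametrize(
        "value, expected",
        [
            (0.49, AgreementCategory.POOR),
            (0.50, AgreementCategory.MODERATE),
            (0.60, AgreementCategory.MODERATE),
            (0.75, AgreementCategory.MODERATE),
            (0.80, AgreementCategory.GOOD),
            (0.90, AgreementCategory.GOOD),
            (0.91, AgreementCategory.EXCELLENT),
        ],
    )
    def test_category_boundaries(self, value, expected):
        assert icc_category(value) is expected

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        subj = rng.normal(0, 2, size=30)
        r1 = subj + rng.normal(0, 0.5, size=30)
        r2 = subj + 0.3 + rng.normal(0, 0.5, size=30)
        ours = icc_agreement(r1, r2).icc
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(30), 2),
                "rater": np.repeat(["a", "b"], 30),
                "score": np.concatenate([r1, r2]),
            }
        )
        res = pg.intraclass_corr(
            data=df, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        # absolute-agreement single-rater row (ICC(2,1) in the 2-way scheme)
        label = "ICC(A,1)" if "ICC(A,1)" in res.index else "ICC2"
        icc2 = res.loc[label, "ICC"]
        assert ours == pytest.approx(float(icc2), abs=1e-9)

    def test_recovers_analytic_icc_from_variance_components(self):
        # sigma_subject^2 = 4, sigma_rater^2 = 0.25, sigma_err^2 = 1
        # analytic ICC(2,1) = 4 / (4 + 0.25 + 1)
        rng = np.random.default_rng(5)
        n, reps = 300, 60
        vals = []
        for _ in range(reps):
            subj = rng.normal(0, 2.0, size=n)
            rater_fx = rng.normal(0, 0.5, size=2)
            r1 = subj + rater_fx[0] + rng.normal(0, 1.0, size=n)
            r2 = subj + rater_fx[1] + rng.normal(0, 1.0, size=n)
            vals.append(icc_agreement(r1, r2).icc)
        target = 4 / (4 + 0.25 + 1)
        mc_se = np.std(vals, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(vals) - target) < 4 * mc_se + 0.01

    def test_zero_subject_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_agreement([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])


class TestTwoSampleT:
    def test_identical_samples(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_degenerate_zero_variance(self):
        with pytest.raises(UndefinedStatisticError):
            two_sample_t([0.0, 0.0], [1.0, 1.0])

    def test_matches_pooled_formula(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(1, 1, 9)
        t, _ = two_sample_t(x, y)
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        expected = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))
        assert t == pytest.approx(expected, rel=1e-12)

    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(99)
        n_rep, n = 4000, 15
        x = rng.normal(size=(n_rep, n))
        y = rng.normal(size=(n_rep, n))
        rej = sum(
            two_sample_t(x[i], y[i])[1] < 0.05 for i in range(n_rep)
        )
        assert abs(rej / n_rep - 0.05) < 0.012
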