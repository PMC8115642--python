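"""Non-survival statistics for the cohort analyses.

Fisher's exact test on 2x2 tables (imaging stratum vs pCR/RD),
diagnostic performance of binary predictors against pathological
truth, Spearman rank correlation, inter-reader agreement by the
two-way random-effects absolute-agreement single-rater intraclass
correlation coefficient (ICC(2,1)), and the two-sample Student t-test.

Percentages are carried at full precision; display rounding (1 decimal
place for percentages, 4 for p-values) happens only in report
formatting.
"""

from __future__ import annotations

import enum
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import UndefinedStatisticError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a, b / c, d: rows = imaging stratum, columns = pCR / RD."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        counts = (self.a, self.b, self.c, self.d)
        if any(x < 0 for x in counts):
            raise ValueError(f"counts must be non-negative, got {counts}")
        if sum(counts) == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class ConfusionMatrix:
    """Prediction vs pathological truth counts."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if any(x < 0 for x in (self.tp, self.fp, self.fn, self.tn)):
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and accuracy in percent.

    A metric whose denominator is zero is undefined and reported as
    NaN (with a warning at computation time).
    """

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


class AgreementCategory(enum.Enum):
    POOR = "poor"
    MODERATE = "moderate"
    GOOD = "good"
    EXCELLENT = "excellent"


@dataclass(frozen=True)
class IccResult:
    icc: float
    category: AgreementCategory


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value by the sum-of-small-p definition.

    Sums, over all tables with the observed margins, the hypergeometric
    probabilities that do not exceed the observed table's probability
    (up to a 1e-7 relative tolerance guarding floating-point ties).
    Degenerate margins (an all-zero row or column) give p = 1.
    """
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.warning("degenerate 2x2 margins: Fisher p-value is 1 by convention")
        return 1.0
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def _ratio_pct(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} is undefined (zero denominator)", stacklevel=3)
        return math.nan
    return 100.0 * num / den


def diagnostic_performance(cm: ConfusionMatrix) -> DiagnosticPerformance:
    """Sensitivity, specificity, PPV, NPV and overall accuracy (percent)."""
    return DiagnosticPerformance(
        sensitivity=_ratio_pct(cm.tp, cm.tp + cm.fn, "sensitivity"),
        specificity=_ratio_pct(cm.tn, cm.tn + cm.fp, "specificity"),
        ppv=_ratio_pct(cm.tp, cm.tp + cm.fp, "PPV"),
        npv=_ratio_pct(cm.tn, cm.tn + cm.fn, "NPV"),
        accuracy=_ratio_pct(cm.tp + cm.tn, cm.n, "accuracy"),
    )


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with mid-ranks for ties.

    The p-value uses the large-sample t approximation.  A constant
    sequence has no rank correlation and raises
    :class:`UndefinedStatisticError`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("constant sequence: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(x))


def icc_category(icc: float) -> AgreementCategory:
    """Agreement category of an ICC value.

    Below 0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good, above 0.90
    excellent; exact boundary values fall in the lower-named category.
    """
    if icc < 0.50:
        return AgreementCategory.POOR
    if icc <= 0.75:
        return AgreementCategory.MODERATE
    if icc <= 0.90:
        return AgreementCategory.GOOD
    return AgreementCategory.EXCELLENT


def icc_agreement(ratings_r1, ratings_r2) -> IccResult:
    """Inter-reader agreement by ICC(2,1).

    Two-way random-effects, absolute-agreement, single-rater ICC from
    the two-way ANOVA decomposition of an n-subjects x 2-raters rating
    matrix:

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    with MSR the between-subject, MSC the between-rater and MSE the
    residual mean squares.  Zero between-subject variance leaves the
    coefficient undefined.
    """
    r1 = np.asarray(ratings_r1, dtype=float)
    r2 = np.asarray(ratings_r2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("rating sequences must be 1-D and of equal length")
    n = len(r1)
    if n < 3:
        raise ValueError("need at least 3 rated subjects")
    data = np.column_stack([r1, r2])
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_rater = n * np.sum((rater_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_subj - ss_rater
    msr = ss_subj / (n - 1)
    msc = ss_rater / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr <= 0:
        raise UndefinedStatisticError(
            "zero between-subject variance: ICC undefined"
        )
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return IccResult(icc=float(icc), category=icc_category(float(icc)))


def two_sample_t(x, y, *, welch: bool = False) -> tuple[float, float]:
    """Two-sided two-sample t-test; pooled-variance (Student) by default.

    Set ``welch=True`` for the unequal-variance form.  Zero pooled
    variance (both samples constant and equal spread impossible) makes
    the statistic undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 observations per group")
    if not welch:
        pooled = ((len(x) - 1) * np.var(x, ddof=1) + (len(y) - 1) * np.var(y, ddof=1))
        if pooled == 0:
            if np.mean(x) == np.mean(y):
                return 0.0, 1.0
            raise UndefinedStatisticError("zero pooled variance: t undefined")
    t, p = sps.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def format_percent(value: float) -> str:
    """Display rounding for percentages: 1 decimal place."""
    return "nan" if math.isnan(value) else f"{value:.1f}"


def format_p(value: float) -> str:
    """Display rounding for p-values: 4 decimal places."""
    return f"{value:.4f}"
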