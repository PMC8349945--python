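"""Statistical evaluation: ROC/Youden, DeLong AUC comparison, group
tests with a normality gate, confusion metrics, and ICC.

Implements the statistics used to derive and validate malignancy
cutoffs. ROC curves are empirical; the AUC equals the normalised
Mann-Whitney U statistic (ties count one half) and its confidence
interval uses the DeLong structural-components variance estimator, which
also drives paired and unpaired AUC comparisons. The optimal cutoff
maximises the Youden index J = sensitivity + specificity - 1 over the
midpoints between consecutive observed values.

Group differences are tested with a Welch t test when both groups pass a
Shapiro-Wilk normality check (alpha = 0.05), otherwise with the
Mann-Whitney U test (exact enumeration for pooled n <= 12, normal
approximation with tie correction above). Rater agreement uses the
two-way random-effects, absolute-agreement, single-measure intraclass
correlation coefficient ICC(2,1) by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

__all__ = [
    "LabeledSample",
    "ROCResult",
    "ConfusionTable",
    "GroupTestResult",
    "roc",
    "youden_cutoff",
    "delong_compare",
    "group_test",
    "confusion_metrics",
    "accuracy_from_rates",
    "icc",
]


@dataclass
class LabeledSample:
    """Scalar marker values with binary labels and a test direction.

    ``direction`` states which way the marker points: with
    ``lower_is_positive`` (e.g. D' for malignancy) smaller values call
    the positive class; with ``higher_is_positive`` (e.g. percent-red)
    larger values do.
    """

    values: np.ndarray
    labels: np.ndarray  # True = positive class
    direction: str = "higher_is_positive"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=bool)
        if self.values.shape != self.labels.shape or self.values.ndim != 1:
            raise ValueError("values and labels must be 1-D and aligned")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")
        if self.direction not in ("lower_is_positive", "higher_is_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.labels.all() or not self.labels.any():
            raise ValueError("both classes must be non-empty")

    def scores(self) -> np.ndarray:
        """Values mapped so that higher score = more positive."""
        return self.values if self.direction == "higher_is_positive" else -self.values

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return int((~self.labels).sum())


@dataclass
class ROCResult:
    """Empirical ROC curve with AUC, DeLong CI and Youden optimum."""

    thresholds: np.ndarray  # candidate cutoffs in original value space
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_var: float
    auc_ci95: tuple[float, float]
    optimal_cutoff: float
    optimal_sens: float
    optimal_spec: float
    optimal_acc: float
    sample: LabeledSample = field(repr=False)


@dataclass(frozen=True)
class ConfusionTable:
    """2x2 diagnostic table of non-negative integer counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 or int(c) != c for c in counts):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg


@dataclass(frozen=True)
class GroupTestResult:
    test_name: str  # {"welch_t", "mann_whitney_exact", "mann_whitney_normal"}
    statistic: float
    p_value: float


# ---------------------------------------------------------------------------
# ROC / AUC / DeLong


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """DeLong placement values V10 (per positive), V01 (per negative), AUC.

    psi(x, y) = 1 if x > y, 1/2 if x == y, 0 otherwise; V10_i is the mean
    of psi over all negatives, V01_j the mean over all positives, and the
    AUC is the grand mean of psi.
    """
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    return v10, v01, float(psi.mean())


def _auc_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = float(np.var(v10, ddof=1)) if v10.size > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if v01.size > 1 else 0.0
    return s10 / v10.size + s01 / v01.size


def _candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0 if u.size > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def _operating_counts(sample: LabeledSample, cutoffs: np.ndarray,
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Integer (TP, TN) counts at each cutoff under the strict rule.

    lower_is_positive: positive call iff value < cutoff;
    higher_is_positive: positive call iff value > cutoff. Integer counts
    keep the Youden maximisation exact (no float ties at 1/n precision).
    """
    pos = sample.values[sample.labels]
    neg = sample.values[~sample.labels]
    if sample.direction == "lower_is_positive":
        tp = (pos[:, None] < cutoffs[None, :]).sum(axis=0)
        tn = (neg[:, None] >= cutoffs[None, :]).sum(axis=0)
    else:
        tp = (pos[:, None] > cutoffs[None, :]).sum(axis=0)
        tn = (neg[:, None] <= cutoffs[None, :]).sum(axis=0)
    return tp.astype(np.int64), tn.astype(np.int64)


def roc(sample: LabeledSample) -> ROCResult:
    """Empirical ROC analysis of one marker.

    The AUC is the normalised Mann-Whitney U (pair-counting with ties =
    1/2), its 95% CI the DeLong Wald interval clipped to [0, 1], and the
    optimal operating point the Youden maximum (see ``youden_cutoff``).
    """
    scores = sample.scores()
    v10, v01, auc = _placements(scores[sample.labels], scores[~sample.labels])
    var = _auc_variance(v10, v01)
    half = 1.959963984540054 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    cutoffs = _candidate_cutoffs(sample.values)
    tp, tn = _operating_counts(sample, cutoffs)
    sens = tp / sample.n_pos
    spec = tn / sample.n_neg
    result = ROCResult(cutoffs, sens, spec, auc, var, ci,
                       math.nan, math.nan, math.nan, math.nan, sample)
    cut, (s, p, a) = youden_cutoff(result)
    result.optimal_cutoff, result.optimal_sens = cut, s
    result.optimal_spec, result.optimal_acc = p, a
    return result


def youden_cutoff(roc_result: ROCResult) -> tuple[float, tuple[float, float, float]]:
    """Cutoff maximising J = sens + spec - 1, with its (sens, spec, acc).

    Candidates are the midpoints between consecutive sorted unique marker
    values plus +/-inf. Ties on J are broken towards higher sensitivity,
    then towards the smaller cutoff value; accuracy uses the sample's
    class prevalences.
    """
    sample = roc_result.sample
    n_pos, n_neg = sample.n_pos, sample.n_neg
    tp, tn = _operating_counts(sample, roc_result.thresholds)
    # integer-valued Youden objective: J * n_pos * n_neg
    j_num = tp * n_neg + tn * n_pos
    order = np.lexsort((roc_result.thresholds, -tp, -j_num))
    best = order[0]
    sens = tp / n_pos
    spec = tn / n_neg
    acc = (tp[best] + tn[best]) / (n_pos + n_neg)
    return float(roc_result.thresholds[best]), (float(sens[best]), float(spec[best]), float(acc))


def delong_compare(roc_a: ROCResult, roc_b: ROCResult, paired: bool,
                   ) -> tuple[float, float]:
    """DeLong z test of AUC_a vs AUC_b; returns (z, two-sided p).

    For paired markers (same subjects, same labels) the covariance of the
    placement values enters var(AUC_a - AUC_b); independent samples use
    the sum of the single-marker variances. Identical AUCs with zero
    variance of the difference give z = 0, p = 1.
    """
    sa, sb = roc_a.sample, roc_b.sample
    va10, va01, auc_a = _placements(sa.scores()[sa.labels], sa.scores()[~sa.labels])
    vb10, vb01, auc_b = _placements(sb.scores()[sb.labels], sb.scores()[~sb.labels])
    if paired:
        if sa.values.size != sb.values.size or not np.array_equal(sa.labels, sb.labels):
            raise ValueError("paired comparison requires identical subjects and labels")
        m, n = va10.size, va01.size
        cov10 = float(np.cov(va10, vb10, ddof=1)[0, 1]) if m > 1 else 0.0
        cov01 = float(np.cov(va01, vb01, ddof=1)[0, 1]) if n > 1 else 0.0
        var = (_auc_variance(va10, va01) + _auc_variance(vb10, vb01)
               - 2.0 * (cov10 / m + cov01 / n))
    else:
        var = _auc_variance(va10, va01) + _auc_variance(vb10, vb01)
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.copysign(math.inf, diff)
    else:
        z = diff / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(1.0, p))


# ---------------------------------------------------------------------------
# group tests


def _mwu_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney test by full enumeration.

    Enumerates every assignment of the pooled midranks to group a,
    computes the U distribution and returns p = min(1, 2 min(P(U <= u),
    P(U >= u))). Handles ties through midranks; intended for pooled
    n <= 12 (<= 924 combinations).
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n1 = a.size
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u_all = np.array([sum(ranks[list(idx)]) for idx in combinations(range(pooled.size), n1)])
    u_all = u_all - n1 * (n1 + 1) / 2.0
    p_le = np.mean(u_all <= u_obs + 1e-12)
    p_ge = np.mean(u_all >= u_obs - 1e-12)
    return float(u_obs), float(min(1.0, 2.0 * min(p_le, p_ge)))


def group_test(a, b, alpha_normality: float = 0.05) -> GroupTestResult:
    """Two-group difference test with a Shapiro-Wilk normality gate.

    Both groups normal at ``alpha_normality`` -> two-sided Welch t test;
    otherwise Mann-Whitney U (exact enumeration when n1 + n2 <= 12, else
    normal approximation with tie and continuity correction). Groups of
    fewer than 3 observations cannot be tested for normality and go to
    the Mann-Whitney branch.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs at least 2 observations")

    def looks_normal(x: np.ndarray) -> bool:
        if x.size < 3 or np.ptp(x) == 0:
            return False
        return stats.shapiro(x).pvalue >= alpha_normality

    if looks_normal(a) and looks_normal(b):
        res = stats.ttest_ind(a, b, equal_var=False)
        return GroupTestResult("welch_t", float(res.statistic), float(res.pvalue))
    if a.size + b.size <= 12:
        u, p = _mwu_exact(a, b)
        return GroupTestResult("mann_whitney_exact", u, p)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return GroupTestResult("mann_whitney_normal", float(res.statistic), float(res.pvalue))


# ---------------------------------------------------------------------------
# confusion metrics


def confusion_metrics(table: ConfusionTable) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) of a 2x2 table.

    Raises on zero denominators instead of silently returning NaN.
    Rounding to the conventional 3 decimals is left to display code.
    """
    if table.n_pos == 0 or table.n_neg == 0 or table.total == 0:
        raise ValueError("confusion table has an empty class; metrics undefined")
    sens = table.tp / table.n_pos
    spec = table.tn / table.n_neg
    acc = (table.tp + table.tn) / table.total
    return sens, spec, acc


def accuracy_from_rates(sens: float, spec: float, n_pos: int, n_neg: int) -> float:
    """Pooled accuracy implied by printed sensitivity/specificity.

    Reconstructs the integer counts (TP = round(sens * n_pos), TN =
    round(spec * n_neg)) and returns their accuracy; this is exact when
    sens/spec were themselves printed from integer counts.
    """
    tp = round(sens * n_pos)
    tn = round(spec * n_neg)
    return (tp + tn) / (n_pos + n_neg)


# ---------------------------------------------------------------------------
# intraclass correlation


def icc(ratings: np.ndarray, form: str = "ICC2") -> float:
    """Single-measure intraclass correlation of a subjects x raters matrix.

    Forms: ``ICC1`` one-way random; ``ICC2`` two-way random, absolute
    agreement (default — the appropriate model when raters/sessions are
    interchangeable and systematic shifts should count as disagreement);
    ``ICC3`` two-way mixed, consistency. The matrix must be complete.
    Raises when the between-subject variance is zero (coefficient
    undefined).
    """
    x = np.asarray(ratings, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("ratings must be a subjects x raters matrix, >= 2 each")
    if not np.all(np.isfinite(x)):
        raise ValueError("ratings matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    msw = (ss_total - ss_rows) / (n * (k - 1))

    if ss_rows == 0:
        raise ValueError("zero between-subject variance; ICC undefined")
    if form == "ICC1":
        denom = msr + (k - 1) * msw
        return float((msr - msw) / denom)
    if form == "ICC2":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
        return float((msr - mse) / denom)
    if form == "ICC3":
        denom = msr + (k - 1) * mse
        return float((msr - mse) / denom)
    raise ValueError(f"unknown ICC form {form!r}")
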