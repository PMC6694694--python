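"""Screening diagnostic statistics and group-comparison inference.

Everything a screening evaluation against a clinician reference needs:
confusion matrices, sensitivity/specificity and their complements (the
missed-diagnosis rate 1 - sensitivity and the misdiagnosis rate
1 - specificity), predictive values, unweighted Cohen's kappa with the
conventional qualitative bands, ROC/AUC, plus one-way ANOVA computed
directly from per-group (n, mean, SD) summaries and Fisher-LSD pairwise
comparisons with the pooled error term.

The ANOVA-from-summaries identity: with group sizes n_i, means m_i and
sample SDs s_i,

    SS_between = sum n_i (m_i - m)^2,   m = weighted grand mean
    SS_within  = sum (n_i - 1) s_i^2

which equals the raw-data decomposition exactly, so published summary
tables can be re-analyzed without the raw data.  LSD pairwise tests use
SE = sqrt(MS_within (1/n_i + 1/n_j)) on df_within, unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ContractError, InfiniteFError, UndefinedMetricError

# ---------------------------------------------------------------------------
# confusion matrix and screening metrics


@dataclass
class ConfusionMatrix:
    """Reference (rows) by test (columns) label counts."""

    labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ContractError("counts must be a labels x labels table")
        if (self.counts < 0).any():
            raise ContractError("counts must be non-negative")
        if self.counts.sum() == 0:
            raise ContractError("grand total must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self, row_percent: bool = False) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=self.labels, columns=self.labels)
        if row_percent:
            pct = self.counts / self.counts.sum(axis=1, keepdims=True).clip(min=1) * 100
            df = pd.DataFrame(
                [
                    [f"{c} ({p:.1f}%)" for c, p in zip(crow, prow)]
                    for crow, prow in zip(self.counts, pct)
                ],
                index=self.labels,
                columns=self.labels,
            )
        return df


def confusion_matrix(
    pairs: list[tuple[str, str]], labels: list[str]
) -> ConfusionMatrix:
    """Tabulate (reference, test) label pairs."""
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for ref, test in pairs:
        if ref not in index or test not in index:
            raise ContractError(f"unknown label in pair ({ref!r}, {test!r})")
        counts[index[ref], index[test]] += 1
    return ConfusionMatrix(list(labels), counts)


@dataclass
class ScreeningMetrics:
    sensitivity: float
    specificity: float
    missed_rate: float
    misdiagnosis_rate: float
    accuracy: float
    ppv: float
    npv: float

    def __post_init__(self) -> None:
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ContractError(f"{name} out of [0, 1]")


def screening_metrics(
    cm: ConfusionMatrix, positive_labels: set[str] | list[str]
) -> ScreeningMetrics:
    """Collapse to binary by the positive-label set, then apply the
    standard definitions (sensitivity = diseased correctly called,
    specificity = non-diseased correctly called; missed = 1 - sensitivity,
    misdiagnosis = 1 - specificity)."""
    pos = set(positive_labels)
    unknown = pos - set(cm.labels)
    if unknown:
        raise ContractError(f"positive labels not in matrix: {sorted(unknown)}")
    is_pos = np.array([lab in pos for lab in cm.labels])
    tp = int(cm.counts[np.ix_(is_pos, is_pos)].sum())
    fn = int(cm.counts[np.ix_(is_pos, ~is_pos)].sum())
    fp = int(cm.counts[np.ix_(~is_pos, is_pos)].sum())
    tn = int(cm.counts[np.ix_(~is_pos, ~is_pos)].sum())
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity", "no positive reference cases")
    if tn + fp == 0:
        raise UndefinedMetricError("specificity", "no negative reference cases")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    total = tp + fn + fp + tn
    if tp + fp == 0:
        raise UndefinedMetricError("ppv", "no positive test calls")
    if tn + fn == 0:
        raise UndefinedMetricError("npv", "no negative test calls")
    return ScreeningMetrics(
        sensitivity=sens,
        specificity=spec,
        missed_rate=1.0 - sens,
        misdiagnosis_rate=1.0 - spec,
        accuracy=(tp + tn) / total,
        ppv=tp / (tp + fp),
        npv=tn / (tn + fn),
    )


# ---------------------------------------------------------------------------
# Cohen's kappa

KAPPA_BANDS = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (np.inf, "excellent"),
)


def kappa_band(kappa: float) -> str:
    """Qualitative agreement band for a kappa value (cut points 0.2, 0.4,
    0.6, 0.8)."""
    for upper, name in KAPPA_BANDS:
        if kappa <= upper:
            return name
    raise AssertionError("unreachable")


def cohen_kappa(cm: ConfusionMatrix) -> tuple[float, str]:
    """Unweighted Cohen's kappa (p_o - p_e)/(1 - p_e) with chance agreement
    from the row/column margins, plus its qualitative band."""
    n = cm.total
    p_o = np.trace(cm.counts) / n
    row = cm.counts.sum(axis=1) / n
    col = cm.counts.sum(axis=0) / n
    p_e = float(row @ col)
    if abs(1.0 - p_e) < 1e-12:
        raise UndefinedMetricError("kappa", "degenerate margins (p_e = 1)")
    kappa = (p_o - p_e) / (1.0 - p_e)
    return float(kappa), kappa_band(float(kappa))


# ---------------------------------------------------------------------------
# ROC


@dataclass
class RocCurve:
    points: list[tuple[float, float]]  # (1 - specificity, sensitivity)
    auc: float

    def __post_init__(self) -> None:
        xs = [p[0] for p in self.points]
        ys = [p[1] for p in self.points]
        if not (np.diff(xs) >= -1e-12).all() or not (np.diff(ys) >= -1e-12).all():
            raise ContractError("ROC points must be monotone nondecreasing")


def roc_auc(scores: list[float], labels: list[int]) -> RocCurve:
    """Threshold sweep over the unique scores; AUC by the trapezoid rule
    (equal to the pairwise concordance statistic)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ContractError("labels must be binary 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # one operating point per unique threshold
    distinct = np.r_[np.flatnonzero(np.diff(s)), s.size - 1]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(list(zip(map(float, fpr), map(float, tpr))), auc)


# ---------------------------------------------------------------------------
# ANOVA from summary statistics, LSD pairwise


@dataclass
class AnovaResult:
    k: int
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    F: float
    p: float

    def __post_init__(self) -> None:
        if self.F < 0:
            raise ContractError("F must be non-negative")
        if self.df_within < 1:
            raise ContractError("df_within must be >= 1")


@dataclass
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    standard_error: float
    p: float
    ci95: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not lo - 1e-9 <= self.mean_difference <= hi + 1e-9:
            raise ContractError("CI must bracket the mean difference")


def anova_oneway_summary(groups: list[tuple[int, float, float]]) -> AnovaResult:
    """One-way ANOVA from per-group (n, mean, sample SD) triples."""
    if len(groups) < 2:
        raise ContractError("need at least 2 groups")
    ns = np.array([g[0] for g in groups], dtype=np.float64)
    means = np.array([g[1] for g in groups], dtype=np.float64)
    sds = np.array([g[2] for g in groups], dtype=np.float64)
    if (ns < 2).any():
        raise ContractError("each group needs n >= 2")
    if (sds < 0).any():
        raise ContractError("SDs must be non-negative")
    k = len(groups)
    N = ns.sum()
    grand = float((ns * means).sum() / N)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1) * sds**2).sum())
    df_b, df_w = k - 1, int(N) - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w
    if ms_w <= 0:
        raise InfiniteFError("within-group mean square is zero; F is unbounded")
    F = ms_b / ms_w
    p = float(stats.f.sf(F, df_b, df_w))
    return AnovaResult(k, df_b, df_w, ms_b, ms_w, float(F), p)


def lsd_pairwise(
    anova: AnovaResult,
    groups: list[tuple[int, float, float]],
    labels: list[str] | None = None,
    method: str = "lsd",
) -> list[PairwiseComparison]:
    """Fisher-LSD pairwise comparisons using the pooled ANOVA error.

    For each ordered pair (i, j): difference = mean_i - mean_j,
    SE = sqrt(MS_within (1/n_i + 1/n_j)), two-sided p from t on df_within,
    CI95 = difference +/- t_{0.975, df} SE.  ``method='bonferroni'``
    multiplies p by the number of unordered pairs and widens the CI
    accordingly; the default is the unadjusted LSD.
    """
    if anova.k != len(groups):
        raise ContractError("anova was computed from a different number of groups")
    if method not in ("lsd", "bonferroni"):
        raise ContractError(f"unknown method {method!r}")
    labels = labels or [f"group{i + 1}" for i in range(len(groups))]
    if len(labels) != len(groups):
        raise ContractError("labels length mismatch")
    m = len(groups) * (len(groups) - 1) // 2
    alpha = 0.05 / m if method == "bonferroni" else 0.05
    tcrit = stats.t.ppf(1 - alpha / 2, anova.df_within)
    out = []
    for i, (ni, mi, _) in enumerate(groups):
        for j, (nj, mj, _) in enumerate(groups):
            if i == j:
                continue
            diff = mi - mj
            se = float(np.sqrt(anova.ms_within * (1.0 / ni + 1.0 / nj)))
            t = diff / se if se > 0 else np.inf
            p = float(2 * stats.t.sf(abs(t), anova.df_within))
            if method == "bonferroni":
                p = min(1.0, p * m)
            out.append(
                PairwiseComparison(
                    (labels[i], labels[j]),
                    float(diff),
                    se,
                    p,
                    (float(diff - tcrit * se), float(diff + tcrit * se)),
                )
            )
    return out


def format_p(p: float) -> str:
    """Table-style display: values below 0.001 print as '< 0.001'."""
    return "< 0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# cohort arithmetic


@dataclass
class CohortSummaryResult:
    n_total: int
    n_qualified: int
    n_disqualified: int
    prevalence_qualified: float

    @property
    def disqualified_pct(self) -> float:
        return round(self.n_disqualified / self.n_total * 100, 1)

    @property
    def prevalence_pct(self) -> float:
        return round(self.prevalence_qualified * 100, 1)


def cohort_summary(
    cm: ConfusionMatrix, dr_labels: set[str] | list[str], disqualified_label: str
) -> CohortSummaryResult:
    """Cohort arithmetic from a reference-by-test count table: how many
    photographs the reference graders disqualified, and DR prevalence
    among the qualified ones (reference rows in ``dr_labels`` over the
    qualified total)."""
    if disqualified_label not in cm.labels:
        raise ContractError(f"disqualified label {disqualified_label!r} not in table")
    unknown = set(dr_labels) - set(cm.labels)
    if unknown:
        raise ContractError(f"DR labels not in table: {sorted(unknown)}")
    row_totals = dict(zip(cm.labels, cm.counts.sum(axis=1)))
    n_total = cm.total
    n_disq = int(row_totals[disqualified_label])
    n_qual = n_total - n_disq
    if n_qual == 0:
        raise UndefinedMetricError("prevalence", "no qualified photographs")
    n_dr = int(sum(row_totals[lab] for lab in dr_labels))
    return CohortSummaryResult(n_total, n_qual, n_disq, n_dr / n_qual)
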