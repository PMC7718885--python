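"""Diagnostic-test statistics and normality-gated group comparisons.

ROC/AUC via the Mann-Whitney concordance identity, sensitivity/specificity
with exact (Clopper-Pearson) binomial confidence intervals, and a small
facade that picks parametric vs. non-parametric tests the way bench
scientists using common graphing software do: run a Lilliefors-corrected
Kolmogorov-Smirnov normality test on each group first, then choose the
test accordingly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "DiagnosticMetrics",
    "ComparisonResult",
    "roc_auc",
    "roc_curve",
    "sens_spec_at_cutoff",
    "exact_binomial_ci",
    "percent",
    "ks_normal",
    "ks_then_compare",
    "compare_subgroups",
    "correlate",
]


@dataclass
class DiagnosticMetrics:
    """Confusion counts and derived diagnostic quantities at one cutoff."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    auc: float
    auc_p: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0

    def as_dict(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity_ci": list(self.specificity_ci),
            "auc": self.auc,
            "auc_p": self.auc_p,
        }


@dataclass
class ComparisonResult:
    test_used: str
    statistic: float
    p_value: float
    posthoc: Optional[pd.DataFrame] = None
    warning: Optional[str] = None
    coefficient: Optional[float] = field(default=None)


def _as_bool_labels(labels) -> np.ndarray:
    lab = np.asarray(labels)
    if lab.dtype.kind in "USO":
        raise ValueError(
            "labels must be boolean case indicators; map group names first"
        )
    return lab.astype(bool)


def _split(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    lab = _as_bool_labels(labels)
    if s.shape != lab.shape:
        raise ValueError("scores and labels differ in length")
    case, control = s[lab], s[~lab]
    if case.size == 0 or control.size == 0:
        raise ValueError("both classes must be present (one class is empty)")
    return case, control


def roc_auc(scores, labels, positive_is_low: bool = True) -> tuple[float, float]:
    """AUC as the concordance probability, ties counted 1/2.

    With ``positive_is_low`` the AUC is P(case score < control score) plus
    half the probability of a tie -- the Mann-Whitney U identity.  The
    p-value is the two-sided Mann-Whitney test of group separation.
    """
    case, control = _split(scores, labels)
    oriented_case = -case if positive_is_low else case
    oriented_control = -control if positive_is_low else control
    res = stats.mannwhitneyu(oriented_case, oriented_control, alternative="two-sided")
    auc = res.statistic / (case.size * control.size)
    return float(auc), float(res.pvalue)


def roc_curve(scores, labels, positive_is_low: bool = True) -> pd.DataFrame:
    """ROC coordinates (FPR, TPR, cutoff) over all achievable cutoffs."""
    case, control = _split(scores, labels)
    s = np.asarray(scores, dtype=float)
    cuts = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    rows = []
    for c in cuts:
        if positive_is_low:
            tp, fp = np.sum(case < c), np.sum(control < c)
        else:
            tp, fp = np.sum(case > c), np.sum(control > c)
        rows.append((fp / control.size, tp / case.size, c))
    return pd.DataFrame(rows, columns=["fpr", "tpr", "cutoff"])


def exact_binomial_ci(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval.

    Uses the beta-quantile form; at ``successes == n`` the lower bound has
    the closed form (alpha/2)**(1/n) and the upper bound is 1.
    """
    if n < 1:
        raise ValueError("exact_binomial_ci requires n >= 1")
    if not 0 <= successes <= n:
        raise ValueError(f"successes {successes} outside [0, {n}]")
    alpha = 1.0 - confidence
    lo = 0.0 if successes == 0 else stats.beta.ppf(alpha / 2, successes, n - successes + 1)
    hi = 1.0 if successes == n else stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes)
    return float(lo), float(hi)


def percent(p: float) -> int:
    """Proportion -> integer percent, rounding half up (12/14 -> 86)."""
    return int(math.floor(p * 100.0 + 0.5))


def sens_spec_at_cutoff(
    scores,
    labels,
    cutoff: float = -6.7,
    positive_is_low: bool = True,
    confidence: float = 0.95,
) -> DiagnosticMetrics:
    """Sensitivity/specificity at a fixed cutoff with exact 95% CIs.

    Classification uses a strict inequality: with ``positive_is_low`` a
    score strictly below the cutoff is called diseased.
    """
    case, control = _split(scores, labels)
    if positive_is_low:
        tp, fn = int(np.sum(case < cutoff)), int(np.sum(case >= cutoff))
        fp, tn = int(np.sum(control < cutoff)), int(np.sum(control >= cutoff))
    else:
        tp, fn = int(np.sum(case > cutoff)), int(np.sum(case <= cutoff))
        fp, tn = int(np.sum(control > cutoff)), int(np.sum(control <= cutoff))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    auc, auc_p = roc_auc(scores, labels, positive_is_low=positive_is_low)
    return DiagnosticMetrics(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=sens,
        specificity=spec,
        sensitivity_ci=exact_binomial_ci(tp, tp + fn, confidence),
        specificity_ci=exact_binomial_ci(tn, tn + fp, confidence),
        auc=auc,
        auc_p=auc_p,
    )


def ks_normal(x, alpha: float = 0.05) -> bool:
    """Lilliefors-corrected KS normality gate.

    Returns True when normality is NOT rejected at ``alpha``.  Samples with
    fewer than 4 observations or zero variance cannot support the test and
    are treated as failing the gate (the non-parametric branch is then
    used, the conservative choice).
    """
    arr = np.asarray(x, dtype=float)
    if arr.size < 4 or np.std(arr, ddof=1) == 0:
        return False
    _, p = lilliefors(arr, dist="norm", pvalmethod="table")
    return bool(p >= alpha)


def _check_min_size(*samples, minimum: int = 3) -> None:
    for i, s in enumerate(samples):
        if len(np.asarray(s)) < minimum:
            raise ValueError(f"sample {i} has fewer than {minimum} observations")


def ks_then_compare(a, b, paired: bool = False, alpha: float = 0.05) -> ComparisonResult:
    """Two-group comparison with normality-gated test selection.

    Both groups normal (Lilliefors KS at ``alpha``) -> t-test (paired or
    unpaired per the flag); otherwise Mann-Whitney (unpaired) or Wilcoxon
    signed-rank (paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    _check_min_size(a, b)
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length samples")

    if paired and np.all(a == b):
        return ComparisonResult(
            "paired_t" if ks_normal(a, alpha) and ks_normal(b, alpha) else "wilcoxon_signed_rank",
            0.0,
            1.0,
            warning="all paired differences are zero; p set to 1",
        )
    if not paired and np.std(a) == 0 and np.std(b) == 0 and a[0] == b[0]:
        return ComparisonResult(
            "mann_whitney", 0.0, 1.0, warning="both groups constant and equal; p set to 1"
        )

    normal = ks_normal(a, alpha) and ks_normal(b, alpha)
    if normal:
        if paired:
            res = stats.ttest_rel(a, b)
            return ComparisonResult("paired_t", float(res.statistic), float(res.pvalue))
        res = stats.ttest_ind(a, b, equal_var=True)
        return ComparisonResult("unpaired_t", float(res.statistic), float(res.pvalue))
    if paired:
        res = stats.wilcoxon(a, b)
        return ComparisonResult("wilcoxon_signed_rank", float(res.statistic), float(res.pvalue))
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return ComparisonResult("mann_whitney", float(res.statistic), float(res.pvalue))


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's z-test on mean ranks with tie correction, Bonferroni-adjusted."""
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        k = groups[g].size
        mean_ranks[g] = ranks[start : start + k].mean()
        sizes[g] = k
        start += k
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in combinations(names, 2):
        se = math.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)) * m)
        rows.append((g1, g2, z, p))
    return pd.DataFrame(rows, columns=["group1", "group2", "statistic", "p_adj"])


def compare_subgroups(values, grouping, paired: bool = False, alpha: float = 0.05) -> ComparisonResult:
    """k-group comparison: two levels delegate to :func:`ks_then_compare`;
    three or more use ANOVA+Tukey when every group passes the KS gate and
    Kruskal-Wallis+Dunn otherwise."""
    values = np.asarray(values, dtype=float)
    grouping = np.asarray(grouping)
    levels = [g for g in pd.unique(grouping)]
    samples = {g: values[grouping == g] for g in levels}
    for g, s in samples.items():
        if s.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    if len(levels) == 2:
        return ks_then_compare(samples[levels[0]], samples[levels[1]], paired=paired, alpha=alpha)

    if all(ks_normal(s, alpha) for s in samples.values()):
        stat, p = stats.f_oneway(*samples.values())
        tukey = pairwise_tukeyhsd(values, grouping, alpha=alpha)
        posthoc = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        return ComparisonResult("anova_tukey", float(stat), float(p), posthoc=posthoc)
    stat, p = stats.kruskal(*samples.values())
    return ComparisonResult(
        "kruskal_wallis_dunn", float(stat), float(p), posthoc=_dunn_posthoc(samples)
    )


def correlate(x, y, alpha: float = 0.05) -> ComparisonResult:
    """Pearson correlation when both vectors pass the KS gate, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal lengths")
    _check_min_size(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    if ks_normal(x, alpha) and ks_normal(y, alpha):
        r, p = stats.pearsonr(x, y)
        return ComparisonResult("pearson", float(r), float(p), coefficient=float(r))
    r, p = stats.spearmanr(x, y)
    return ComparisonResult("spearman", float(r), float(p), coefficient=float(r))
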