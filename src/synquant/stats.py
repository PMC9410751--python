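"""Statistics harness mirroring the study's testing conventions.

Two-group comparisons are gated on normality: each group is checked with
the Shapiro-Wilk test and, when both pass, a two-tailed t test (unpaired,
equal variances assumed, or paired) is used; otherwise the Mann-Whitney U
(unpaired) or Wilcoxon signed-rank (paired) test. Repeated measurements on
the same cells across two genotypes are compared with a mixed
(between x within) repeated-measures ANOVA. No multiple-comparison
correction is applied. Group summaries are reported as mean +/- SEM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

__all__ = ["GroupComparison", "compare_groups", "rm_anova",
           "summarize_changes", "mean_sem"]

ALPHA_NORMALITY = 0.05


@dataclass
class GroupComparison:
    labels: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sems: tuple[float, float]
    test: str                       # 't' | 'paired t' | 'Mann-Whitney' | 'Wilcoxon'
    statistic: float
    p: float
    normality_p: tuple[float, float]


def mean_sem(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, float)
    return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size))


def compare_groups(a: np.ndarray, b: np.ndarray, paired: bool = False,
                   labels: tuple[str, str] = ("a", "b")) -> GroupComparison:
    """Normality-gated two-group comparison, two-tailed at alpha = 0.05."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 values per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal lengths")
    if paired and np.allclose(a, b):
        # identical vectors: zero difference, nothing to test
        pa = pb = 1.0
        return GroupComparison(labels, (a.size, b.size),
                               (float(a.mean()), float(b.mean())),
                               (mean_sem(a)[1], mean_sem(b)[1]),
                               "paired t", 0.0, 1.0, (pa, pb))
    pa = float(sps.shapiro(a).pvalue)
    pb = float(sps.shapiro(b).pvalue)
    normal = pa >= ALPHA_NORMALITY and pb >= ALPHA_NORMALITY
    if normal and paired:
        res = sps.ttest_rel(a, b)
        test = "paired t"
    elif normal:
        res = sps.ttest_ind(a, b, equal_var=True)
        test = "t"
    elif paired:
        res = sps.wilcoxon(a, b)
        test = "Wilcoxon"
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        test = "Mann-Whitney"
    return GroupComparison(labels, (a.size, b.size),
                           (float(a.mean()), float(b.mean())),
                           (mean_sem(a)[1], mean_sem(b)[1]), test,
                           float(res.statistic), float(res.pvalue), (pa, pb))


def rm_anova(table: pd.DataFrame, dv: str = "value", within: str = "pulse",
             between: str = "genotype", subject: str = "subject"
             ) -> tuple[float, float]:
    """Mixed repeated-measures ANOVA; returns (F, p) for the between factor.

    ``table`` is long-form: one row per subject x within-level, with a
    between-group column. Measurements must be balanced; missing cells are
    an error (no imputation).
    """
    counts = table.groupby([subject])[within].nunique()
    if counts.nunique() != 1:
        raise ValueError("unbalanced design: missing within-factor cells")
    if table[subject].nunique() < 2:
        raise ValueError("need more than one subject")
    if table.groupby(between)[subject].nunique().min() < 2:
        raise ValueError("need at least two subjects per group")
    aov = pg.mixed_anova(data=table, dv=dv, within=within, between=between,
                         subject=subject)
    row = aov[aov["Source"] == between].iloc[0]
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    return float(row["F"]), float(row[pcol])


def summarize_changes(mean_a: float, mean_b: float
                      ) -> tuple[float, float, str]:
    """Fold change and percent change of group b relative to group a.

    Returns ``(ratio, percent, direction)`` where ``ratio = mean_b/mean_a``.
    Increases are reported as percent larger than the reference; decreases
    as percent lower *of the larger value* (e.g. 55 -> 22 is a 60%
    reduction), matching the reporting convention of the source data.
    """
    if mean_a <= 0:
        raise ValueError("reference mean must be positive")
    ratio = mean_b / mean_a
    if ratio >= 1.0:
        return ratio, 100.0 * (mean_b - mean_a) / mean_a, "larger"
    return ratio, 100.0 * (mean_a - mean_b) / mean_a, "lower"
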