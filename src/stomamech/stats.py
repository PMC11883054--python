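"""Statistical comparisons used in the sweep analyses.

One-way ANOVA with Tukey HSD post hoc tests (compact letter display) for
comparing stress summaries between pressure scenarios, and a normality-
gated paired location test (paired t vs Wilcoxon signed-rank) for
within-pair guard-cell geometry comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["AnovaResult", "PairedTestResult", "anova_tukey", "paired_location_test"]


@dataclass(frozen=True)
class AnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    tukey_table: object  # statsmodels TukeyHSDResults
    letters: dict[str, str]  # compact letter display per group


@dataclass(frozen=True)
class PairedTestResult:
    test_name: str
    statistic: float
    p_value: float
    degenerate: bool = False


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> AnovaResult:
    """Classical one-way ANOVA plus Tukey HSD with letter groups.

    Unbalanced groups are handled by the standard unbalanced one-way
    decomposition.  Groups sharing a letter cannot be distinguished at
    ``alpha``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = list(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    f, p = sps.f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    distinct = _distinct_pairs(tukey)
    letters = _compact_letter_display(names, distinct)
    return AnovaResult(
        f_statistic=float(f),
        p_value=float(p),
        df_between=len(names) - 1,
        df_within=len(values) - len(names),
        tukey_table=tukey,
        letters=letters,
    )


def _distinct_pairs(tukey) -> set[tuple[str, str]]:
    out = set()
    data = tukey.summary().data[1:]
    for row in data:
        g1, g2, reject = str(row[0]), str(row[1]), row[-1]
        if reject is True or str(reject) == "True":
            out.add((g1, g2))
            out.add((g2, g1))
    return out


def _compact_letter_display(names: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Each letter marks a maximal set of mutually indistinguishable groups;
    identical lettering between two groups means they cannot be told
    apart.
    """
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all((name, other) not in distinct for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    # absorb subsets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letter_sets):
        for name in names:
            if name in s:
                out[name] += letter
    return out


def paired_location_test(values_gc1, values_gc2, alpha: float = 0.05) -> PairedTestResult:
    """Two-tailed paired comparison with a normality gate.

    Shapiro-Wilk on the pair differences at ``alpha`` selects a paired
    t-test (normal) or the Wilcoxon matched-pairs signed-rank test.
    Zero-variance differences are reported as degenerate (p = 1 when all
    differences are zero).
    """
    a = np.asarray(values_gc1, float)
    b = np.asarray(values_gc2, float)
    if a.shape != b.shape or len(a) < 3:
        raise ValueError("need at least 3 pairs of equal length")
    d = a - b
    if np.ptp(d) == 0.0:
        if np.all(d == 0):
            return PairedTestResult("degenerate", 0.0, 1.0, degenerate=True)
        return PairedTestResult("degenerate", np.inf, 0.0, degenerate=True)
    if sps.shapiro(d).pvalue > alpha:
        t = sps.ttest_rel(a, b)
        return PairedTestResult("paired t-test", float(t.statistic), float(t.pvalue))
    w = sps.wilcoxon(a, b, method="auto")
    return PairedTestResult("wilcoxon signed-rank", float(w.statistic), float(w.pvalue))
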