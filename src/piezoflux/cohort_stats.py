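"""Condition summaries and normality-gated two-group comparisons.

Interblade-distance cohorts are summarized as mean +- SEM over trimers
(trimers treated as replicates).  Two-condition comparisons follow a gated
procedure: each group's distribution is checked with the D'Agostino-Pearson
omnibus normality test; if both groups pass, a two-sided unpaired Student's
t-test is used, otherwise a two-sided Mann-Whitney U test.  No
multiple-comparison adjustment is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

#: Minimum group size for scipy's D'Agostino-Pearson test.
_NORMALTEST_MIN_N = 8


@dataclass(frozen=True)
class ConditionSummary:
    n: int
    mean: float  # nm
    sd: float  # nm, unbiased (n-1)
    sem: float  # nm, sd / sqrt(n); NaN (flagged) for n < 2

    @property
    def sem_defined(self) -> bool:
        return self.n >= 2


@dataclass(frozen=True)
class ComparisonResult:
    test: str  # "student-t" | "welch-t" | "mann-whitney"
    statistic: float
    p_value: float
    normality_p_a: float  # NaN when the gate could not run (n too small)
    normality_p_b: float
    effect_nm: float  # mean(A) - mean(B)
    gate_alpha: float


def summarize(distances) -> ConditionSummary:
    """Mean +- SEM summary of one condition's interblade distances."""
    x = np.asarray(distances, float)
    if x.size == 0:
        raise ValueError("empty distance vector")
    n = int(x.size)
    sd = float(x.std(ddof=1)) if n >= 2 else float("nan")
    return ConditionSummary(
        n=n,
        mean=float(x.mean()),
        sd=sd,
        sem=sd / np.sqrt(n) if n >= 2 else float("nan"),
    )


def compare_conditions(
    group_a,
    group_b,
    alpha_normality: float = 0.05,
    welch: bool = False,
) -> ComparisonResult:
    """Normality-gated two-sided comparison of two interblade-distance groups.

    If both groups pass D'Agostino-Pearson at ``alpha_normality``, an
    unpaired t-test is used (classic equal-variance Student form by default,
    Welch via ``welch=True``); otherwise Mann-Whitney U.  Groups too small
    for the normality test fall back to Mann-Whitney with a warning.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs n >= 3")
    effect = float(a.mean() - b.mean())
    if len(a) < _NORMALTEST_MIN_N or len(b) < _NORMALTEST_MIN_N:
        warnings.warn(
            "group too small for the D'Agostino-Pearson gate; "
            "falling back to Mann-Whitney",
            stacklevel=2,
        )
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        return ComparisonResult(
            "mann-whitney", float(stat), float(p),
            float("nan"), float("nan"), effect, alpha_normality,
        )
    p_norm_a = float(stats.normaltest(a).pvalue)
    p_norm_b = float(stats.normaltest(b).pvalue)
    if p_norm_a >= alpha_normality and p_norm_b >= alpha_normality:
        stat, p = stats.ttest_ind(a, b, equal_var=not welch)
        name = "welch-t" if welch else "student-t"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann-whitney"
    return ComparisonResult(
        name, float(stat), float(p), p_norm_a, p_norm_b, effect, alpha_normality
    )


def power_check(
    mean_shift: float,
    sd: float,
    n_per_group: int,
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> float:
    """Detection rate of the gated comparison under a Normal shift alternative.

    Simulates ``n_sims`` pairs of Normal groups differing by ``mean_shift``
    and returns the fraction with p < ``alpha``.  With shift 0 this is the
    procedure's type-I error rate.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_sims):
        a = rng.normal(mean_shift, sd, n_per_group)
        b = rng.normal(0.0, sd, n_per_group)
        if compare_conditions(a, b).p_value < alpha:
            hits += 1
    return hits / n_sims
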