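"""Statistical procedures for validation and scenario comparison.

All procedures operate on *summary statistics* — (n, mean, SD) or
(n, mean, SE) per group — because that is the form validation and comparison
data are published and exchanged in.

* :func:`welch_from_summary` — Welch two-sample t-test with a
  Welch–Satterthwaite df, used to validate simulated daily request counts
  against historical ones.
* :func:`anova_tukey` — balanced one-way ANOVA with Tukey HSD all-pairs
  comparisons: simultaneous confidence intervals and adjusted p-values from
  the studentized-range distribution.
* :func:`group_ci` — individual group CIs using the pooled ANOVA error
  variance (the convention used in balanced-design report tables).
* :func:`percent_reduction` — headline percentage improvement of a scenario
  mean over a baseline mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "WelchResult",
    "ComparisonResult",
    "welch_from_summary",
    "anova_tukey",
    "pooled_mse",
    "group_ci",
    "percent_reduction",
]


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, mean, and spread (SD, or SE for Welch inputs)."""

    label: str
    n: int
    mean: float
    sd: float = float("nan")
    se: float = float("nan")

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"group {self.label!r}: n must be >= 2")
        if not (math.isnan(self.sd) or self.sd >= 0):
            raise ValueError(f"group {self.label!r}: sd must be nonnegative")


@dataclass(frozen=True)
class WelchResult:
    diff: float
    se_diff: float
    df: float
    ci_low: float
    ci_high: float
    t: float
    p: float


@dataclass(frozen=True)
class ComparisonResult:
    pair: tuple[str, str]
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    t: float
    p_adj: float


def welch_from_summary(
    n1: int,
    mean1: float,
    se1: float,
    n2: int,
    mean2: float,
    se2: float,
    conf: float = 0.95,
    *,
    integer_df: bool = True,
) -> WelchResult:
    """Welch two-sample t-test computed from (n, mean, SE of mean) summaries.

    ``diff = mean1 - mean2``; ``se_diff = sqrt(se1^2 + se2^2)``; the
    Welch–Satterthwaite df is truncated to an integer by default, matching
    the convention of the common statistics packages these tables come from
    (``integer_df=False`` keeps the fractional value).
    """
    if min(n1, n2) < 2:
        raise ValueError("both groups need n >= 2")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    v1, v2 = se1**2, se2**2
    diff = mean1 - mean2
    se_diff = math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    if integer_df:
        df = float(int(df))
    tcrit = sps.t.ppf(0.5 + conf / 2.0, df)
    t = diff / se_diff
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(
        diff, se_diff, df, diff - tcrit * se_diff, diff + tcrit * se_diff, t, p
    )


def pooled_mse(groups: Sequence[GroupSummary]) -> tuple[float, int]:
    """Pooled within-group variance (ANOVA MSE) and error df, balanced design."""
    ns = {g.n for g in groups}
    if len(ns) != 1:
        raise ValueError("unequal group sizes are not supported (balanced design only)")
    n = ns.pop()
    k = len(groups)
    mse = float(np.mean([g.sd**2 for g in groups]))
    return mse, k * (n - 1)


def anova_tukey(
    groups: Sequence[GroupSummary], conf: float = 0.95
) -> list[ComparisonResult]:
    """All-pairs Tukey HSD comparisons from balanced group summaries.

    For ``k`` groups of common size ``n``: MSE is the mean of the group
    variances, ``se_diff = sqrt(2 MSE / n)``, the simultaneous CI half-width
    is ``q(conf, k, df) / sqrt(2) * se_diff`` with ``q`` the studentized-range
    quantile, and the adjusted p-value is the studentized-range tail
    probability of ``|t| * sqrt(2)``.

    Pairs are emitted in input order as (later group, earlier group), i.e.
    ``diff = mean_j - mean_i`` for ``i < j``.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    mse, df_error = pooled_mse(groups)
    n = groups[0].n
    k = len(groups)
    se_diff = math.sqrt(2.0 * mse / n)
    qcrit = sps.studentized_range.ppf(conf, k, df_error)
    half = qcrit / math.sqrt(2.0) * se_diff
    out: list[ComparisonResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = groups[i], groups[j]
            diff = gj.mean - gi.mean
            t = diff / se_diff if se_diff > 0 else 0.0
            if se_diff > 0:
                p = float(sps.studentized_range.sf(abs(t) * math.sqrt(2.0), k, df_error))
            else:
                p = 1.0 if diff == 0 else 0.0
            out.append(
                ComparisonResult(
                    (gj.label, gi.label),
                    diff,
                    se_diff,
                    diff - half,
                    diff + half,
                    t,
                    min(1.0, max(0.0, p)),
                )
            )
    return out


def group_ci(
    group: GroupSummary, mse: float, df_error: int, conf: float = 0.95
) -> tuple[float, float]:
    """Individual group CI using the pooled error variance.

    ``mean ± t(conf, df_error) * sqrt(mse / n)`` — the pooled-variance
    convention used in balanced one-way ANOVA report tables.
    """
    if mse < 0:
        raise ValueError("mse must be nonnegative")
    half = sps.t.ppf(0.5 + conf / 2.0, df_error) * math.sqrt(mse / group.n)
    return group.mean - half, group.mean + half


def percent_reduction(baseline_mean: float, new_mean: float) -> float:
    """Percent reduction of ``new_mean`` relative to ``baseline_mean``."""
    if baseline_mean <= 0:
        raise ValueError("baseline mean must be positive")
    return 100.0 * (baseline_mean - new_mean) / baseline_mean
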