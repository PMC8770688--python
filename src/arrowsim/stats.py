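"""Condition-comparison statistics: Welch t-tests, Cohen's d, Bonferroni
correction, F-tests of variance equality, and one-sample t-tests.

The pipeline mirrors the analysis applied to the arrowhead experiment: each
participant's mean score over a season's 30 trials is the unit of analysis;
each social condition is compared against the asocial baseline with a Welch
two-sample t-test, two comparisons per season, with the family-wise alpha
Bonferroni-divided across the six tests (0.05 / 6 ~= 0.0083).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

RESULT_COLUMNS = [
    "comparison", "season", "n1", "n2", "mean1", "mean2", "sd1", "sd2",
    "t", "df", "p", "d", "alpha", "significant",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics of one group of participant scores."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group size must be >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    """Outcome of one hypothesis test; ``df`` is fractional for Welch tests
    and a (df1, df2) pair for F-tests."""

    statistic: float
    df: object
    p: float
    effect_size: Optional[float] = None
    alpha_used: Optional[float] = None
    kind: str = ""


def welch_t(g1: GroupSummary, g2: GroupSummary) -> TestResult:
    """Welch two-sample t-test from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2), with Welch-Satterthwaite
    degrees of freedom and a two-sided p from the t distribution.
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    if v1 + v2 == 0:
        raise ValueError("both groups have zero variance; t statistic undefined")
    t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), kind="welch_t")


def cohens_d(g1: GroupSummary, g2: GroupSummary) -> float:
    """Cohen's d with the pooled standard deviation
    sqrt(((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2))."""
    pooled_var = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / (g1.n + g2.n - 2)
    if pooled_var == 0:
        raise ValueError("zero pooled standard deviation; d undefined")
    return float((g1.mean - g2.mean) / np.sqrt(pooled_var))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def f_variance_test(var1: float, n1: int, var2: float, n2: int) -> TestResult:
    """Two-sided F-test of variance equality: F = var1/var2 with
    (n1-1, n2-1) degrees of freedom."""
    if var1 <= 0 or var2 <= 0:
        raise ValueError("variances must be positive")
    f = var1 / var2
    df = (n1 - 1, n2 - 1)
    cdf = sps.f.cdf(f, *df)
    p = float(min(1.0, 2.0 * min(cdf, 1.0 - cdf)))
    return TestResult(statistic=float(f), df=df, p=p, kind="f_variance")


def one_sample_t(g: GroupSummary, mu0: float) -> TestResult:
    """One-sample t-test of the group mean against ``mu0``."""
    if g.sd == 0:
        raise ValueError("zero standard deviation; t statistic undefined")
    t = (g.mean - mu0) / (g.sd / np.sqrt(g.n))
    df = g.n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p=float(p), kind="one_sample_t")


def season_means(
    dataset: pd.DataFrame,
    score_col: str = "perceived_score",
    trials_per_season: Optional[int] = None,
) -> pd.DataFrame:
    """Per-participant per-season mean score.

    Participant-seasons with fewer trials than expected (the modal trial
    count, unless given) are excluded with a logged warning.
    """
    counts = dataset.groupby(["condition", "agent_id", "season"])[score_col].agg(
        ["mean", "count"]
    )
    expected = trials_per_season or int(counts["count"].mode().iloc[0])
    incomplete = counts[counts["count"] != expected]
    if len(incomplete):
        logger.warning(
            "excluding %d participant-season(s) with incomplete trials (expected %d)",
            len(incomplete), expected,
        )
        counts = counts[counts["count"] == expected]
    return counts["mean"].rename("season_mean").reset_index()


def compare_conditions(
    dataset: pd.DataFrame,
    baseline: str = "asocial",
    alpha: float = 0.05,
    score_col: str = "perceived_score",
) -> pd.DataFrame:
    """Welch t / Cohen's d of every non-baseline condition against the
    baseline, per season, on participant season means, with the Bonferroni
    threshold over all comparisons attached.

    Returns one row per (condition, season) with columns
    ``comparison, season, n1, n2, mean1, mean2, sd1, sd2, t, df, p, d,
    alpha, significant``.
    """
    conditions = sorted(dataset["condition"].unique())
    if baseline not in conditions:
        raise ValueError(f"baseline condition {baseline!r} not present in dataset")
    others = [c for c in conditions if c != baseline]
    if not others:
        raise ValueError("dataset must contain at least one non-baseline condition")

    means = season_means(dataset, score_col=score_col)
    seasons = sorted(means["season"].unique())
    m_comparisons = len(others) * len(seasons)
    threshold = bonferroni_threshold(alpha, m_comparisons)

    rows = []
    for condition in others:
        for season in seasons:
            def summarize(cond: str) -> GroupSummary:
                mask = (means["condition"] == cond) & (means["season"] == season)
                x = means.loc[mask, "season_mean"]
                return GroupSummary(label=cond, n=len(x), mean=float(x.mean()),
                                    sd=float(x.std(ddof=1)))

            g1, g2 = summarize(condition), summarize(baseline)
            res = welch_t(g1, g2)
            rows.append(
                {
                    "comparison": f"{condition}_vs_{baseline}",
                    "season": season,
                    "n1": g1.n, "n2": g2.n,
                    "mean1": g1.mean, "mean2": g2.mean,
                    "sd1": g1.sd, "sd2": g2.sd,
                    "t": res.statistic, "df": res.df, "p": res.p,
                    "d": cohens_d(g1, g2),
                    "alpha": threshold,
                    "significant": res.p < threshold,
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)
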