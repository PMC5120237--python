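"""Statistical analysis of the two-arm messaging trial.

The primary endpoint is the *daily rating*: for each arm and each message
day (ordinal 1..30), the mean of the ratings given by everyone in the arm
that day.  A day "agreed" when its daily rating is >= 4 (agree / strongly
agree); arms are compared on the count of agreed days with a Pearson
chi-square test (df=1, no continuity correction), on daily means over day
windows with a two-sample t test, and at follow-up on dichotomized 5-level
influence responses, one-day cessation, and moving up the five-level
readiness-to-quit ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .message_store import ReadinessStage
from .synthetic_data import Arm

__all__ = [
    "DailyRatingSeries",
    "Table2x2",
    "daily_means",
    "days_agreed",
    "chi2_2x2",
    "window_ttest",
    "WindowTTestResult",
    "dichotomize_influence",
    "ladder_movement",
    "round_half_away",
]

N_DAYS_DEFAULT = 30
AGREE_THRESHOLD = 4.0


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (display-style rounding)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class DailyRatingSeries:
    """Per-day mean ratings for one arm over message days 1..n_days."""

    arm: str
    means: np.ndarray  # (n_days,) NaN where no rating was given
    n: np.ndarray  # (n_days,) raters contributing each day

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if self.means.shape != self.n.shape:
            raise ValueError("means and n must be aligned")
        defined = self.means[~np.isnan(self.means)]
        if len(defined) and ((defined < 1) | (defined > 5)).any():
            raise ValueError("daily means must lie in [1, 5]")

    @property
    def n_days(self) -> int:
        return len(self.means)

    @property
    def defined_days(self) -> np.ndarray:
        return ~np.isnan(self.means)


@dataclass
class Table2x2:
    """2x2 contingency table with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, str] = ("row0", "row1")
    col_labels: tuple[str, str] = ("col0", "col1")

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (2, 2):
            raise ValueError("counts must be 2x2")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if self.counts.sum() == 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def daily_means(
    logs: pd.DataFrame, arm: str | Arm = "", n_days: int = N_DAYS_DEFAULT
) -> DailyRatingSeries:
    """Daily mean rating series for one arm's session logs.

    ``logs`` is tidy with columns ``user``, ``day`` (ordinal 1..n_days) and
    ``rating``; day d's mean averages over all users with a rating at
    ordinal d.  Days with no rating are NaN with n=0.
    """
    if len(logs) == 0 or logs["rating"].notna().sum() == 0:
        raise ValueError("no ratings to aggregate")
    arm_name = arm.value if isinstance(arm, Arm) else str(arm)
    means = np.full(n_days, np.nan)
    counts = np.zeros(n_days, dtype=int)
    rated = logs.dropna(subset=["rating"])
    grouped = rated.groupby("day")["rating"]
    for day, vals in grouped:
        d = int(day)
        if not 1 <= d <= n_days:
            raise ValueError(f"day {d} outside 1..{n_days}")
        means[d - 1] = float(vals.mean())
        counts[d - 1] = len(vals)
    return DailyRatingSeries(arm=arm_name, means=means, n=counts)


def days_agreed(series: DailyRatingSeries, threshold: float = AGREE_THRESHOLD) -> tuple[int, int]:
    """(number of defined days with mean >= threshold, number of defined days)."""
    defined = series.defined_days
    if not defined.any():
        raise ValueError("series has no defined days")
    count = int(np.sum(series.means[defined] >= threshold))
    return count, int(defined.sum())


def chi2_2x2(table: Table2x2 | np.ndarray | Sequence) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table, df=1, no continuity correction.

    Raises on zero row or column marginals (an expected count would be 0).
    """
    t = table if isinstance(table, Table2x2) else Table2x2(np.asarray(table))
    counts = t.counts
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValueError("zero marginal: chi-square is undefined")
    stat, p, dof, _ = stats.chi2_contingency(counts, correction=False)
    assert dof == 1
    return float(stat), float(p)


@dataclass
class WindowTTestResult:
    window: tuple[int, int]
    mean_a: float
    mean_b: float
    se_a: float
    se_b: float
    n_days: int
    t: float
    p: float


def window_ttest(
    series_a: DailyRatingSeries,
    series_b: DailyRatingSeries,
    window: tuple[int, int] | None = None,
) -> WindowTTestResult:
    """Two-sample Student t test on the daily means within a day window.

    Days missing in either series are excluded pairwise; the effective
    number of days is reported.  Per-arm means and standard errors describe
    the daily-mean series within the window.
    """
    if window is None:
        window = (1, min(series_a.n_days, series_b.n_days))
    lo, hi = window
    if lo < 1 or hi > min(series_a.n_days, series_b.n_days) or lo > hi:
        raise ValueError(f"window {window} outside 1..{min(series_a.n_days, series_b.n_days)}")
    sl = slice(lo - 1, hi)
    a, b = series_a.means[sl], series_b.means[sl]
    keep = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[keep], b[keep]
    if len(a) < 2:
        raise ValueError("need at least two jointly defined days in the window")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):  # zero variance in both samples
        t, p = (0.0, 1.0) if np.allclose(a.mean(), b.mean()) else (np.inf, 0.0)
    return WindowTTestResult(
        window=(lo, hi),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        se_a=float(a.std(ddof=1) / np.sqrt(len(a))),
        se_b=float(b.std(ddof=1) / np.sqrt(len(b))),
        n_days=int(len(a)),
        t=float(t),
        p=float(p),
    )


def dichotomize_influence(
    responses: pd.DataFrame, question: str | None = None
) -> Table2x2 | dict[str, Table2x2]:
    """Dichotomized (<=3 vs >=4) influence responses cross-tabbed by arm.

    ``responses`` is tidy with columns ``arm``, ``question`` and ``rating``
    (5-level Likert codes).  Rows of each table: disagree/neutral (<=3)
    then agree/strongly agree (>=4); columns: comparison then intervention.
    Returns one table, or a dict keyed by question when ``question`` is
    None.
    """
    r = responses["rating"]
    if r.isna().any() or (r < 1).any() or (r > 5).any():
        raise ValueError("influence responses must be coded 1..5")
    if question is None:
        return {
            q: dichotomize_influence(responses, q) for q in sorted(responses["question"].unique())
        }
    sub = responses[responses["question"] == question]
    counts = np.zeros((2, 2), dtype=np.int64)
    for _, row in sub.iterrows():
        i = 0 if row["rating"] <= 3 else 1
        j = 0 if row["arm"] == Arm.COMPARISON.value else 1
        counts[i, j] += 1
    return Table2x2(
        counts,
        row_labels=("disagree_neutral", "agree"),
        col_labels=(Arm.COMPARISON.value, Arm.INTERVENTION.value),
    )


def ladder_movement(
    baseline: Mapping, followup: Mapping, arms: Mapping
) -> tuple[pd.Series, Table2x2]:
    """Per-user moved-up indicator plus the arm x moved 2x2 table.

    A user moved up when the follow-up ladder level is strictly greater
    than baseline under the five-level ordering.  All three mappings are
    keyed by user id; every follow-up user must have a baseline and an arm.
    """
    moved = {}
    counts = np.zeros((2, 2), dtype=np.int64)
    for user, post in followup.items():
        if user not in baseline or user not in arms:
            raise ValueError(f"user {user!r} lacks a paired baseline or arm record")
        pre_s = ReadinessStage.parse(baseline[user])
        post_s = ReadinessStage.parse(post)
        up = post_s > pre_s
        moved[user] = up
        arm = arms[user]
        arm_name = arm.value if isinstance(arm, Arm) else str(arm)
        i = 0 if arm_name == Arm.INTERVENTION.value else 1
        counts[i, 0 if up else 1] += 1
    table = Table2x2(
        counts,
        row_labels=(Arm.INTERVENTION.value, Arm.COMPARISON.value),
        col_labels=("moved_up", "not_moved"),
    )
    return pd.Series(moved, name="moved_up"), table
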