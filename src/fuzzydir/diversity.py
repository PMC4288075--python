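"""Name-diversity analysis: coverage curves and two-sample K-S tests.

How many distinct names does it take to cover, say, 70% of a
population?  Sorting a name-frequency table by descending count and
accumulating gives a *coverage curve*; a population with more diverse
names needs far more names to reach the same coverage, and its names
are correspondingly harder to spell.  Two curves (e.g. physician
surnames vs general-population surnames) are compared with a
two-sample Kolmogorov-Smirnov test on samples drawn from the coverage
increments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "coverage_count",
    "coverage_curve",
    "curve_to_sample",
    "ks_two_sample",
    "load_frequency_table",
]


def load_frequency_table(path: str | Path) -> pd.DataFrame:
    """Read a ``name,count`` CSV into a validated frequency table."""
    df = pd.read_csv(path)
    if not {"name", "count"}.issubset(df.columns):
        raise ValueError(f"{path}: header must contain name,count")
    return _validate(df)


def _validate(table: pd.DataFrame) -> pd.DataFrame:
    if table.empty:
        raise ValueError("frequency table is empty")
    if table["name"].duplicated().any():
        dupes = table.loc[table["name"].duplicated(), "name"].tolist()
        raise ValueError(f"duplicate names in frequency table: {dupes[:5]}")
    if (table["count"] < 0).any():
        raise ValueError("counts must be nonnegative")
    if not (table["count"] > 0).any():
        raise ValueError("at least one count must be positive")
    return table


def _sorted_counts(table: pd.DataFrame) -> np.ndarray:
    # descending count, name ascending on ties, zero-count names dropped
    t = _validate(table)
    t = t[t["count"] > 0].sort_values(
        ["count", "name"], ascending=[False, True], kind="mergesort"
    )
    return t["count"].to_numpy(dtype=float)


def coverage_curve(table: pd.DataFrame) -> np.ndarray:
    """Cumulative population fraction covered by the top-i names, i = 1..N.

    Nondecreasing, ending at 1 (within floating tolerance).
    """
    counts = _sorted_counts(table)
    return np.cumsum(counts) / counts.sum()


def coverage_count(table: pd.DataFrame, fraction: float) -> int:
    """Minimum number of top-frequency names covering >= ``fraction``.

    E.g. with counts {a: 50, b: 30, c: 20} and fraction 0.7, two names
    suffice (50 + 30 = 80% >= 70%; 50% alone does not).
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    curve = coverage_curve(table)
    # tiny epsilon so 0.7 on an exactly-70% prefix is not missed to rounding
    return int(np.searchsorted(curve, fraction - 1e-12) + 1)


def curve_to_sample(curve: Sequence[float], n: int = 10_000) -> np.ndarray:
    """Discretize a coverage curve into a numeric sample for K-S testing.

    Each rank i (1-based) is repeated in proportion to its coverage
    increment c_i - c_{i-1}, yielding ~``n`` draws of the rank of the
    name covering a random individual.  Two curves discretized this way
    are comparable with :func:`ks_two_sample`.
    """
    c = np.asarray(curve, dtype=float)
    if c.ndim != 1 or len(c) == 0:
        raise ValueError("curve must be a nonempty 1-D sequence")
    increments = np.diff(np.concatenate([[0.0], c]))
    reps = np.round(increments / c[-1] * n).astype(int)
    ranks = np.arange(1, len(c) + 1)
    return np.repeat(ranks, reps)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns ``(D, p)`` where D is the supremum absolute difference of
    the two empirical CDFs and p comes from the asymptotic K-S
    distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    result = stats.ks_2samp(x, y, method="asymp")
    return float(result.statistic), float(result.pvalue)
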