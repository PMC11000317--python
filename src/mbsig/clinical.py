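"""Baseline-characteristics statistics: Fisher exact tests for categorical
covariates and Mann-Whitney U for continuous ones, and the formatted
baseline table (N, overall, per-group summaries, p-value per row).
"""

from __future__ import annotations

from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats

from .data import DataError

__all__ = [
    "ContingencyTable",
    "fisher_exact",
    "mann_whitney_u",
    "baseline_table",
]


@dataclass
class ContingencyTable:
    """r x c non-negative integer counts with optional axis labels."""

    counts: np.ndarray
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise DataError("contingency counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise DataError("contingency counts must be integers")
            self.counts = self.counts.astype(int)


def _fisher_rxc(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for an r x c table by enumeration of all
    tables with the observed margins (point-probability rule). Feasible only
    for small tables; used for the multi-level baseline rows."""
    from math import lgamma

    table = np.asarray(table, dtype=int)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = table.sum()

    def lfact(k):
        return lgamma(k + 1)

    log_const = (
        sum(lfact(r) for r in rows) + sum(lfact(c) for c in cols) - lfact(n)
    )

    def log_prob(t):
        return log_const - sum(lfact(v) for v in t.flat)

    obs = log_prob(table)
    total = 0.0
    r, c = table.shape

    def recurse(i, remaining_cols, t):
        nonlocal total
        if i == r - 1:
            t[-1] = remaining_cols
            if np.all(t[-1] >= 0):
                lp = log_prob(t)
                if lp <= obs + 1e-7:
                    total += np.exp(lp)
            return
        # enumerate row i cell by cell
        def fill(j, left_in_row, rem):
            if j == c - 1:
                if 0 <= left_in_row <= rem[j]:
                    t[i, j] = left_in_row
                    new_rem = rem.copy()
                    new_rem[j] -= left_in_row
                    recurse(i + 1, new_rem, t)
                return
            for v in range(min(left_in_row, rem[j]) + 1):
                t[i, j] = v
                new_rem = rem.copy()
                new_rem[j] -= v
                fill(j + 1, left_in_row - v, new_rem)

        fill(0, rows[i], remaining_cols)

    recurse(0, cols.astype(int).copy(), np.zeros_like(table))
    return float(min(1.0, total))


def fisher_exact(table, exact_rxc: bool = False) -> float:
    """Two-sided Fisher exact p-value.

    2x2 tables use the point-probability rule (sum of hypergeometric
    probabilities of all margin-fixed tables no more likely than the
    observed, with a 1e-7 relative tolerance). Larger tables require
    ``exact_rxc=True`` and are enumerated directly.
    """
    if isinstance(table, ContingencyTable):
        table = table.counts
    table = np.asarray(table)
    if np.any(table < 0):
        raise DataError("contingency counts must be non-negative")
    if table.shape == (2, 2):
        return float(stats.fisher_exact(table, alternative="two-sided")[1])
    if not exact_rxc:
        raise DataError(
            f"table shape {table.shape} needs exact_rxc=True (2x2 otherwise)"
        )
    return _fisher_rxc(table)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Mann-Whitney U statistic and two-sided p-value.

    Exact enumeration when n_x * n_y <= 400 and the pooled sample is
    tie-free; midranks with the tie-corrected normal approximation
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DataError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and x.size * y.size <= 400) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def _is_categorical(series: pd.Series) -> bool:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return True
    return series.dtype == object or series.dtype == bool


def baseline_table(samples) -> pd.DataFrame:
    """Per-covariate baseline table with group comparisons.

    Continuous covariates: mean (SD) per group and a Mann-Whitney p-value.
    Categorical covariates: n (%) per level and group, and a Fisher exact
    p-value (point-probability 2x2; exact r x c enumeration for more
    levels). Missing values reduce that row's N and are reported. A
    covariate with a single observed level is summarized without a test.
    """
    if samples.group is None:
        raise DataError("group labels required for the baseline table")
    if samples.covariates is None or samples.covariates.empty:
        raise DataError("no covariates present")
    g = samples.group
    levels = sorted(g.unique())
    rows = []
    for name, col in samples.covariates.items():
        mask = col.notna()
        n = int(mask.sum())
        cg = g[mask]
        cv = col[mask]
        if _is_categorical(cv):
            cats = sorted(map(str, cv.unique()))
            counts = np.array(
                [[int(((cv.astype(str) == cat) & (cg == lv)).sum()) for lv in levels]
                 for cat in cats]
            )
            if len(cats) < 2:
                p, note = np.nan, "single level; test skipped"
            else:
                p = fisher_exact(counts.T if counts.shape[0] == 2 else counts,
                                 exact_rxc=counts.shape[0] > 2)
                note = ""
            overall = ", ".join(
                f"{cat}: {int((cv.astype(str) == cat).sum())} "
                f"({100 * (cv.astype(str) == cat).mean():.0f}%)"
                for cat in cats
            )
            per_group = {
                lv: ", ".join(
                    f"{cat}: {int(((cv.astype(str) == cat) & (cg == lv)).sum())} "
                    f"({100 * ((cv[cg == lv].astype(str) == cat).mean() if (cg == lv).any() else 0):.0f}%)"
                    for cat in cats
                )
                for lv in levels
            }
        else:
            vals = cv.astype(float)
            if vals.nunique() < 2:
                p, note = np.nan, "single value; test skipped"
            else:
                _, p = mann_whitney_u(
                    vals[cg == levels[0]], vals[cg == levels[1]]
                )
                note = ""
            overall = f"{vals.mean():.1f} ({vals.std(ddof=1):.1f})"
            per_group = {
                lv: f"{vals[cg == lv].mean():.1f} ({vals[cg == lv].std(ddof=1):.1f})"
                for lv in levels
            }
        row = {"covariate": name, "N": n, "overall": overall}
        for lv in levels:
            row[str(lv)] = per_group[lv]
        row["p_value"] = p
        row["note"] = note
        rows.append(row)
    return pd.DataFrame(rows)
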