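"""Baseline-characteristics tables, group comparisons and the exclusion flowchart.

The group comparison for every categorical row is a Pearson chi-square on
the complete-case contingency table. For 2x2 tables a capped continuity
correction is applied: the per-cell correction term is min(0.5, |O - E|),
so the statistic is never over-corrected below zero — two groups with
near-identical proportions give a statistic of exactly 0 and p = 1.
Tables with more than one degree of freedom are uncorrected.

Percentages in the descriptive table are computed over the printed group
totals (half-up rounding to one decimal), while the tests use complete-case
counts; the hormone-replacement row is tested among women only.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import cohort as ch
from .cohort import ExclusionResult


def chi_square_test(observed) -> tuple[float, int, float]:
    """Pearson chi-square with the capped continuity correction on 2x2.

    ``observed`` is an r x c array of non-negative counts (r, c >= 2).
    Returns (statistic, df, two-sided p). Raises on a zero row or column
    margin, where expected counts vanish.
    """
    O = np.asarray(observed, dtype=float)
    if O.ndim != 2 or O.shape[0] < 2 or O.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(O < 0):
        raise ValueError("negative counts")
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: expected counts are undefined")
    E = rows * cols / O.sum()
    d = np.abs(O - E)
    if O.shape == (2, 2):
        stat = float((((d - np.minimum(0.5, d)) ** 2) / E).sum())
    else:
        stat = float(((d ** 2) / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def pearson_chi_square(observed) -> tuple[float, int, float]:
    """Plain (uncorrected) Pearson chi-square, any table size."""
    O = np.asarray(observed, dtype=float)
    rows = O.sum(axis=1, keepdims=True)
    cols = O.sum(axis=0, keepdims=True)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero margin: expected counts are undefined")
    E = rows * cols / O.sum()
    stat = float((((O - E) ** 2) / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


def format_percent(count: int, denom: int) -> str:
    """One-decimal half-up percentage string, e.g. '76.7%'."""
    pct = decimal.Decimal(100 * count) / decimal.Decimal(denom)
    return f"{pct.quantize(decimal.Decimal('0.1'), rounding=decimal.ROUND_HALF_UP)}%"


@dataclass
class DescriptiveRow:
    variable: str
    level: str
    cells: dict[str, str]  # group -> "N (p%)"
    p_value: float | None = None


#: Default descriptive variables; ``female_only`` rows are tested among women.
TABLE1_VARIABLES: tuple[tuple[str, bool], ...] = (
    ("sex", False), ("education", False), ("bmi", False), ("smoking", False),
    ("prs_tertile", False), ("alcohol", False), ("physical_activity", False),
    ("red_meat", False), ("processed_meat", False), ("hrt", True),
    ("diabetes", False), ("family_history_crc", False), ("nsaids", False),
    ("history_colonoscopy", False), ("whole_grain", False), ("fruit", False),
    ("vegetable", False), ("poultry", False),
)


def _levels(s: pd.Series) -> list:
    if isinstance(s.dtype, pd.CategoricalDtype):
        return [lv for lv in s.cat.categories if s.eq(lv).any()]
    return sorted(s.dropna().unique())


def build_table1(data: pd.DataFrame, variables=TABLE1_VARIABLES) -> list[DescriptiveRow]:
    """Baseline characteristics by outcome group with chi-square p-values.

    Groups are no-finding, any-neoplasm and (as a sub-column) advanced
    neoplasm; the test compares no-finding against any-neoplasm on
    complete-case counts. Counts and percentages use the full group totals
    as denominators, matching the printed-table convention.
    """
    groups = {
        "no_finding": data["outcome_class"].eq(ch.NO_FINDING),
        "any_neoplasm": data["outcome_class"].isin(ch.ANY_NEOPLASM),
        "advanced_neoplasm": data["outcome_class"].isin(ch.ADVANCED_NEOPLASM),
    }
    totals = {g: int(m.sum()) for g, m in groups.items()}
    rows = [DescriptiveRow("Total", "", {g: str(t) for g, t in totals.items()})]
    for var, female_only in variables:
        if var not in data.columns:
            continue
        s = data[var]
        levels = _levels(s)
        female = data["sex"].astype(str).eq("Female")
        counts = {}
        for g, gmask in groups.items():
            sel = gmask & female if female_only else gmask
            counts[g] = [int((data.loc[sel, var].astype(object) == lv).sum())
                         for lv in levels]
        table = np.array([counts["no_finding"], counts["any_neoplasm"]]).T
        try:
            _, _, p = chi_square_test(table)
        except ValueError:
            p = None
        display_counts = {
            g: [int((data.loc[groups[g], var].astype(object) == lv).sum())
                for lv in levels] for g in groups
        }
        for i, lv in enumerate(levels):
            cells = {
                g: f"{display_counts[g][i]} "
                   f"({format_percent(display_counts[g][i], totals[g])})"
                for g in groups
            }
            rows.append(DescriptiveRow(var, str(lv), cells,
                                       p if i == 0 else None))
    return rows


def table1_frame(rows: list[DescriptiveRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.variable, r.level, r.cells.get("no_finding", ""),
          r.cells.get("any_neoplasm", ""), r.cells.get("advanced_neoplasm", ""),
          "" if r.p_value is None else f"{r.p_value:.4f}")
         for r in rows],
        columns=["variable", "level", "no_finding", "any_neoplasm",
                 "advanced_neoplasm", "p_value"],
    )


def flowchart_report(result: ExclusionResult) -> str:
    """Ordered rule -> count listing of the exclusion flow, totals reconciled."""
    lines = [f"Participants assessed: {result.n_input}"]
    if any(result.tallies.values()):
        lines.append("Excluded (first matching rule):")
        for rule, n in result.tallies.items():
            if n:
                lines.append(f"  {rule}: {n}")
    total_excl = sum(result.tallies.values())
    assert result.n_kept + total_excl == result.n_input
    lines.append(f"Included in analysis: {result.n_kept}")
    return "\n".join(lines)
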