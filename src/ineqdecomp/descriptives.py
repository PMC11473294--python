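"""Frequency tables and Pearson chi-squared comparisons.

Cross-tabulations are computed per table on that table's own non-missing
denominator (item missingness differs by variable, so denominators differ
across tables).  Tests are plain Pearson chi-squared without continuity
correction, including for 2x2 tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DataError, DegenerateTableError

#: forgone-care indicators are only collected in a subset of waves
WAVE_SUBSETS = {
    "forgone_outpatient": ["2011", "2013", "2015"],
    "forgone_hospitalization": ["2011", "2013", "2015"],
}


@dataclass(frozen=True)
class ContingencyTable:
    """A labelled count matrix with column-wise percentages."""

    row_variable: str
    col_variable: str
    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise DataError("counts must be a 2-d matrix")
        if (c < 0).any():
            raise DataError("counts must be non-negative")

    @property
    def margin_percentages(self) -> np.ndarray:
        """Column-wise percentages on each column's own total."""
        totals = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / totals

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)

    def formatted(self, digits: int = 1) -> pd.DataFrame:
        """'n (%)' cells as printed in descriptive tables."""
        pct = self.margin_percentages
        cells = [
            [f"{self.counts[i, j]} ({pct[i, j]:.{digits}f})"
             for j in range(self.counts.shape[1])]
            for i in range(self.counts.shape[0])
        ]
        return pd.DataFrame(cells, index=self.row_labels, columns=self.col_labels)


@dataclass(frozen=True)
class ChiSquaredResult:
    statistic: float
    df: int
    p_value: float

    def stars(self) -> str:
        for cut, mark in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p_value < cut:
                return mark
        return ""


def crosstab(
    records: pd.DataFrame,
    row_variable: str,
    col_variable: str,
    row_order: list | None = None,
    col_order: list | None = None,
) -> ContingencyTable:
    """Cross-tabulate two categorical variables, dropping missing pairs.

    Unobserved levels yield no row/column (and therefore do not inflate the
    degrees of freedom of a subsequent test).
    """
    for v in (row_variable, col_variable):
        if v not in records.columns:
            raise DataError(f"unknown variable {v!r}")
    tab = pd.crosstab(records[row_variable], records[col_variable], dropna=True)
    if row_order is not None:
        tab = tab.reindex(index=[r for r in row_order if r in tab.index])
    if col_order is not None:
        tab = tab.reindex(columns=[c for c in col_order if c in tab.columns])
    # drop structurally empty rows/columns
    tab = tab.loc[tab.sum(axis=1) > 0, tab.sum(axis=0) > 0]
    return ContingencyTable(
        row_variable=row_variable,
        col_variable=col_variable,
        row_labels=list(tab.index),
        col_labels=list(tab.columns),
        counts=tab.to_numpy(dtype=np.int64),
    )


def chi_squared(table: ContingencyTable) -> ChiSquaredResult:
    """Pearson chi-squared test of independence, no continuity correction."""
    counts = np.asarray(table.counts, dtype=float)
    keep_r = counts.sum(axis=1) > 0
    keep_c = counts.sum(axis=0) > 0
    counts = counts[np.ix_(keep_r, keep_c)]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise DegenerateTableError(
            f"{table.row_variable} x {table.col_variable}: need at least two "
            "non-empty rows and columns")
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return ChiSquaredResult(statistic=float(stat), df=int(df), p_value=float(p))


def _outcome_block(records, outcome, group, group_order):
    sub = records
    if group == "wave" and outcome in WAVE_SUBSETS:
        sub = records[records["wave"].isin(WAVE_SUBSETS[outcome])]
    sub = sub[sub[outcome].notna() & sub[group].notna()].copy()
    if sub.empty:
        return None
    sub["_level"] = np.where(sub[outcome].astype(float) == 1, "yes", "no")
    table = crosstab(sub, "_level", group,
                     row_order=["yes", "no"], col_order=group_order)
    table = ContingencyTable(outcome, group, table.row_labels,
                             table.col_labels, table.counts)
    return table


def utilization_table(
    records: pd.DataFrame,
    outcomes: list[str] | None = None,
    groups: tuple[str, ...] = ("wave", "disability_type"),
) -> dict[str, dict[str, tuple[ContingencyTable, ChiSquaredResult]]]:
    """Yes/no utilization counts and chi-squared tests by wave and type.

    Returns ``{outcome: {group: (table, test)}}``; an outcome entirely
    missing (or absent) is omitted with a warning.
    """
    if outcomes is None:
        outcomes = [c for c in ("outpatient", "inpatient", "self_treatment",
                                "forgone_outpatient", "forgone_hospitalization")
                    if c in records.columns]
    order = {
        "wave": sorted(records["wave"].dropna().unique().astype(str))
        if "wave" in records else None,
        "disability_type": ["physical", "intellectual", "vision", "hearing",
                            "speech", "multiple"],
    }
    out: dict = {}
    for outcome in outcomes:
        if outcome not in records.columns or records[outcome].notna().sum() == 0:
            warnings.warn(f"outcome {outcome!r} has no observed values; block omitted",
                          stacklevel=2)
            continue
        blocks = {}
        for g in groups:
            if g not in records.columns:
                continue
            table = _outcome_block(records, outcome, g, order.get(g))
            if table is None:
                continue
            try:
                test = chi_squared(table)
            except DegenerateTableError:
                test = None
            blocks[g] = (table, test)
        if blocks:
            out[outcome] = blocks
    return out


def utilization_frame(tables: dict) -> pd.DataFrame:
    """Flatten :func:`utilization_table` output to one long tidy frame."""
    rows = []
    for outcome, blocks in tables.items():
        for group, (table, test) in blocks.items():
            pct = table.margin_percentages
            for i, lev in enumerate(table.row_labels):
                for j, g in enumerate(table.col_labels):
                    rows.append({
                        "outcome": outcome, "group_variable": group,
                        "group": g, "level": lev,
                        "count": int(table.counts[i, j]),
                        "percent": round(float(pct[i, j]), 1),
                        "chi2": round(test.statistic, 3) if test else np.nan,
                        "df": test.df if test else np.nan,
                        "p_value": test.p_value if test else np.nan,
                    })
    return pd.DataFrame(rows)


def characteristics_tables(
    records: pd.DataFrame,
    variables: list[str],
    group: str = "wave",
) -> dict[str, tuple[ContingencyTable, ChiSquaredResult | None]]:
    """Variable-by-group frequency tables with chi-squared tests."""
    out = {}
    for v in variables:
        if v not in records.columns:
            continue
        sub = records[records[v].notna() & records[group].notna()]
        if sub.empty:
            continue
        table = crosstab(sub, v, group)
        try:
            test = chi_squared(table)
        except DegenerateTableError:
            test = None
        out[v] = (table, test)
    return out
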