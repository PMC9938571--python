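"""Baseline descriptive statistics and cohort inclusion filtering.

Covariate-by-group contingency tables with chi-square tests (Yates
continuity correction for 2x2 tables, plain Pearson otherwise — the
convention used for survey descriptive tables), column percentages, and the
ordered application of cohort inclusion criteria with an attrition log.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "ContingencyTable",
    "chi_square_test",
    "cohort_characteristics_table",
    "apply_inclusion_criteria",
    "InclusionCriterion",
]


@dataclass(frozen=True)
class ContingencyTable:
    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] < 2 or c.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(c < 0) or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        object.__setattr__(self, "counts", c.astype(np.int64))
        if not self.row_labels:
            object.__setattr__(
                self, "row_labels", tuple(f"r{i}" for i in range(c.shape[0]))
            )
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"c{j}" for j in range(c.shape[1]))
            )


def chi_square_test(table: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square of independence: (statistic, df, p).

    2x2 tables get the Yates continuity correction (each |O - E| reduced by
    0.5, clamped at zero); larger tables are uncorrected.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else np.asarray(table)
    if counts.ndim != 2 or min(counts.shape) < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("zero row or column margin: expected counts undefined")
    correction = counts.shape == (2, 2)
    res = chi2_contingency(counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def cohort_characteristics_table(
    panel_dataset: pd.DataFrame,
    group_variable: str,
    covariates: Sequence[str],
    *,
    id_col: str = "id",
    baseline_only: bool = True,
) -> pd.DataFrame:
    """Table-1-style descriptives: counts, column percentages and a
    chi-square test per categorical covariate, by a binary group variable.

    Percentages are column percentages within group, reported to one
    decimal in the formatted columns; the raw counts stay in the table.
    Single-level covariates are flagged rather than tested.
    """
    df = panel_dataset
    if group_variable not in df.columns:
        raise KeyError(f"missing group column {group_variable!r}")
    if baseline_only and "wave_index" in df.columns:
        df = df[df["wave_index"] == 0]
    if id_col in df.columns:
        df = df.drop_duplicates(subset=id_col)
    groups = sorted(df[group_variable].unique())
    if len(groups) != 2:
        raise ValueError(
            f"group variable {group_variable!r} must be binary, got {groups}"
        )
    rows = []
    for cov in covariates:
        if cov not in df.columns:
            raise KeyError(f"missing covariate column {cov!r}")
        ct = pd.crosstab(df[cov], df[group_variable])
        ct = ct.reindex(columns=groups, fill_value=0)
        levels = list(ct.index)
        if len(levels) < 2:
            rows.append(
                {
                    "covariate": cov,
                    "level": str(levels[0]) if levels else "",
                    **{f"n_{g}": int(ct[g].iloc[0]) if levels else 0 for g in groups},
                    **{f"pct_{g}": 100.0 for g in groups},
                    "chi2": np.nan,
                    "df": 0,
                    "p": np.nan,
                    "note": "single level; no test",
                }
            )
            continue
        stat, dof, p = chi_square_test(ct.to_numpy())
        totals = ct.sum(axis=0)
        for i, lev in enumerate(levels):
            rows.append(
                {
                    "covariate": cov,
                    "level": str(lev),
                    **{f"n_{g}": int(ct.loc[lev, g]) for g in groups},
                    **{
                        f"pct_{g}": round(100.0 * ct.loc[lev, g] / totals[g], 1)
                        for g in groups
                    },
                    "chi2": round(stat, 3) if i == 0 else np.nan,
                    "df": dof if i == 0 else np.nan,
                    "p": p if i == 0 else np.nan,
                    "note": "",
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class InclusionCriterion:
    """One filtering step: keep rows where ``column`` equals ``keep_value``."""

    name: str
    column: str
    keep_value: object = True


def apply_inclusion_criteria(
    raw_panel: pd.DataFrame,
    criteria: Sequence[InclusionCriterion],
    *,
    id_col: str = "id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply inclusion criteria in order; return (filtered panel, attrition log).

    The attrition log has one row per criterion with the participant count
    before, excluded, and remaining after the step.
    """
    df = raw_panel
    log_rows = []
    for crit in criteria:
        if crit.column not in df.columns:
            raise KeyError(f"criterion {crit.name!r}: missing flag column {crit.column!r}")
        n_before = df[id_col].nunique() if id_col in df.columns else len(df)
        kept = df[df[crit.column] == crit.keep_value]
        n_after = kept[id_col].nunique() if id_col in kept.columns else len(kept)
        log_rows.append(
            {
                "criterion": crit.name,
                "n_before": n_before,
                "n_excluded": n_before - n_after,
                "n_after": n_after,
            }
        )
        df = kept
    return df.copy(), pd.DataFrame(log_rows)
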