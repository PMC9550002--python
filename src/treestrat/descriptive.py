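"""Characteristics-table reporting: level counts, percentages, chi-square tests.

Reproduces the study's descriptive table: for every variable, per-level totals
with percentage of the cohort, counts split by outcome, and a Pearson
chi-square test of association with the outcome (Yates continuity correction
on 2x2 tables, none for K > 2 — the convention that reproduces the printed
sex-row p-value of 0.002 from its counts).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortError, EstimationError
from .schema import CohortTable


def characteristics_row(cohort: CohortTable, var: str) -> pd.DataFrame:
    """Per-level summary for one variable: total, percent, counts by outcome."""
    if var not in cohort.specs:
        raise CohortError(f"unknown variable {var!r}")
    spec = cohort.specs[var]
    col = cohort.data[var].astype(str).to_numpy()
    y = cohort.outcome
    n = cohort.n_subjects
    rows = []
    for level in spec.ordered_display_levels:
        mask = col == level
        total = int(mask.sum())
        events = int(y[mask].sum())
        rows.append(
            {
                "variable": var,
                "level": level,
                "total": total,
                "percent": 100.0 * total / n,
                "non_outcome": total - events,
                "outcome": events,
            }
        )
    out = pd.DataFrame(rows)
    assert out["total"].sum() == n, "level counts must partition the cohort"
    return out


def contingency_from_cohort(cohort: CohortTable, var: str) -> np.ndarray:
    """K x 2 array of (non-outcome, outcome) counts for one variable."""
    rows = characteristics_row(cohort, var)
    return rows[["non_outcome", "outcome"]].to_numpy(dtype=float)


def pearson_chi2(table: np.ndarray, correction: bool | None = None) -> dict:
    """Pearson chi-square test on a K x 2 contingency table.

    ``correction=None`` applies the Yates continuity correction exactly when
    the table is 2x2. Zero expected counts are refused: merge sparse levels.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[1] != 2 or table.shape[0] < 2:
        raise EstimationError("expected a K x 2 contingency table with K >= 2")
    if (table < 0).any() or table.sum() == 0:
        raise EstimationError("contingency counts must be non-negative with a positive total")
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise EstimationError(
            "zero expected count; merge sparse levels before testing"
        )
    if correction is None:
        correction = table.shape == (2, 2)
    stat, p, df, _ = stats.chi2_contingency(table, correction=correction)
    return {"statistic": float(stat), "df": int(df), "p_value": float(p)}


def characteristics_table(cohort: CohortTable, variables: list[str] | None = None) -> pd.DataFrame:
    """Full descriptive table with one chi-square p-value per variable."""
    if variables is None:
        variables = [v for v in cohort.specs if v != cohort.outcome_name]
    pieces = []
    for var in variables:
        rows = characteristics_row(cohort, var)
        table = rows[["non_outcome", "outcome"]].to_numpy(dtype=float)
        try:
            p = pearson_chi2(table)["p_value"]
        except EstimationError:
            p = np.nan
        rows["p_value"] = p
        pieces.append(rows)
    return pd.concat(pieces, ignore_index=True)


def _sigfig(x: float, digits: int = 3) -> str:
    return f"{x:.{digits}g}"


def write_characteristics(table: pd.DataFrame, path) -> None:
    """Write the descriptive table; percentages to 3 significant figures."""
    out = table.copy()
    out["percent"] = [_sigfig(v) for v in out["percent"]]
    out.to_csv(path, sep="\t", index=False)
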