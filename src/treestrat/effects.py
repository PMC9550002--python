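"""Crude and Mantel-Haenszel stratum-adjusted effect estimation.

The second stage of the two-stage analysis: each putative risk factor is
summarized as a 2x2 outcome-by-exposure table, either marginally (crude) or
within each stratum defined by the confounder tree, and a common effect across
strata is pooled with the Mantel-Haenszel estimator.

Both effect measures are provided. The odds ratio (cross-product ratio) is the
default for the adjusted effect table; the risk ratio is the measure used for
pairwise tree-node comparisons. Confidence intervals: Woolf (crude OR), Katz
log (risk ratio), Robins-Breslow-Greenland (MH OR) and Greenland-Robins
(MH RR), all at 95% with z = 1.959964.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CohortError, EstimationError

Z95 = 1.959964


@dataclass(frozen=True)
class TwoByTwo:
    """Outcome-by-exposure counts: a,b exposed with/without outcome; c,d unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise EstimationError("2x2 counts must be non-negative")
        if self.n == 0:
            raise EstimationError("2x2 table is empty")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    def continuity_corrected(self, increment: float = 0.5) -> tuple[float, float, float, float]:
        return (self.a + increment, self.b + increment, self.c + increment, self.d + increment)

    def __add__(self, other: "TwoByTwo") -> "TwoByTwo":
        return TwoByTwo(self.a + other.a, self.b + other.b, self.c + other.c, self.d + other.d)


@dataclass
class StratumSeries:
    """Per-stratum 2x2 tables for one exposure contrast."""

    exposure: str
    exposed_level: str
    reference_level: str
    tables: list[tuple[str, TwoByTwo]]

    def pooled(self) -> TwoByTwo:
        a = sum(t.a for _, t in self.tables)
        b = sum(t.b for _, t in self.tables)
        c = sum(t.c for _, t in self.tables)
        d = sum(t.d for _, t in self.tables)
        return TwoByTwo(a, b, c, d)


@dataclass
class EffectEstimate:
    """A point estimate with its 95% CI and provenance tags."""

    exposure: str
    exposed_level: str
    point: float
    ci_low: float
    ci_high: float
    measure: str  # "odds-ratio" | "risk-ratio"
    method: str  # "crude" | "MH" | "LR"
    model: str | None = None  # stratification model id for MH / adjustment set for LR
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.point > 0):
            raise EstimationError(f"{self.exposure}: non-positive effect estimate")
        if not (self.ci_low <= self.point <= self.ci_high):
            raise EstimationError(f"{self.exposure}: CI does not bracket the point estimate")


def marginal_table(cohort, exposure: str, exposed_level: str, reference_level: str | None = None) -> TwoByTwo:
    """Collapse the cohort to the 2x2 table of one exposure contrast.

    Subjects at other levels of a multi-level exposure are excluded so the
    contrast is pairwise against the reference.
    """
    spec = cohort.specs[exposure]
    if reference_level is None:
        reference_level = spec.reference
    if exposed_level == reference_level:
        raise CohortError(f"{exposure}: exposed level equals reference level")
    col = cohort.data[exposure].astype(str).to_numpy()
    y = cohort.outcome
    exp_mask = col == exposed_level
    ref_mask = col == reference_level
    if exp_mask.sum() == 0 or ref_mask.sum() == 0:
        raise CohortError(f"{exposure}: empty level in contrast {exposed_level} vs {reference_level}")
    return TwoByTwo(
        a=int(y[exp_mask].sum()),
        b=int((~y.astype(bool))[exp_mask].sum()),
        c=int(y[ref_mask].sum()),
        d=int((~y.astype(bool))[ref_mask].sum()),
    )


def crude_or(t: TwoByTwo, exposure: str = "", exposed_level: str = "") -> EffectEstimate:
    """Cross-product (odds) ratio with Woolf log CI; Haldane-Anscombe 0.5
    increment to every cell when any cell is zero (flagged)."""
    flags = []
    if t.has_zero_cell():
        a, b, c, d = t.continuity_corrected()
        flags.append("zero-cell-continuity")
    else:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return EffectEstimate(
        exposure=exposure,
        exposed_level=exposed_level,
        point=point,
        ci_low=point * math.exp(-Z95 * se),
        ci_high=point * math.exp(Z95 * se),
        measure="odds-ratio",
        method="crude",
        flags=flags,
    )


def crude_rr(t: TwoByTwo, exposure: str = "", exposed_level: str = "") -> EffectEstimate:
    """Risk (incidence) ratio with Katz log CI.

    Zero events in either arm trigger the 0.5 continuity increment to all four
    cells (flagged), mirroring the odds-ratio rule.
    """
    flags = []
    if t.a == 0 or t.c == 0:
        a, b, c, d = t.continuity_corrected()
        flags.append("zero-cell-continuity")
    else:
        a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n1, n0 = a + b, c + d
    point = (a / n1) / (c / n0)
    se = math.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    return EffectEstimate(
        exposure=exposure,
        exposed_level=exposed_level,
        point=point,
        ci_low=point * math.exp(-Z95 * se),
        ci_high=point * math.exp(Z95 * se),
        measure="risk-ratio",
        method="crude",
        flags=flags,
    )


def _informative(t: TwoByTwo) -> bool:
    return t.a * t.d != 0 or t.b * t.c != 0


def mh_common_or(series: StratumSeries, model: str | None = None) -> EffectEstimate:
    """Mantel-Haenszel common odds ratio across strata.

    Point estimate sum(a_i d_i / n_i) / sum(b_i c_i / n_i); variance of the log
    estimate by Robins-Breslow-Greenland. Strata with a_i d_i = b_i c_i = 0
    contribute nothing.
    """
    tables = [t for _, t in series.tables if _informative(t)]
    if not tables:
        raise EstimationError(f"{series.exposure}: all strata uninformative for the MH odds ratio")
    R = sum(t.a * t.d / t.n for t in tables)
    S = sum(t.b * t.c / t.n for t in tables)
    if R == 0 or S == 0:
        # all discordant pairs on one side; fall back to pooled continuity handling
        pooled = series.pooled()
        est = crude_or(pooled, series.exposure, series.exposed_level)
        est.method = "MH"
        est.model = model
        est.flags.append("one-sided-strata-pooled")
        return est
    point = R / S
    sum_PR = sum((t.a + t.d) / t.n * (t.a * t.d / t.n) for t in tables)
    sum_PSQR = sum(
        (t.a + t.d) / t.n * (t.b * t.c / t.n) + (t.b + t.c) / t.n * (t.a * t.d / t.n)
        for t in tables
    )
    sum_QS = sum((t.b + t.c) / t.n * (t.b * t.c / t.n) for t in tables)
    var = sum_PR / (2 * R * R) + sum_PSQR / (2 * R * S) + sum_QS / (2 * S * S)
    se = math.sqrt(var)
    return EffectEstimate(
        exposure=series.exposure,
        exposed_level=series.exposed_level,
        point=point,
        ci_low=point * math.exp(-Z95 * se),
        ci_high=point * math.exp(Z95 * se),
        measure="odds-ratio",
        method="MH",
        model=model,
    )


def mh_common_rr(series: StratumSeries, model: str | None = None) -> EffectEstimate:
    """Mantel-Haenszel common risk ratio with the Greenland-Robins variance."""
    tables = [t for _, t in series.tables if t.n_exposed > 0 and t.n_unexposed > 0]
    if not tables:
        raise EstimationError(f"{series.exposure}: all strata uninformative for the MH risk ratio")
    R = sum(t.a * t.n_unexposed / t.n for t in tables)
    S = sum(t.c * t.n_exposed / t.n for t in tables)
    if R == 0 or S == 0:
        pooled = series.pooled()
        est = crude_rr(pooled, series.exposure, series.exposed_level)
        est.method = "MH"
        est.model = model
        est.flags.append("one-sided-strata-pooled")
        return est
    point = R / S
    num = sum(
        (t.n_exposed * t.n_unexposed * (t.a + t.c) - t.a * t.c * t.n) / (t.n * t.n)
        for t in tables
    )
    var = num / (R * S)
    se = math.sqrt(max(var, 0.0))
    return EffectEstimate(
        exposure=series.exposure,
        exposed_level=series.exposed_level,
        point=point,
        ci_low=point * math.exp(-Z95 * se),
        ci_high=point * math.exp(Z95 * se),
        measure="risk-ratio",
        method="MH",
        model=model,
    )


def stratum_series(cohort, exposure: str, exposed_level: str, strata: np.ndarray,
                   reference_level: str | None = None) -> StratumSeries:
    """Split one exposure contrast into per-stratum 2x2 tables.

    Strata in which the contrast is empty on either side are dropped (they
    carry no information about the common effect).
    """
    spec = cohort.specs[exposure]
    if reference_level is None:
        reference_level = spec.reference
    col = cohort.data[exposure].astype(str).to_numpy()
    y = cohort.outcome
    tables: list[tuple[str, TwoByTwo]] = []
    for label in pd.unique(strata):
        m = strata == label
        exp_mask = m & (col == exposed_level)
        ref_mask = m & (col == reference_level)
        if exp_mask.sum() == 0 or ref_mask.sum() == 0:
            continue
        tables.append(
            (
                str(label),
                TwoByTwo(
                    a=int(y[exp_mask].sum()),
                    b=int(exp_mask.sum() - y[exp_mask].sum()),
                    c=int(y[ref_mask].sum()),
                    d=int(ref_mask.sum() - y[ref_mask].sum()),
                ),
            )
        )
    if not tables:
        raise EstimationError(f"{exposure}: no stratum holds both contrast levels")
    return StratumSeries(exposure, exposed_level, reference_level, tables)


def effect_table(
    cohort,
    exposures: list[str],
    strata_by_model: dict[str, np.ndarray],
    measure: str = "or",
    lr_estimates: dict[tuple[str, str], EffectEstimate] | None = None,
) -> list[EffectEstimate]:
    """Crude plus per-model MH estimates for every non-reference exposure level.

    Rows are ordered by the given exposure order, then by declared level order.
    """
    if measure not in ("or", "rr"):
        raise CohortError(f"measure must be 'or' or 'rr', got {measure!r}")
    crude_fn = crude_or if measure == "or" else crude_rr
    mh_fn = mh_common_or if measure == "or" else mh_common_rr
    rows: list[EffectEstimate] = []
    for name in exposures:
        spec = cohort.specs[name]
        for level in spec.ordered_display_levels:
            if level == spec.reference:
                continue
            t = marginal_table(cohort, name, level)
            rows.append(crude_fn(t, name, level))
            for model, strata in strata_by_model.items():
                series = stratum_series(cohort, name, level, strata)
                rows.append(mh_fn(series, model=model))
            if lr_estimates and (name, level) in lr_estimates:
                rows.append(lr_estimates[(name, level)])
    return rows


def effect_frame(rows: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy DataFrame view of a list of estimates."""
    return pd.DataFrame(
        {
            "exposure": [r.exposure for r in rows],
            "level": [r.exposed_level for r in rows],
            "measure": [r.measure for r in rows],
            "method": [r.method for r in rows],
            "model": [r.model for r in rows],
            "estimate": [r.point for r in rows],
            "ci_low": [r.ci_low for r in rows],
            "ci_high": [r.ci_high for r in rows],
            "flags": [";".join(r.flags) for r in rows],
        }
    )


def write_effect_table(rows: list[EffectEstimate], path) -> None:
    """Write a wide, characteristics-table-style file: one row per contrast,
    one estimate column per method/model, rounded to 2 decimals."""
    frame = effect_frame(rows)
    frame["column"] = [
        r.method if r.method != "MH" else f"MH:{r.model}" for r in rows
    ]
    frame["cell"] = [
        f"{r.point:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})" for r in rows
    ]
    wide = frame.pivot_table(
        index=["exposure", "level"], columns="column", values="cell",
        aggfunc="first", sort=False,
    )
    wide.to_csv(path, sep="\t")
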