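"""Cohort schema: variable specifications, loading, imputation, discretization.

A cohort is a delimited text file, one row per subject, with a binary sepsis
outcome, putative risk factors and potential confounders. Continuous variables
(age, BMI, laboratory values, surgery duration) are collapsed into the clinical
categories of the study design before any analysis; the interval boundaries and
which group a boundary value joins are declared per variable, not hard-coded.

Missing cells are imputed before discretization: arithmetic mean for continuous
columns, most frequent level for categorical columns (ties broken toward the
lexicographically smallest label so results are deterministic).
"""

from __future__ import annotations

import csv
import importlib.resources
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import CohortError, SchemaError

OUTCOME = "outcome"
PUTATIVE_RISK = "putative_risk"
CONFOUNDER = "confounder"

#: the seven comorbidity flags feeding the derived comorbidity count
COMORBIDITY_FLAGS = (
    "diabetes",
    "coronary_disease",
    "cerebrovascular_disease",
    "malignant_tumor",
    "hepatic_failure",
    "pneumonia",
    "acute_kidney_injury",
)


@dataclass(frozen=True)
class Cutpoint:
    """A discretization threshold.

    ``boundary`` says which interval the threshold value itself joins:
    ``"low"`` for a left-closed group (e.g. creatinine "<=116" / ">116"),
    ``"high"`` for a right-closed one (e.g. CAR "<0.278" / ">=0.278").
    """

    threshold: float
    boundary: str = "low"

    def __post_init__(self) -> None:
        if self.boundary not in ("low", "high"):
            raise SchemaError(f"cutpoint boundary must be 'low' or 'high', got {self.boundary!r}")


@dataclass(frozen=True)
class VariableSpec:
    """Metadata for one cohort variable."""

    name: str
    role: str
    vtype: str
    levels: tuple[str, ...]
    reference: str
    cutpoints: tuple[Cutpoint, ...] = ()
    group: str | None = None
    derived_from_comorbidities: bool = False
    display_order: tuple[str, ...] | None = None
    counts: dict[str, tuple[int, int]] | None = None  # published [non-event, event]
    min_value: float | None = 0.0

    def __post_init__(self) -> None:
        if self.role not in (OUTCOME, PUTATIVE_RISK, CONFOUNDER):
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.vtype not in ("continuous", "categorical"):
            raise SchemaError(f"{self.name}: unknown vtype {self.vtype!r}")
        if len(self.levels) < 2:
            raise SchemaError(f"{self.name}: needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise SchemaError(f"{self.name}: duplicate level labels")
        if self.reference not in self.levels:
            raise SchemaError(f"{self.name}: reference {self.reference!r} not in levels")
        if self.role == OUTCOME and set(self.levels) != {"0", "1"}:
            raise SchemaError(f"{self.name}: outcome levels must be {{'0','1'}}")
        if self.vtype == "continuous":
            thresholds = [c.threshold for c in self.cutpoints]
            if sorted(thresholds) != thresholds or len(set(thresholds)) != len(thresholds):
                raise SchemaError(f"{self.name}: cutpoints must be strictly increasing")
            if len(self.levels) != len(self.cutpoints) + 1:
                raise SchemaError(
                    f"{self.name}: {len(self.levels)} levels require "
                    f"{len(self.levels) - 1} cutpoints, got {len(self.cutpoints)}"
                )

    @property
    def ordered_display_levels(self) -> tuple[str, ...]:
        return self.display_order if self.display_order else self.levels

    def interval_label(self, value: float) -> str:
        """Map a numeric value to its interval level label."""
        if self.min_value is not None and value < self.min_value:
            raise CohortError(
                f"{self.name}: value {value} below domain minimum {self.min_value}"
            )
        idx = 0
        for cp in self.cutpoints:
            if value > cp.threshold or (value == cp.threshold and cp.boundary == "high"):
                idx += 1
            else:
                break
        return self.levels[idx]


def _parse_spec_entry(entry: dict) -> VariableSpec:
    cutpoints = tuple(
        Cutpoint(float(c["threshold"]), c.get("boundary", "low"))
        for c in entry.get("cutpoints", [])
    )
    counts = entry.get("counts")
    if counts is not None:
        counts = {str(k): (int(v[0]), int(v[1])) for k, v in counts.items()}
    return VariableSpec(
        name=entry["name"],
        role=entry["role"],
        vtype=entry["vtype"],
        levels=tuple(str(v) for v in entry["levels"]),
        reference=str(entry["reference"]),
        cutpoints=cutpoints,
        group=entry.get("group"),
        derived_from_comorbidities=bool(entry.get("derived_from_comorbidities", False)),
        display_order=(
            tuple(str(v) for v in entry["display_order"]) if "display_order" in entry else None
        ),
        counts=counts,
        min_value=entry.get("min_value", 0.0),
    )


def load_variable_specs(source) -> list[VariableSpec]:
    """Read variable specifications from a YAML path or file-like object."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
    specs = [_parse_spec_entry(e) for e in doc["variables"]]
    validate_specs(specs)
    return specs


def default_specs() -> list[VariableSpec]:
    """The packaged 34-variable specification of the study cohort."""
    text = importlib.resources.files("treestrat.data").joinpath("table1.yaml").read_text()
    return load_variable_specs(io.StringIO(text))


def validate_specs(specs: list[VariableSpec]) -> None:
    outcomes = [s for s in specs if s.role == OUTCOME]
    if len(outcomes) != 1:
        raise SchemaError(f"exactly one outcome variable required, found {len(outcomes)}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise SchemaError("duplicate variable names in specification")


def outcome_spec(specs: list[VariableSpec]) -> VariableSpec:
    return next(s for s in specs if s.role == OUTCOME)


def specs_by_role(specs: list[VariableSpec], role: str) -> list[VariableSpec]:
    return [s for s in specs if s.role == role]


@dataclass
class CohortTable:
    """A fully imputed, discretized cohort: categorical labels + binary outcome."""

    data: pd.DataFrame
    outcome_name: str
    specs: dict[str, VariableSpec] = field(repr=False)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def outcome(self) -> np.ndarray:
        return self.data[self.outcome_name].astype(int).to_numpy()

    @property
    def prevalence(self) -> float:
        return float(self.outcome.mean())

    def validate(self) -> None:
        if self.data.isna().any().any():
            raise CohortError("cohort contains missing values after imputation")
        for name, spec in self.specs.items():
            if name == self.outcome_name:
                continue
            bad = set(self.data[name].astype(str)) - set(spec.levels)
            if bad:
                raise CohortError(f"{name}: labels outside declared levels: {sorted(bad)}")

    def require_estimable(self) -> None:
        p = self.prevalence
        if not 0.0 < p < 1.0:
            raise CohortError(f"outcome prevalence {p} is degenerate; cannot estimate")

    def write(self, path) -> None:
        self.data.to_csv(path, index=False)


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def load_cohort(path, specs: list[VariableSpec]) -> pd.DataFrame:
    """Load a raw cohort table; missing cells become NaN, rows are never dropped.

    Continuous columns may hold either numbers (to be discretized later) or
    labels already matching the declared levels (e.g. a simulated cohort).
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df = df.replace({"": np.nan, "NA": np.nan, "nan": np.nan})

    missing_cols = [
        s.name
        for s in specs
        if s.name not in df.columns
        and not (s.derived_from_comorbidities and _flags_available(df))
    ]
    if missing_cols:
        raise SchemaError(f"input lacks required column(s): {', '.join(missing_cols)}")

    for s in specs:
        if s.name not in df.columns:
            continue
        col = df[s.name]
        if s.vtype == "continuous":
            observed = col.dropna()
            if len(observed) and set(observed.astype(str)) <= set(s.levels):
                continue  # already categorical (simulated or pre-grouped input)
            numeric = pd.to_numeric(col, errors="coerce")
            bad = col.notna() & numeric.isna()
            if bad.any():
                lines = [int(i) + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
                raise CohortError(
                    f"{s.name}: unparseable numeric value(s) at line(s) {lines}"
                )
            df[s.name] = numeric
    return df


def _flags_available(df: pd.DataFrame) -> bool:
    return all(f in df.columns for f in COMORBIDITY_FLAGS)


def impute_missing(raw: pd.DataFrame, specs: list[VariableSpec]) -> pd.DataFrame:
    """Fill missing cells: column mean (continuous) or mode (categorical)."""
    out = raw.copy()
    for s in specs:
        if s.name not in out.columns:
            continue
        col = out[s.name]
        if not col.isna().any():
            continue
        observed = col.dropna()
        if observed.empty:
            raise CohortError(f"{s.name}: column entirely missing, cannot impute")
        if s.vtype == "continuous" and pd.api.types.is_numeric_dtype(col):
            fill = float(observed.mean())
        else:
            freq = observed.value_counts()
            top = freq.max()
            fill = sorted(freq.index[freq == top])[0]  # deterministic tie-break
        out[s.name] = col.fillna(fill)
    return out


def discretize(raw: pd.DataFrame, specs: list[VariableSpec]) -> CohortTable:
    """Map continuous columns to interval labels; validate categorical labels."""
    if raw.isna().any().any():
        raise CohortError("impute before discretizing: missing cells present")
    out = pd.DataFrame(index=raw.index)
    spec_map = {s.name: s for s in specs}
    out_name = outcome_spec(specs).name
    for s in specs:
        if s.name not in raw.columns:
            if s.derived_from_comorbidities and _flags_available(raw):
                out[s.name] = _comorbidity_count_levels(raw)
                continue
            raise SchemaError(f"input lacks required column(s): {s.name}")
        col = raw[s.name]
        if s.vtype == "continuous" and pd.api.types.is_numeric_dtype(col):
            out[s.name] = [s.interval_label(float(v)) for v in col]
        else:
            vals = col.astype(str)
            bad = set(vals) - set(s.levels)
            if bad:
                raise CohortError(f"{s.name}: unknown level label(s) {sorted(bad)}")
            out[s.name] = vals
    table = CohortTable(data=out, outcome_name=out_name, specs=spec_map)
    table.validate()
    _warn_inverted_references(table)
    return table


def _comorbidity_count_levels(df: pd.DataFrame) -> list[str]:
    flags = df[list(COMORBIDITY_FLAGS)].astype(str).eq("yes").sum(axis=1)
    return ["0" if k == 0 else ("1-2" if k <= 2 else ">=3") for k in flags]


def _warn_inverted_references(cohort: CohortTable) -> None:
    """Warn when a reference level has *higher* outcome incidence than every
    other level — a hint that the declared levels may be mislabeled."""
    y = cohort.outcome
    for name, spec in cohort.specs.items():
        if spec.role != PUTATIVE_RISK or len(spec.levels) != 2:
            continue
        col = cohort.data[name].astype(str).to_numpy()
        rates = {}
        for lv in spec.levels:
            mask = col == lv
            if mask.sum() == 0:
                continue
            rates[lv] = y[mask].mean()
        if len(rates) == 2:
            other = next(lv for lv in rates if lv != spec.reference)
            if rates.get(spec.reference, 0) > rates[other]:
                warnings.warn(
                    f"{name}: reference level {spec.reference!r} has higher outcome "
                    f"incidence than {other!r}; check whether levels are inverted",
                    stacklevel=2,
                )
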