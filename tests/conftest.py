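import warnings

import numpy as np
import pandas as pd
import pytest

import treestrat as ts
from treestrat.schema import CohortTable, VariableSpec, OUTCOME, CONFOUNDER, PUTATIVE_RISK


def make_cohort(columns: dict[str, list[str]], outcome: list[int],
                roles: dict[str, str] | None = None,
                references: dict[str, str] | None = None) -> CohortTable:
    """Build a small categorical cohort directly from lists.

    Levels are the sorted distinct labels per column; reference defaults to
    the lexicographically smallest level. Role defaults to putative_risk.
    """
    roles = roles or {}
    references = references or {}
    data = pd.DataFrame({k: [str(v) for v in vals] for k, vals in columns.items()})
    data["sepsis"] = [str(int(v)) for v in outcome]
    specs = {"sepsis": VariableSpec("sepsis", OUTCOME, "categorical", ("0", "1"), "0")}
    for name in columns:
        levels = tuple(sorted(set(data[name])))
        if len(levels) == 1:
            levels = levels + ("__other__",)  # pad: specs need >= 2 declared levels
        specs[name] = VariableSpec(
            name,
            roles.get(name, PUTATIVE_RISK),
            "categorical",
            levels,
            references.get(name, levels[0]),
        )
    return CohortTable(data=data, outcome_name="sepsis", specs=specs)


def expand_published(var: str) -> CohortTable:
    """Reconstruct a one-variable cohort from the published per-level counts."""
    from treestrat.published import published_counts
    from treestrat.schema import default_specs, outcome_spec

    specs = default_specs()
    spec = next(s for s in specs if s.name == var)
    rows, outcome = [], []
    for level, (non_ev, ev) in spec.counts.items():
        rows += [level] * (non_ev + ev)
        outcome += [0] * non_ev + [1] * ev
    data = pd.DataFrame({var: rows, "sepsis": [str(v) for v in outcome]})
    return CohortTable(
        data=data,
        outcome_name="sepsis",
        specs={var: spec, "sepsis": outcome_spec(specs)},
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort under the default study-like conditions."""
    cfg = ts.default_config(n=2500, seed=424242)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cohort, truth = ts.generate_cohort(cfg)
    return cohort, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20150901)
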