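"""Published summary counts of the study cohort, exposed as analysis inputs.

The original subject-level data are not public; what the study reports are
per-level counts by outcome (the characteristics table), the three tree-model
AIC values, and a handful of stratum incidences. Those printed numbers are
sufficient inputs for crude 2x2 effect estimation, chi-square tests, and
model-selection checks, and they anchor the synthetic-cohort defaults.
"""

from __future__ import annotations

from .effects import TwoByTwo
from .schema import VariableSpec, default_specs

#: printed AIC of the three candidate stratification models
PUBLISHED_AICS: dict[str, float] = {"model1": 3056.8, "model2": 2943.7, "model3": 2907.4}

COHORT_N = 7302
COHORT_EVENTS = 397


def published_counts(specs: list[VariableSpec] | None = None) -> dict[str, dict[str, tuple[int, int]]]:
    """Map variable -> level -> (non-event count, event count) as printed."""
    specs = specs if specs is not None else default_specs()
    return {s.name: dict(s.counts) for s in specs if s.counts is not None}


def published_two_by_two(
    variable: str,
    exposed: str,
    reference: str | None = None,
    specs: list[VariableSpec] | None = None,
) -> TwoByTwo:
    """Build the 2x2 outcome-by-exposure table for one printed contrast.

    Other levels of a multi-level variable are excluded (pairwise vs reference).
    """
    specs = specs if specs is not None else default_specs()
    spec = next(s for s in specs if s.name == variable)
    if reference is None:
        reference = spec.reference
    counts = spec.counts
    non_e, ev_e = counts[exposed]
    non_r, ev_r = counts[reference]
    return TwoByTwo(a=ev_e, b=non_e, c=ev_r, d=non_r)


def published_contingency(variable: str, specs: list[VariableSpec] | None = None):
    """K x 2 array of (non-event, event) counts in printed display order."""
    import numpy as np

    specs = specs if specs is not None else default_specs()
    spec = next(s for s in specs if s.name == variable)
    rows = [spec.counts[lv] for lv in spec.ordered_display_levels]
    return np.asarray(rows, dtype=float)
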