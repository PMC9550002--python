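"""Exception hierarchy for the pipeline.

``SchemaError`` covers configuration/specification problems (exit code 2 in the
CLI); ``CohortError`` covers problems with the data itself (exit code 1);
``EstimationError`` covers degenerate inputs to an estimator.
"""


class TreestratError(Exception):
    """Base class for all package errors."""


class SchemaError(TreestratError):
    """Variable specification or configuration is invalid."""


class CohortError(TreestratError):
    """The cohort data violates the schema or a precondition."""


class EstimationError(TreestratError):
    """An estimator received degenerate input (e.g. all strata uninformative)."""
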