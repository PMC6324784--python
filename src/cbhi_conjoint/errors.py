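"""Exception hierarchy for the conjoint pipeline.

Every error raised on bad user input derives from :class:`ConjointError`,
so callers (and the CLI) can catch one base class.
"""


class ConjointError(ValueError):
    """Base class for all package-specific errors."""


class SpecificationError(ConjointError):
    """Invalid attribute/level specification."""


class DesignError(ConjointError):
    """Invalid design request (pair counts, chunking, pair universe)."""


class ModelError(ConjointError):
    """Invalid population-model parameters."""


class DataError(ConjointError):
    """Malformed choice data (unknown levels, missing columns, bad brackets)."""


class EstimationError(ConjointError):
    """Estimation cannot proceed (empty cells, rank deficiency, too few clusters)."""
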