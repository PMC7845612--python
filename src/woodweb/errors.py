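"""Exception types raised across the pipeline."""


class WoodwebError(Exception):
    """Base class for all package-specific errors."""


class FormatError(WoodwebError, ValueError):
    """A file could not be parsed in the named dialect."""


class ValidationError(WoodwebError, ValueError):
    """Input data violates a structural invariant (ids, counts, metadata)."""


class UndefinedEstimatorError(WoodwebError, ValueError):
    """An estimator is mathematically undefined for the given input
    (e.g. ACE when every rare species is a singleton)."""


class DegenerateTestError(WoodwebError, ValueError):
    """A statistical test is degenerate for the given data
    (e.g. paired t with zero-variance differences)."""
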