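"""Exception hierarchy shared across the pipeline stages."""


class EcothreshError(Exception):
    """Base class for all package errors."""


class InputError(EcothreshError):
    """Invalid or inconsistent user input (bad CSV, missing covariate, ...)."""


class EmptySubgroupError(InputError):
    """A response series was requested for a subgroup with no member species."""


class NumericalError(EcothreshError):
    """A numerical stage failed (no converged fit, degenerate selection, ...)."""
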