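"""Exception types shared across the package."""


class MethylEstimandError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MethylEstimandError, ValueError):
    """A value passed to a transform or estimator is outside its domain."""


class InvalidConfigError(MethylEstimandError, ValueError):
    """A simulation or run configuration is infeasible or malformed."""


class DataError(MethylEstimandError, ValueError):
    """A file or table violates the format contract (bad header, range, ids)."""


class EmptyEnvelopeError(MethylEstimandError, ValueError):
    """No Beta-value pair within the requested bounds attains the M difference."""
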