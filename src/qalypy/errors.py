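"""Exception hierarchy shared across the package."""


class QalypyError(Exception):
    """Base class for all package-specific errors."""


class InputError(QalypyError, ValueError):
    """A caller supplied an out-of-range or malformed value."""


class ConfigurationError(QalypyError, ValueError):
    """A cohort spec or run configuration violates its invariants."""


class EstimationError(QalypyError, RuntimeError):
    """An estimator cannot produce a result (empty risk set, too few events, ...)."""


class SchemaError(QalypyError, ValueError):
    """A cohort table fails blocking validation checks."""
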