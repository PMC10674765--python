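"""Exception hierarchy shared across the pipeline."""


class SedmixError(Exception):
    """Base class for all package errors."""


class DataFormatError(SedmixError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class ValidationError(SedmixError):
    """A dataset row violates a range or structural rule."""


class DomainError(SedmixError, ValueError):
    """A parameter value lies outside its mathematical domain."""


class DesignError(SedmixError):
    """A study/cohort design is internally inconsistent."""


class InitializationError(SedmixError):
    """Estimation could not start from the supplied initial values."""


class ConvergenceError(SedmixError):
    """An iterative procedure failed to converge."""


class LinkageError(SedmixError):
    """Sequential PK-PD linkage is incomplete (e.g. a subject with BIS data
    has no individual PK estimate)."""


class DependencyError(SedmixError):
    """A pipeline stage was invoked before the stage it depends on."""
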