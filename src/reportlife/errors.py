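"""Exception hierarchy shared across the package."""


class ReportLifeError(Exception):
    """Base class for all package errors."""


class ParameterError(ReportLifeError, ValueError):
    """A numeric parameter is outside its admissible range.

    The message always names the offending field.
    """


class ConfigurationError(ReportLifeError, ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class IntegrityError(ReportLifeError, ValueError):
    """Referential or temporal integrity of input tables is violated."""


class SchemaError(ReportLifeError, ValueError):
    """A table does not conform to its declared schema."""


class EmptyStratumError(ReportLifeError, ValueError):
    """A summary was requested for a stratum that contains no observations."""


class FitError(ReportLifeError, ValueError):
    """Too few usable points remain to fit a trend model."""
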