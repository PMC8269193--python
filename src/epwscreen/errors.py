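"""Exception hierarchy shared across the package."""


class EpwScreenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EpwScreenError):
    """A configuration object violates its invariants; names the field."""


class ValidationError(EpwScreenError):
    """An input value is out of its physiologic/logical range."""


class ParseError(EpwScreenError):
    """A file could not be parsed; carries a line number where possible."""


class IncompleteBiometryError(EpwScreenError):
    """A required ultrasound measurement is missing; names the measurement."""


class MissingCovariateError(EpwScreenError):
    """A customized standard lacks a required maternal/fetal covariate."""


class FormulaRegistrationError(EpwScreenError):
    """Duplicate formula id at registration time."""


class FormulaNotFoundError(EpwScreenError):
    """Lookup of an unregistered formula id."""


class InfeasibleBiometryError(EpwScreenError):
    """No physiologic biometry set attains the requested fetal weight."""


class RangeError(EpwScreenError):
    """Gestational age (or another coordinate) outside a supported span."""


class ParameterError(EpwScreenError):
    """A growth-standard or reference parameter file fails validation at load."""


class DegenerateClassesError(EpwScreenError):
    """A screening statistic is undefined because one class is empty."""


class AlignmentError(EpwScreenError):
    """Paired score vectors do not align record-for-record."""


class SeparationError(EpwScreenError):
    """Logistic fit aborted: complete separation of classes."""
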