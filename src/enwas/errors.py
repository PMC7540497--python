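"""Exception types shared across the package."""


class EnwasError(Exception):
    """Base class for all package errors."""


class DictionaryError(EnwasError):
    """The data dictionary is inconsistent (bad gate level, cyclic parents, ...)."""


class ClassificationError(EnwasError):
    """A variable's type cannot be determined (e.g. mixed numeric/text, undeclared)."""


class ValidationError(EnwasError):
    """Input values violate a contract (e.g. an item score outside 0..3)."""


class ConfigError(EnwasError):
    """A scan/imputation/simulation configuration is invalid or references absent columns."""


class DegenerateFitError(EnwasError):
    """Exposure is constant after complete-case restriction; no model can be fit."""


class RankDeficiencyError(EnwasError):
    """Exposure design is collinear with the covariates."""


class SpecError(EnwasError):
    """A synthetic-cohort specification is infeasible."""
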