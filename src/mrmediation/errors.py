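"""Exception hierarchy for the MR pipeline."""


class MRMediationError(Exception):
    """Base class for all package errors."""


class ConfigError(MRMediationError):
    """A configuration value violates its documented bounds."""


class SchemaError(MRMediationError):
    """An input table is missing a mandatory column."""


class EmptyInputError(MRMediationError):
    """A table contains no valid rows after validation."""


class HarmonizationError(MRMediationError):
    """Exposure and outcome tables share no variants."""


class UndefinedRatioError(MRMediationError):
    """Wald ratio requested for a variant with zero exposure effect."""


class InsufficientInstrumentsError(MRMediationError):
    """An estimator was given fewer instruments than it requires."""


class UndefinedProportionError(MRMediationError):
    """Proportion mediated requested with a zero total effect."""
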