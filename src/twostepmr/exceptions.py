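"""Exception hierarchy for the two-step MR pipeline."""


class TwoStepMRError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TwoStepMRError):
    """A setting, column map, or parameter value is unusable."""


class EmptyInputError(TwoStepMRError):
    """An input file or record list contained no usable rows."""


class NoInstrumentsError(TwoStepMRError):
    """No instrumental variables survive selection/harmonization."""


class InsufficientInstrumentsError(NoInstrumentsError):
    """Instruments exist but are too few for the requested method."""


class DegenerateInstrumentError(TwoStepMRError, ValueError):
    """An instrument with a zero exposure effect cannot form a Wald ratio."""
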