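"""Exception hierarchy shared by all pipeline stages."""


class KinomeScreenError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(KinomeScreenError):
    """A table is missing a required column or has an unparseable header."""


class IntegrityError(KinomeScreenError):
    """A table violates a structural invariant (duplicate keys, self-loops...)."""


class VocabularyError(KinomeScreenError):
    """A categorical field holds a label outside its controlled vocabulary."""


class ValidationError(KinomeScreenError):
    """A value or argument violates an operation's precondition."""


class ParameterError(KinomeScreenError):
    """An analysis parameter is out of its admissible range."""


class DegenerateScreenError(KinomeScreenError):
    """A robust scale estimate is zero; the screen needs manual inspection."""


class QCError(KinomeScreenError):
    """Plate-level quality control cannot be evaluated (missing controls)."""


class FitError(KinomeScreenError):
    """A model fit is impossible on the given data (e.g. constant degrees)."""


class PlacementError(KinomeScreenError):
    """Synthetic objects cannot be placed at the requested density."""


class ConfigError(KinomeScreenError):
    """A generator or pipeline configuration is inconsistent."""


class PipelineError(KinomeScreenError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
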