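"""Exception hierarchy shared across the package."""


class BeecastError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(BeecastError):
    """Invalid configuration value (non-positive counts, negative rates, ...)."""


class AlignmentError(BeecastError):
    """Series that must share an hour grid do not overlap or disagree in length."""


class GapError(BeecastError):
    """A weather gap exceeds the configured maximum interpolatable length."""


class InsufficientDataError(BeecastError):
    """Panel or dataset too short for the requested window / split."""


class DegenerateScaleError(BeecastError):
    """A channel is constant, so min-max scaling is undefined."""


class TrainingError(BeecastError):
    """Training diverged (non-finite loss) or a replicate failed.

    ``partial`` may carry results collected before the failure.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial
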