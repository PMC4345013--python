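"""Exception hierarchy shared across the pipeline."""


class LarvatrackError(Exception):
    """Base class for all larvatrack errors."""


class ConfigurationError(LarvatrackError):
    """A configuration value violates a documented invariant.

    The message names the offending key so callers (and the CLI) can report it.
    """


class CalibrationError(LarvatrackError):
    """The mm/pixel calibration is unusable (e.g. worm thinner than 2 px)."""


class TopologyError(LarvatrackError):
    """A skeleton could not be reduced to a single endpoint-to-endpoint path."""

    def __init__(self, message: str, reason: str = "topology"):
        super().__init__(message)
        self.reason = reason


class EmptySeriesError(LarvatrackError):
    """An operation that needs at least one valid pose received none."""


class PointsFileError(LarvatrackError):
    """A points/stage-log table could not be parsed; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line
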