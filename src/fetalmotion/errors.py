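"""Exception hierarchy for the fetalmotion pipeline."""


class FetalMotionError(Exception):
    """Base class for all fetalmotion errors."""


class FormatError(FetalMotionError):
    """A file does not conform to the documented on-disk format."""


class SamplingError(FormatError):
    """A time column is present but not uniformly sampled."""


class ConfigurationError(FetalMotionError):
    """A configuration value is invalid or inconsistent."""


class InputError(FetalMotionError):
    """An in-memory input violates an operation precondition."""


class IncompleteDesignError(InputError):
    """A repeated-measures table has missing cells."""


class DegenerateSessionError(InputError):
    """A session has zero analysis time."""
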