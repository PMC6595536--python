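"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 1 (user error), ``DataError`` and its
subclasses to exit code 2 (data error).
"""


class ApneaEbrError(Exception):
    """Base class for all package errors."""


class ConfigError(ApneaEbrError):
    """Invalid configuration or arguments supplied by the user."""


class DataError(ApneaEbrError):
    """Input data violates a precondition of the pipeline."""


class MissingChannelError(DataError):
    """A requested channel label is absent from a recording."""


class AnnotationParseError(DataError):
    """An annotation file line could not be parsed."""


class FlatFrameError(DataError):
    """A frame is constant after mean removal and cannot be normalised."""


class DegenerateBandError(DataError):
    """A band-limited signal carries exactly zero energy."""
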