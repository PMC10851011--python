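"""Exception hierarchy.

Configuration problems (bad parameters, malformed run configs) are kept
distinct from data problems (unparseable or inconsistent input files) so the
CLI can map them to different exit codes.
"""


class AmpEditError(Exception):
    """Base class for all package errors."""


class ConfigurationError(AmpEditError):
    """Invalid parameters or run configuration."""


class InputError(AmpEditError):
    """Invalid input data (sequences, tables, descriptors)."""


class ParseError(InputError):
    """A file could not be parsed; carries record/line context in the message."""


class GuideNotFoundError(InputError):
    """The protospacer+PAM was not found on the stated strand of the reference."""


class AmbiguousGuideError(InputError):
    """The protospacer+PAM matched the reference more than once."""


class InternalError(AmpEditError):
    """Invariant violation inside the package; indicates a bug."""
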