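"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: validation/config errors -> 2,
data/format errors -> 3, protocol or degenerate-input errors -> 4.
"""


class AttachmonError(Exception):
    """Base class for package errors."""


class ConfigError(AttachmonError, ValueError):
    """Invalid configuration value or combination."""


class FormatError(AttachmonError, ValueError):
    """A file could not be parsed in the expected dialect."""


class SchemaError(AttachmonError, ValueError):
    """Structurally valid input whose shape/schema is inconsistent."""


class LabelError(AttachmonError, ValueError):
    """Invalid or duplicated attachment label row."""


class DegenerateInputError(AttachmonError, ValueError):
    """Input too small or too uniform for the requested operation."""


class ProtocolError(AttachmonError, ValueError):
    """Evaluation protocol preconditions violated (e.g. one child only)."""
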