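"""Exception hierarchy.

``ConstrictaxisError`` marks user/input problems (CLI exit code 1); anything
else escaping a command is treated as an internal error (exit code 2).
"""


class ConstrictaxisError(Exception):
    """Base class for user-facing errors."""


class InvalidParameterError(ConstrictaxisError, ValueError):
    """A parameter violates its documented domain."""


class OutOfBoundsError(ConstrictaxisError, ValueError):
    """A coordinate lies outside the device chamber."""


class FormatError(ConstrictaxisError, ValueError):
    """An input file does not match the expected dialect."""


class ConfigError(ConstrictaxisError, ValueError):
    """Invalid or unknown configuration keys/values."""


class MaskError(ConstrictaxisError, ValueError):
    """Label/mask images that violate a precondition (nesting, size...)."""


class RenderOverlapError(ConstrictaxisError, RuntimeError):
    """Cells could not be placed without overlap within the retry cap."""


class ReportError(ConstrictaxisError, RuntimeError):
    """A report stage is missing its upstream output."""
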