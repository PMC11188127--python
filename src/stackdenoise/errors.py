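"""Exception hierarchy shared across the package.

The CLI maps these onto distinct process exit codes, so keep raising the
most specific class available.
"""


class StackDenoiseError(Exception):
    """Base class for all package errors."""


class ConfigError(StackDenoiseError):
    """Invalid configuration or arguments (exit code 3)."""


class FormatError(StackDenoiseError):
    """Malformed file contents: inconsistent TIFF pages, bad manifest (exit 4)."""


class ResolutionError(StackDenoiseError):
    """A manifest references files that do not exist (exit 4)."""


class DegenerateInputError(StackDenoiseError):
    """Input degenerate for the requested operation, e.g. a constant stack."""


class NumericError(StackDenoiseError):
    """Non-finite values where finite ones are required (exit 5)."""
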