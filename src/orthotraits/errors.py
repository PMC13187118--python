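"""Exception hierarchy shared by all pipeline stages.

The command-line layer maps :class:`OrthotraitsError` (and subclasses) to
exit code 2 (bad input / bad configuration); anything else is an internal
error and exits 1.
"""


class OrthotraitsError(Exception):
    """Base class for user-facing errors (bad input, bad config)."""


class ParseError(OrthotraitsError):
    """A file could not be parsed in the declared dialect."""

    def __init__(self, message: str, path=None, line: int | None = None):
        prefix = ""
        if path is not None:
            prefix += f"{path}: "
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)
        self.path = path
        self.line = line


class EmptyInputError(ParseError):
    """The input file contained no records at all."""


class ValidationError(OrthotraitsError):
    """Parsed data violate a documented invariant."""


class ConfigError(OrthotraitsError):
    """Parameters or column specifications are inconsistent."""
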