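"""Exception hierarchy shared across modules."""


class AllomethError(Exception):
    """Base class for package errors."""


class ConfigError(AllomethError):
    """A configuration value violates its documented invariant."""


class FormatError(AllomethError):
    """An input file does not match the expected dialect."""


class RowError(FormatError):
    """A specific row of an input file is invalid; the message names it."""


class ParameterError(AllomethError):
    """A function argument is outside its valid range."""
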