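"""Exception hierarchy shared across the package."""


class CooccurError(Exception):
    """Base class for all package errors."""


class InputError(CooccurError):
    """A required input file is missing or unreadable."""


class FormatError(CooccurError):
    """An input file exists but does not match the expected layout."""


class EmptyInputError(CooccurError):
    """An operation received zero usable records or transactions."""


class ConfigError(CooccurError):
    """A run configuration value is invalid or inconsistent."""
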