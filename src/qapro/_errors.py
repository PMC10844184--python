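"""Exception types shared across the package."""


class QaproError(Exception):
    """Base class for package errors."""


class InvalidResponseError(QaproError):
    """An item response lies outside the declared range for its scale."""


class InvalidLevelError(QaproError):
    """A health-state dimension level lies outside 1-4."""


class InsufficientDataError(QaproError):
    """An analysis was requested on data that cannot support it."""


class ConfigurationError(QaproError):
    """An analysis or simulation configuration is invalid."""
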