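"""Exception hierarchy for the accelval pipeline."""


class AccelValError(Exception):
    """Base class for all accelval-specific errors."""


class FormatError(AccelValError):
    """A delimited-text input does not have the expected layout."""


class DataError(AccelValError):
    """Input values violate a data contract (e.g. non-monotone timestamps)."""


class ProfileError(AccelValError):
    """A recording is inconsistent with the device profile it was read under."""


class InsufficientDataError(AccelValError):
    """Too few samples/seconds to compute the requested quantity."""


class UndefinedStatisticError(AccelValError):
    """The requested statistic is undefined on this input (e.g. zero variance)."""


class ConfigError(AccelValError):
    """A simulation or experiment configuration violates its invariants."""


class LinkageError(AccelValError):
    """Records that must be joined (sessions, METs, recordings) do not match up."""
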