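"""Exception hierarchy for wheelbouts."""


class WheelboutsError(ValueError):
    """Base class for all wheelbouts validation failures."""


class FormatError(WheelboutsError):
    """A file does not conform to the expected on-disk dialect."""


class ValidationError(WheelboutsError):
    """Data violates a structural invariant (ordering, overlap, coverage)."""


class InsufficientDataError(WheelboutsError):
    """An operation received fewer samples than its minimum."""


class ConfigurationError(WheelboutsError):
    """An estimator or run configuration is out of its valid range."""
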