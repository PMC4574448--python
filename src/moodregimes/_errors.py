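"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Invalid input: malformed data, inconsistent parameters, bad config."""


class DegenerateSeriesError(ValueError):
    """A series whose statistic is undefined (e.g. zero variance).

    Deliberately *not* a :class:`ValidationError`: a constant series is a
    legitimate observation (a patient who never changed state), not bad
    input, and callers are expected to report it as "undefined" rather than
    reject it.
    """


class ConfigError(ValidationError):
    """A configuration file failed validation."""
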