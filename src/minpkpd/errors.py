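"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """An unknown key or malformed document was passed to a config loader."""


class ValidationError(ValueError):
    """A parameter or schedule field violates its invariant.

    The message always names the offending field.
    """


class ScheduleError(ValueError):
    """A dose schedule was used with the wrong channel or out-of-range time."""


class IntegrationError(RuntimeError):
    """The ODE state became non-finite; the message reports the time of failure."""
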