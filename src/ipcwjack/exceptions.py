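"""Exception hierarchy.

``ConfigError`` and ``DataError`` map to distinct CLI exit codes (2 and 3);
everything else derives from :class:`IPCWJackError`.
"""


class IPCWJackError(Exception):
    """Base class for all package errors."""


class ConfigError(IPCWJackError):
    """Invalid configuration, request, or argument combination."""


class DataError(IPCWJackError):
    """Malformed or inconsistent input data."""


class WeightUndefinedError(IPCWJackError):
    """The censoring-survival estimate is zero at a required evaluation point.

    IPC weights 1/G(t) are undefined there; ``time`` records the offending
    evaluation point.
    """

    def __init__(self, time: float):
        self.time = float(time)
        super().__init__(
            f"censoring-survival estimate is 0 at t={self.time:g}; "
            "IPC weight 1/G(t) is undefined"
        )


class FitError(IPCWJackError):
    """A model fit failed (separation, non-convergence, degenerate data)."""
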