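"""Exception hierarchy.

Every error the library raises deliberately derives from :class:`HurstwaveError`
so callers (and the CLI) can distinguish our diagnostics from genuine bugs.
"""


class HurstwaveError(Exception):
    """Base class for all library errors."""


class ParameterError(HurstwaveError, ValueError):
    """A function argument violates its documented precondition."""


class FormatError(HurstwaveError, ValueError):
    """A file does not conform to the expected on-disk format."""


class ChannelLookupError(HurstwaveError, KeyError):
    """A requested EDF channel is not present in the recording."""

    def __init__(self, requested: str, available: list[str]):
        self.requested = requested
        self.available = list(available)
        super().__init__(
            f"channel {requested!r} not found; available channels: {self.available}"
        )


class DegenerateInputError(HurstwaveError, ValueError):
    """Input is degenerate for the requested operation (e.g. constant signal)."""


class ZeroDispersionError(DegenerateInputError):
    """A window has zero standard deviation, so R/S is undefined there."""


class EstimationError(HurstwaveError, RuntimeError):
    """A statistical estimate could not be formed from the available data."""


class LayoutMismatchError(HurstwaveError, ValueError):
    """Feature names/order at predict time differ from those seen at fit time."""
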