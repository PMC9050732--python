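"""Exception hierarchy shared by the nanosynapse modules."""


class NanosynapseError(Exception):
    """Base class for all package-specific errors."""


class FormatError(NanosynapseError):
    """A localization table (or other input file) violates the declared dialect."""


class RowParseError(FormatError):
    """A specific data row could not be parsed; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class UnknownChannelError(NanosynapseError, KeyError):
    """A requested channel label is not present in the table."""


class DegenerateInputError(NanosynapseError, ValueError):
    """An operation received an input it is mathematically undefined on
    (empty cluster, zero macroclusters, all-zero histogram, ...)."""


class PlacementError(NanosynapseError, RuntimeError):
    """The synthetic field is too crowded to place the requested objects."""


class InsufficientReplicatesError(NanosynapseError, ValueError):
    """A significance test was requested with fewer than two replicates."""
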