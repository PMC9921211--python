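"""Exception hierarchy shared across the package."""


class ScreenMDError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ScreenMDError):
    """An input file is missing required structure (columns, header)."""


class ParseError(ScreenMDError):
    """A cell or record could not be interpreted."""


class UndefinedPotencyError(ScreenMDError):
    """A bioactive record carries no determined affinity value."""


class ConfigurationError(ScreenMDError):
    """A parameter value is outside its admissible range."""


class ShortfallError(ScreenMDError):
    """The candidate pool cannot supply enough eligible decoys."""

    def __init__(self, active_id: str, needed: int, available: int):
        self.active_id = active_id
        self.needed = needed
        self.available = available
        super().__init__(
            f"decoy shortfall for active {active_id!r}: "
            f"needed {needed}, only {available} eligible candidates remain"
        )


class EmptyClassError(ScreenMDError):
    """A ranked library lacks actives or decoys where both are required."""


class JoinError(ScreenMDError):
    """Library entries could not be joined to curated records."""


class SelectionError(ScreenMDError):
    """An atom-selection expression is invalid or matches nothing."""


class DegenerateFitError(ScreenMDError):
    """Too few / collinear atoms for a rigid-body rotational fit."""
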