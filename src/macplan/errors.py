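"""Exception hierarchy for macplan."""


class MacPlanError(Exception):
    """Base class for all macplan errors."""


class SequenceError(MacPlanError):
    """Invalid DNA sequence input (ambiguity codes, multi-record FASTA, ...)."""


class EnzymeTableError(MacPlanError):
    """Malformed enzyme table (missing column, inconsistent cohesive end)."""


class UnknownEnzymeError(MacPlanError):
    """Lookup of an enzyme name or synonym that is not in the set."""


class IncompatibleEndsError(MacPlanError):
    """Ligation or hybrid-site construction over mismatched cohesive ends."""


class EligibilityError(MacPlanError):
    """Enzyme not eligible for hybrid-site generation (not 5', 4-base)."""


class NoJunctionFound(MacPlanError):
    """Planner exhausted all junction candidates for a window."""

    def __init__(self, window: tuple[int, int], message: str | None = None):
        self.window = window
        super().__init__(
            message or f"no usable junction site in window {window[0]}..{window[1]}"
        )


class PlantError(MacPlanError):
    """Overlapping or out-of-bounds planted site."""


class SimulationError(MacPlanError):
    """In-silico assembly could not cut at an intended junction site."""
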