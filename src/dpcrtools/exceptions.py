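"""Typed errors raised across the toolkit."""


class DigitalPCRError(Exception):
    """Base class for all dpcrtools errors."""


class InvalidInputError(DigitalPCRError, ValueError):
    """An argument violates a precondition (negative count, λ ≤ 0, ...)."""


class SaturatedChipError(DigitalPCRError):
    """All partitions positive: the Poisson MLE is unbounded (z = 0)."""


class UnachievablePrecisionError(DigitalPCRError):
    """The requested precision is below the best achievable at this n.

    Carries the achievable minimum so callers can report it.
    """

    def __init__(self, requested: float, minimum: float):
        self.requested = requested
        self.minimum = minimum
        super().__init__(
            f"precision {requested:g} is unachievable; minimum achievable "
            f"precision is {minimum:.6g}"
        )


class SchemaError(DigitalPCRError):
    """An input table is missing required columns."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__(f"input table is missing required columns: {', '.join(missing)}")


class ContaminationError(DigitalPCRError):
    """A no-template control exceeded the allowed number of positives."""
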