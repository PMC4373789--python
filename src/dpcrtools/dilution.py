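"""Dynamic-range extension via paired and serial dilutions.

One chip supports a limited window of concentrations at a given precision.
Running the sample at several dilutions shifts copies of that window up
the concentration axis: a 1:d dilution multiplies the window (expressed in
original-sample copies/µL) by d without changing its log-width.  As long
as consecutive windows overlap — the *continuous detection* criterion —
the union covers one long range.  The largest factor preserving
continuity for identical chips is d* = λ_u/λ_l, the per-chip window ratio.

Splitting a fixed partition budget across steps (constant available
partitioning) shrinks each step's window and raises the undiluted LOD:
dynamic range is bought with sensitivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .core import (
    DEFAULT_SPEC,
    ChipDesign,
    ConfidenceSpec,
    DetectionWindow,
    detection_limits_at_precision,
)
from .exceptions import InvalidInputError

__all__ = [
    "DilutionStep",
    "PlannedStep",
    "DilutionPlan",
    "ContinuityVerdict",
    "step_window",
    "build_plan",
    "check_continuity",
    "combined_range",
    "max_paired_factor",
    "optimize_serial_plan",
]


@dataclass(frozen=True)
class DilutionStep:
    """One dilution point: factor d (1 = undiluted) and its chip."""

    factor: float
    design: ChipDesign

    def __post_init__(self) -> None:
        if not self.factor >= 1.0:
            raise InvalidInputError("dilution factor must be >= 1")

    @property
    def partitions(self) -> int:
        return self.design.n


@dataclass(frozen=True)
class PlannedStep:
    """A step together with its detection window in original-sample units."""

    step: DilutionStep
    lambda_window: DetectionWindow
    conc_low: float  # copies/µL of the *original* sample
    conc_high: float


@dataclass(frozen=True)
class ContinuityVerdict:
    continuous: bool
    first_gap: tuple[float, float] | None = None  # (upper of step k, lower of step k+1)


@dataclass(frozen=True)
class DilutionPlan:
    """An evaluated multi-dilution design."""

    steps: tuple[PlannedStep, ...]
    precision_bound: float
    continuity: ContinuityVerdict
    combined_range: float  # log10 units actually covered
    combined_lod: float  # lowest detectable original-sample copies/µL

    @property
    def continuous(self) -> bool:
        return self.continuity.continuous


def step_window(
    step: DilutionStep, precision_bound: float, spec: ConfidenceSpec = DEFAULT_SPEC
) -> PlannedStep:
    """Detection window of one step, mapped to original-sample copies/µL.

    A 1:d dilution means the chip sees C/d, so original-sample coverage is
    d · [λ_l/V, λ_u/V].
    """
    win = detection_limits_at_precision(step.partitions, precision_bound, spec)
    v = step.design.partition_volume
    return PlannedStep(
        step=step,
        lambda_window=win,
        conc_low=step.factor * win.lambda_low / v,
        conc_high=step.factor * win.lambda_high / v,
    )


def build_plan(
    steps, precision_bound: float, spec: ConfidenceSpec = DEFAULT_SPEC
) -> DilutionPlan:
    """Evaluate a list of :class:`DilutionStep` into a full plan.

    Steps are sorted by factor; windows touching at a point count as
    overlapping.  When the union has gaps, ``combined_range`` is the sum of
    log10 widths actually covered (gaps excluded) and the verdict records
    the first gap.
    """
    steps = list(steps)
    if not steps:
        raise InvalidInputError("a plan needs at least one step")
    planned = sorted(
        (step_window(s, precision_bound, spec) for s in steps),
        key=lambda p: p.step.factor,
    )
    continuous = True
    first_gap = None
    covered = 0.0
    cur_lo, cur_hi = planned[0].conc_low, planned[0].conc_high
    for nxt in planned[1:]:
        if nxt.conc_low <= cur_hi:  # overlap or touch: merge
            cur_hi = max(cur_hi, nxt.conc_high)
        else:
            if continuous:
                continuous = False
                first_gap = (cur_hi, nxt.conc_low)
            covered += math.log10(cur_hi / cur_lo)
            cur_lo, cur_hi = nxt.conc_low, nxt.conc_high
    covered += math.log10(cur_hi / cur_lo)
    return DilutionPlan(
        steps=tuple(planned),
        precision_bound=precision_bound,
        continuity=ContinuityVerdict(continuous=continuous, first_gap=first_gap),
        combined_range=covered,
        combined_lod=planned[0].conc_low,
    )


def check_continuity(plan: DilutionPlan) -> ContinuityVerdict:
    """Continuity verdict of an evaluated plan (first gap if any)."""
    return plan.continuity


def combined_range(plan: DilutionPlan) -> tuple[float, float]:
    """(log10 range covered, combined LOD in original-sample copies/µL)."""
    return plan.combined_range, plan.combined_lod


def max_paired_factor(
    n_per_step: int,
    precision_bound: float,
    spec: ConfidenceSpec = DEFAULT_SPEC,
) -> tuple[float, float]:
    """Largest pair dilution factor keeping detection continuous.

    For two identical chips the diluted window stays attached to the
    undiluted one up to d* = λ_u/λ_l; at that boundary the combined range
    is exactly twice the single-chip range.  Returns ``(d*, R_total)``.
    """
    win = detection_limits_at_precision(n_per_step, precision_bound, spec)
    d_star = win.lambda_high / win.lambda_low
    return d_star, 2.0 * win.dynamic_range


def optimize_serial_plan(
    total_partitions: int,
    k_subsets: int,
    precision_bound: float,
    spec: ConfidenceSpec = DEFAULT_SPEC,
    partition_volume: float = 8.65e-4,
) -> DilutionPlan:
    """Maximal-range serial plan under constant available partitioning.

    The partition budget is split into ``k_subsets`` equal subsets
    (remainder discarded); successive dilution factors sit at the subset
    window's continuity boundary d*, so consecutive windows exactly touch
    and the combined range is maximal while remaining gap-free.
    """
    if k_subsets < 1:
        raise InvalidInputError("k_subsets must be >= 1")
    n_sub = total_partitions // k_subsets
    if n_sub < 1:
        raise InvalidInputError("fewer than one partition per subset")
    design = ChipDesign(n=n_sub, partition_volume=partition_volume)
    win = detection_limits_at_precision(n_sub, precision_bound, spec)
    d_star = win.lambda_high / win.lambda_low
    steps = [DilutionStep(factor=d_star**k, design=design) for k in range(k_subsets)]
    return build_plan(steps, precision_bound, spec)
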