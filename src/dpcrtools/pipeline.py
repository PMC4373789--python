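"""Paired-dilution quantification: read chip summaries, prune, combine.

The workflow mirrors a two-chip absolute-quantification experiment: every
sample is run undiluted and at a fixed dilution (1:50 here), with
replicates, plus no-template controls (NTCs).  Per-chip concentrations are
estimated with the Poisson model, a fixed-order rule set prunes unreliable
chips, and surviving chips are combined per sample by inverse-variance
weighting on the log scale (the CI of a dPCR estimate is log-normal, so
log-scale pooling is the natural choice; a plain geometric mean is
available as an alternative).

Pruning rules, applied in order:

1. every NTC must stay below a positive-call ceiling, else the run aborts
   as contaminated;
2. chips without a "green" quality flag are marked for manual threshold
   review (optionally excluded);
3. if at least one chip of a sample reads inside the preferred
   concentration range, chips outside the range are dropped;
4. if both dilution points read in range but their fold disagrees with the
   expected dilution factor by more than a tolerance, the pair is dropped;
5. if every chip of a sample reads above a high cutoff, only the lowest-
   reading dilution point is kept;
6. if every chip reads below a low cutoff, only the highest is kept.

Range checks use the chip's measured (dilution-uncorrected) concentration;
combination uses the dilution-corrected value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SPEC,
    ChipDesign,
    ConfidenceSpec,
    PartitionCounts,
    estimate_lambda,
    lambda_to_concentration,
    sampling_sigma,
)
from .exceptions import ContaminationError, DigitalPCRError, SaturatedChipError, SchemaError

__all__ = [
    "ChipRecord",
    "PruningConfig",
    "SampleResult",
    "PipelineResult",
    "DEFAULT_COLUMNS",
    "QUANTSTUDIO_COLUMNS",
    "read_chip_table",
    "apply_pruning_rules",
    "combine_sample",
    "fold_changes",
    "overall_dynamic_range",
    "run_pipeline",
    "audit_frame",
]

#: canonical column names expected after mapping
_REQUIRED = ["sample", "chip", "dilution", "total_partitions", "positives", "partition_volume_ul"]
_OPTIONAL = ["is_ntc", "flag"]

DEFAULT_COLUMNS = {c: c for c in _REQUIRED + _OPTIONAL}

#: mapping for tables exported in a QuantStudio-style layout
QUANTSTUDIO_COLUMNS = {
    "sample": "Sample",
    "chip": "Chip ID",
    "dilution": "Dilution",
    "total_partitions": "Total Wells",
    "positives": "FAM Positives",
    "partition_volume_ul": "Well Volume (uL)",
    "is_ntc": "NTC",
    "flag": "Flag",
}


@dataclass
class ChipRecord:
    """One chip flowing through the pipeline, with an append-only audit trail."""

    sample_id: str
    chip_id: str
    dilution_factor: float
    counts: PartitionCounts
    design: ChipDesign
    is_ntc: bool = False
    quality_flag: str = "green"
    lam: float | None = None
    concentration: float | None = None  # measured, copies/µL in-reaction
    corrected_concentration: float | None = None  # × dilution factor
    status: str = "kept"
    audit: list[str] = dc_field(default_factory=list)

    def reject(self, reason: str) -> None:
        self.status = "rejected"
        self.audit.append(reason)

    @property
    def rejection_rule(self) -> str | None:
        return self.audit[-1] if self.status == "rejected" else None


@dataclass(frozen=True)
class PruningConfig:
    """Thresholds of the fixed-order pruning rule set (copies/µL)."""

    ntc_max_positives: int = 50
    preferred_range: tuple[float, float] = (200.0, 2000.0)
    expected_fold: float = 50.0
    pair_fold_tolerance: float = 0.30
    high_cutoff: float = 4600.0
    low_cutoff: float = 9.0
    exclude_review_flagged: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.preferred_range
        if not (0 < lo < hi):
            raise DigitalPCRError("preferred_range must satisfy 0 < low < high")


@dataclass(frozen=True)
class SampleResult:
    """Combined original-sample concentration for one sample."""

    sample_id: str
    combined_concentration: float  # copies/µL, original-sample units
    ci: tuple[float, float]
    contributing_chips: tuple[str, ...]


@dataclass(frozen=True)
class PipelineResult:
    records: tuple[ChipRecord, ...]
    sample_results: tuple[SampleResult, ...]
    unquantifiable: tuple[str, ...]
    rule_report: dict[str, list[str]]


def _coerce_row(row: pd.Series) -> ChipRecord:
    n = int(row["total_partitions"])
    pos = int(row["positives"])
    if pos < 0 or pos > n:
        raise ValueError(f"positives ({pos}) outside [0, total={n}]")
    d = float(row["dilution"])
    if d < 1:
        raise ValueError(f"dilution factor must be >= 1, got {d}")
    return ChipRecord(
        sample_id=str(row["sample"]),
        chip_id=str(row["chip"]),
        dilution_factor=d,
        counts=PartitionCounts(n=n, negatives=n - pos),
        design=ChipDesign(n=n, partition_volume=float(row["partition_volume_ul"])),
        is_ntc=bool(row.get("is_ntc", False)),
        quality_flag=str(row.get("flag", "green")),
    )


def read_chip_table(
    path, column_map: dict[str, str] | None = None
) -> tuple[list[ChipRecord], list[tuple[int, str]]]:
    """Read a delimited chip-summary table into records.

    ``column_map`` maps canonical names (sample, chip, dilution,
    total_partitions, positives, partition_volume_ul, optionally is_ntc
    and flag) to the file's column headers.  Malformed rows are returned
    as ``(row_index, message)`` pairs rather than silently dropped.
    """
    column_map = dict(column_map or DEFAULT_COLUMNS)
    df = pd.read_csv(path)
    missing = [
        canon for canon in _REQUIRED if column_map.get(canon, canon) not in df.columns
    ]
    if missing:
        raise SchemaError(missing)
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)
    records: list[ChipRecord] = []
    errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            records.append(_coerce_row(row))
        except (ValueError, DigitalPCRError) as exc:
            errors.append((int(idx), str(exc)))
    return records, errors


def _estimate_record(rec: ChipRecord) -> None:
    try:
        rec.lam = estimate_lambda(rec.counts)
    except SaturatedChipError:
        rec.reject("saturated: all partitions positive")
        return
    rec.concentration = lambda_to_concentration(rec.lam, rec.design)
    rec.corrected_concentration = rec.concentration * rec.dilution_factor
    if rec.lam == 0.0 and not rec.is_ntc:
        rec.reject("all_negative: no positives, below detection")


def apply_pruning_rules(
    records: list[ChipRecord], config: PruningConfig = PruningConfig()
) -> tuple[list[ChipRecord], dict[str, list[str]]]:
    """Estimate every chip and apply the rule set in its fixed order.

    Mutates the records' status/audit fields in place and returns them with
    a rule → affected-chip report.  Raises :class:`ContaminationError` if
    any NTC exceeds the positive-call ceiling.
    """
    report: dict[str, list[str]] = {f"rule{i}": [] for i in range(1, 7)}
    for rec in records:
        _estimate_record(rec)

    # rule 1: NTC ceiling
    for rec in records:
        if rec.is_ntc:
            if rec.counts.positives >= config.ntc_max_positives:
                raise ContaminationError(
                    f"NTC {rec.chip_id} has {rec.counts.positives} positives "
                    f"(ceiling {config.ntc_max_positives}); suspect contamination"
                )
            rec.status = "ntc"
            rec.audit.append("rule1: NTC passed positive-call ceiling")
            report["rule1"].append(rec.chip_id)

    # rule 2: quality flag review
    for rec in records:
        if not rec.is_ntc and rec.quality_flag.lower() != "green":
            rec.audit.append("rule2: flagged for manual threshold review")
            report["rule2"].append(rec.chip_id)
            if config.exclude_review_flagged and rec.status == "kept":
                rec.reject("rule2: non-green flag excluded")

    lo, hi = config.preferred_range

    def kept(sample: str) -> list[ChipRecord]:
        return [
            r
            for r in records
            if r.sample_id == sample and not r.is_ntc and r.status == "kept"
        ]

    def in_range(r: ChipRecord) -> bool:
        return lo <= r.concentration <= hi

    samples = list(dict.fromkeys(r.sample_id for r in records if not r.is_ntc))

    # rule 3: preferred concentration range
    for sample in samples:
        chips = kept(sample)
        if any(in_range(r) for r in chips):
            for r in chips:
                if not in_range(r):
                    r.reject("rule3: outside preferred concentration range")
                    report["rule3"].append(r.chip_id)

    # rule 4: paired fold consistency (both dilution points in range)
    for sample in samples:
        chips = kept(sample)
        by_factor: dict[float, list[ChipRecord]] = {}
        for r in chips:
            by_factor.setdefault(r.dilution_factor, []).append(r)
        if len(by_factor) != 2:
            continue
        d_lo, d_hi = sorted(by_factor)
        if not all(in_range(r) for r in chips):
            continue
        conc_orig = _geomean([r.concentration for r in by_factor[d_lo]])
        conc_dil = _geomean([r.concentration for r in by_factor[d_hi]])
        observed_fold = conc_orig / conc_dil
        if abs(observed_fold - config.expected_fold) / config.expected_fold > config.pair_fold_tolerance:
            for r in chips:
                r.reject(
                    f"rule4: pair fold {observed_fold:.3g} deviates from "
                    f"expected {config.expected_fold:g} by more than "
                    f"{config.pair_fold_tolerance:.0%}"
                )
                report["rule4"].append(r.chip_id)

    # rules 5 & 6: saturating / vanishing samples
    for sample in samples:
        chips = kept(sample)
        if not chips:
            continue
        by_factor = {}
        for r in chips:
            by_factor.setdefault(r.dilution_factor, []).append(r)
        if len(by_factor) < 2:
            continue
        if all(r.concentration > config.high_cutoff for r in chips):
            best = min(by_factor, key=lambda d: _geomean([r.concentration for r in by_factor[d]]))
            for d, group in by_factor.items():
                if d != best:
                    for r in group:
                        r.reject("rule5: all chips above high cutoff; keeping lowest")
                        report["rule5"].append(r.chip_id)
        elif all(r.concentration < config.low_cutoff for r in chips):
            best = max(by_factor, key=lambda d: _geomean([r.concentration for r in by_factor[d]]))
            for d, group in by_factor.items():
                if d != best:
                    for r in group:
                        r.reject("rule6: all chips below low cutoff; keeping highest")
                        report["rule6"].append(r.chip_id)

    return records, report


def _geomean(values) -> float:
    return float(np.exp(np.mean(np.log(values))))


def combine_sample(
    records_kept: list[ChipRecord],
    spec: ConfidenceSpec = DEFAULT_SPEC,
    method: str = "inverse-variance",
) -> SampleResult:
    """Pool dilution-corrected concentrations of one sample's kept chips.

    Default weights are 1/σ² with σ the per-chip sampling spread of ln λ̂,
    giving the minimum-variance log-scale combination; ``method="mean"``
    uses an unweighted geometric mean.  The combined CI is propagated on
    the log scale assuming independent chips.
    """
    if not records_kept:
        raise DigitalPCRError("no kept chips to combine")
    samples = {r.sample_id for r in records_kept}
    if len(samples) != 1:
        raise DigitalPCRError(f"chips from multiple samples: {sorted(samples)}")
    logs, weights = [], []
    for r in records_kept:
        if not r.corrected_concentration or r.corrected_concentration <= 0:
            raise DigitalPCRError(f"chip {r.chip_id} has no positive concentration")
        sigma = sampling_sigma(r.lam, r.counts.n)
        logs.append(math.log(r.corrected_concentration))
        weights.append(1.0 / sigma**2 if method == "inverse-variance" else 1.0)
    logs_arr, w = np.asarray(logs), np.asarray(weights)
    mean_log = float(np.average(logs_arr, weights=w))
    if method == "inverse-variance":
        sigma_comb = 1.0 / math.sqrt(w.sum())
    else:
        sigmas = np.asarray([sampling_sigma(r.lam, r.counts.n) for r in records_kept])
        sigma_comb = float(np.sqrt(np.sum(sigmas**2)) / len(sigmas))
    z = spec.z_score
    return SampleResult(
        sample_id=records_kept[0].sample_id,
        combined_concentration=math.exp(mean_log),
        ci=(math.exp(mean_log - z * sigma_comb), math.exp(mean_log + z * sigma_comb)),
        contributing_chips=tuple(r.chip_id for r in records_kept),
    )


def fold_changes(results: list[SampleResult]) -> pd.DataFrame:
    """Ratio of each sample's concentration to the next (input order)."""
    if len(results) < 2:
        raise DigitalPCRError("fold changes need at least two samples")
    rows = [
        {
            "sample_a": a.sample_id,
            "sample_b": b.sample_id,
            "fold": a.combined_concentration / b.combined_concentration,
        }
        for a, b in zip(results, results[1:])
    ]
    return pd.DataFrame(rows)


def overall_dynamic_range(results: list[SampleResult]) -> float:
    """log10 ratio of the highest to the lowest combined concentration."""
    if len(results) < 2:
        raise DigitalPCRError("dynamic range needs at least two samples")
    concs = [r.combined_concentration for r in results]
    return math.log10(max(concs) / min(concs))


def run_pipeline(
    records: list[ChipRecord],
    config: PruningConfig = PruningConfig(),
    spec: ConfidenceSpec = DEFAULT_SPEC,
    method: str = "inverse-variance",
) -> PipelineResult:
    """Prune, combine per sample, and collect unquantifiable samples."""
    records, report = apply_pruning_rules(records, config)
    samples = list(dict.fromkeys(r.sample_id for r in records if not r.is_ntc))
    results, unquantifiable = [], []
    for sample in samples:
        chips = [
            r
            for r in records
            if r.sample_id == sample and not r.is_ntc and r.status == "kept"
        ]
        if chips:
            results.append(combine_sample(chips, spec, method))
        else:
            unquantifiable.append(sample)
    return PipelineResult(
        records=tuple(records),
        sample_results=tuple(results),
        unquantifiable=tuple(unquantifiable),
        rule_report=report,
    )


def audit_frame(records) -> pd.DataFrame:
    """Per-chip audit table: every input chip with status and fired rule."""
    return pd.DataFrame(
        {
            "sample": r.sample_id,
            "chip": r.chip_id,
            "dilution": r.dilution_factor,
            "positives": r.counts.positives,
            "lam": r.lam,
            "concentration": r.concentration,
            "corrected_concentration": r.corrected_concentration,
            "status": r.status,
            "audit": "; ".join(r.audit),
        }
        for r in records
    )
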