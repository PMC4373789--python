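"""Synthetic chip-summary generator emulating a paired-dilution experiment.

The default design mirrors a two-chip absolute-quantification study: five
samples forming a 1:6.8 dilution series (spanning 4·log10(6.8) ≈ 3.330
logs), each run undiluted and at 1:50, three replicates of the pair, plus
three no-template controls — 33 chips of 20 000 partitions at 865 pl.

The top concentration (80 000 copies/µL) is chosen so the series exercises
the pruning rules the way the reference experiment does: the top sample's
undiluted chip saturates (out of the preferred 200–2000 copies/µL range)
while its 1:50 dilution lands mid-range, and the deepest dilutions fall
out of range and are rejected.  Modest false-call rates (ε+ = 5·10⁻⁴,
ε− = 10⁻³) give NTCs a realistic handful of positives.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .noise import NoiseModel
from .simulate import SimConfig, simulate_chip

__all__ = ["FixtureDesign", "generate_fixture"]


@dataclass(frozen=True)
class FixtureDesign:
    """Study conditions for the generated chip table."""

    top_concentration: float = 80000.0  # copies/µL of the first sample
    fold: float = 6.8
    n_samples: int = 5
    pair_dilution: float = 50.0
    replicates: int = 3
    n_partitions: int = 20000
    partition_volume_ul: float = 8.65e-4
    fp_rate: float = 5e-4
    fn_rate: float = 1e-3
    volume_cv: float = 0.0
    n_ntc: int = 3


def generate_fixture(
    seed: int,
    design: FixtureDesign = FixtureDesign(),
    out: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate the full design into a chip-summary table.

    Deterministic for a given ``(seed, design)``; with the defaults the
    table has 5×2×3 + 3 = 33 rows.  When ``out`` is given the table is
    also written as CSV (byte-identical across runs).
    """
    noise = NoiseModel(fp_rate=design.fp_rate, fn_rate=design.fn_rate)
    config = SimConfig(
        n=design.n_partitions,
        mean_volume=design.partition_volume_ul,
        volume_cv=design.volume_cv,
        noise=noise,
    )
    streams = np.random.SeedSequence(seed).spawn(
        design.n_samples * 2 * design.replicates + design.n_ntc
    )
    rows = []
    k = 0
    for s in range(design.n_samples):
        sample = chr(ord("A") + s)
        conc = design.top_concentration / design.fold**s
        for factor in (1.0, design.pair_dilution):
            for rep in range(1, design.replicates + 1):
                chip = simulate_chip(
                    conc / factor, config, rng=np.random.default_rng(streams[k])
                )
                k += 1
                rows.append(
                    {
                        "sample": sample,
                        "chip": f"{sample}-d{int(factor)}-r{rep}",
                        "dilution": factor,
                        "total_partitions": design.n_partitions,
                        "positives": chip.counts.positives,
                        "partition_volume_ul": design.partition_volume_ul,
                        "is_ntc": False,
                        "flag": "green",
                    }
                )
    for i in range(1, design.n_ntc + 1):
        chip = simulate_chip(0.0, config, rng=np.random.default_rng(streams[k]))
        k += 1
        rows.append(
            {
                "sample": f"NTC{i}",
                "chip": f"NTC-{i}",
                "dilution": 1.0,
                "total_partitions": design.n_partitions,
                "positives": chip.counts.positives,
                "partition_volume_ul": design.partition_volume_ul,
                "is_ntc": True,
                "flag": "green",
            }
        )
    df = pd.DataFrame(rows)
    if out is not None:
        df.to_csv(out, index=False, float_format="%.10g")
    return df
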