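"""Monte Carlo simulation of digital PCR chips.

Chips are simulated by drawing a volume for every partition (normal around
the mean with a chosen coefficient of variation, truncated at a tiny
positive floor), loading each partition with an independent Poisson count
at rate ``C · v_i`` — equivalent to placing a Poisson total across
partitions with volume-proportional probabilities — and then flipping
calls: each true negative becomes positive with probability ε+, each true
positive becomes negative with probability ε−.

Replicate chips draw from independent child streams spawned from the
master seed, so chip ``k`` is identical regardless of how many replicates
are requested.  Monodisperse no-noise chips take an exact shortcut
(negatives ~ Binomial(n, e^{−λ}) with binomial flips), which is
distributionally identical and much faster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_SPEC,
    ConfidenceSpec,
    PartitionCounts,
    confidence_interval,
    estimate_lambda,
)
from .exceptions import DigitalPCRError, InvalidInputError
from .noise import IDEAL, NoiseModel

__all__ = [
    "SimConfig",
    "SimulatedChip",
    "EmpiricalPrecision",
    "PrecisionScan",
    "simulate_chip",
    "simulate_replicates",
    "empirical_precision",
    "precision_scan",
]

_VOLUME_FLOOR = 1e-6  # fraction of the mean volume


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one batch of replicate chips."""

    n: int = 20000
    mean_volume: float = 8.65e-4  # µL (865 pl)
    volume_cv: float = 0.0
    noise: NoiseModel = field(default_factory=NoiseModel)
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise InvalidInputError("n must be >= 1")
        if not self.mean_volume > 0:
            raise InvalidInputError("mean_volume must be positive")
        if self.volume_cv < 0:
            raise InvalidInputError("volume_cv must be nonnegative")
        if self.replicates < 1:
            raise InvalidInputError("replicates must be >= 1")


@dataclass(frozen=True)
class SimulatedChip:
    """One simulated chip: the true load and the observed (post-flip) counts."""

    true_lambda: float
    counts: PartitionCounts
    true_copies: np.ndarray | None = None


def simulate_chip(
    concentration: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    keep_copies: bool = False,
) -> SimulatedChip:
    """Simulate one chip at ``concentration`` copies/µL.

    ``rng`` defaults to a fresh generator from ``config.seed``; pass one
    explicitly to take several chips from the same stream.
    """
    if concentration < 0:
        raise InvalidInputError("concentration must be nonnegative")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    lam = concentration * config.mean_volume
    ep, em = config.noise.fp_rate, config.noise.fn_rate

    if config.volume_cv == 0.0 and not keep_copies:
        # exact shortcut: partitions are iid, negative w.p. e^{-λ}
        z_true = int(rng.binomial(n, math.exp(-lam)))
        flips_to_pos = int(rng.binomial(z_true, ep)) if ep > 0 else 0
        flips_to_neg = int(rng.binomial(n - z_true, em)) if em > 0 else 0
        z_obs = z_true - flips_to_pos + flips_to_neg
        return SimulatedChip(lam, PartitionCounts(n=n, negatives=z_obs))

    vols = rng.normal(config.mean_volume, config.volume_cv * config.mean_volume, size=n)
    np.clip(vols, _VOLUME_FLOOR * config.mean_volume, None, out=vols)
    copies = rng.poisson(concentration * vols)
    positive = copies > 0
    if ep > 0:
        positive |= ~positive & (rng.random(n) < ep)
    if em > 0:
        # re-derive true positives so ε− acts on the true class only
        true_pos = copies > 0
        positive &= ~(true_pos & (rng.random(n) < em))
    z_obs = int(n - positive.sum())
    return SimulatedChip(
        lam,
        PartitionCounts(n=n, negatives=z_obs),
        true_copies=copies if keep_copies else None,
    )


def simulate_replicates(concentration: float, config: SimConfig) -> list[SimulatedChip]:
    """Simulate ``config.replicates`` chips on independent spawned streams."""
    children = np.random.SeedSequence(config.seed).spawn(config.replicates)
    return [
        simulate_chip(concentration, config, rng=np.random.default_rng(child))
        for child in children
    ]


@dataclass(frozen=True)
class EmpiricalPrecision:
    """Monte Carlo precision summary at one true load."""

    lam: float
    empirical_precision: float
    coverage: float
    n_saturated: int
    n_used: int
    lambda_hats: np.ndarray


def empirical_precision(
    lam: float, config: SimConfig, spec: ConfidenceSpec = DEFAULT_SPEC
) -> EmpiricalPrecision:
    """Empirical precision and CI coverage across replicate chips at true λ.

    Precision is the larger deviation of the central 95% quantile band of
    λ̂ from the true λ, relative to λ; coverage is the fraction of per-chip
    analytic CIs containing the true λ.  Saturated chips (no negatives)
    are excluded and counted.
    """
    if config.replicates < 100:
        raise InvalidInputError("empirical precision needs >= 100 replicates")
    conc = lam / config.mean_volume
    chips = simulate_replicates(conc, config)
    hats, covered, saturated = [], 0, 0
    for chip in chips:
        if chip.counts.negatives == 0:
            saturated += 1
            continue
        lam_hat = estimate_lambda(chip.counts)
        hats.append(lam_hat)
        if lam_hat > 0:
            lo, hi = confidence_interval(lam_hat, chip.counts.n, spec)
            covered += lo <= lam <= hi
    if not hats:
        raise DigitalPCRError("all replicates saturated; no estimate possible")
    hats_arr = np.asarray(hats)
    lo_q, hi_q = np.quantile(hats_arr, [0.025, 0.975])
    emp_p = max(abs(lam - lo_q), abs(hi_q - lam)) / lam
    return EmpiricalPrecision(
        lam=lam,
        empirical_precision=float(emp_p),
        coverage=covered / len(hats),
        n_saturated=saturated,
        n_used=len(hats),
        lambda_hats=hats_arr,
    )


@dataclass(frozen=True)
class PrecisionScan:
    """Per-λ empirical precision table and the best-precision load."""

    table: pd.DataFrame
    argmin_lambda: float
    argmin_percent_negative: float


def precision_scan(
    lambdas, config: SimConfig, spec: ConfidenceSpec = DEFAULT_SPEC
) -> PrecisionScan:
    """Empirical precision over a λ grid; reports the precision-optimal load.

    Each grid point uses an independent seed derived from ``config.seed``
    so results are reproducible and grid-size invariant.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise InvalidInputError("λ grid must be nonempty")
    rows = []
    for i, lam in enumerate(lambdas):
        grid_seed = int(np.random.SeedSequence([config.seed, i]).generate_state(1)[0] % (2**31))
        sub = replace(config, seed=grid_seed)
        res = empirical_precision(lam, sub, spec)
        rows.append(
            {
                "lam": lam,
                "percent_negative": 100.0 * math.exp(-lam),
                "empirical_precision": res.empirical_precision,
                "coverage": res.coverage,
                "n_saturated": res.n_saturated,
            }
        )
    table = pd.DataFrame(rows)
    best = table["empirical_precision"].idxmin()
    return PrecisionScan(
        table=table,
        argmin_lambda=float(table.loc[best, "lam"]),
        argmin_percent_negative=float(table.loc[best, "percent_negative"]),
    )
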