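"""Initiation-rate calibration against measured per-transcript ribosome loads.

Measured RNA copy numbers and per-transcript ribosome counts are first scaled
globally to a cell budget (total RNA molecules, total ribosomes, active
fraction); per-gene initiation rates λ are then fitted so that the simulated
steady-state mean ribosome count matches the scaled target.  Fitting is
bisection on log λ, exploiting the empirical monotonicity of mean ribosome
load in λ, with replicate-averaged short runs followed by one full-length
refinement run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .engine import gene_seed, simulate
from .io import GeneMeasurement, SimConfig, Transcript

logger = logging.getLogger("ribojam")

__all__ = [
    "CellBudget",
    "BALANCED",
    "DENSE",
    "SPARSE",
    "SCENARIOS",
    "CalibrationTarget",
    "scale_budgets",
    "FitResult",
    "fit_initiation_rate",
    "infer_targets_from_seq",
]


@dataclass(frozen=True)
class CellBudget:
    """Global cell-budget scenario: totals of RNAs and ribosomes."""

    name: str
    total_rna: float
    total_ribosomes: float
    active_fraction: float

    def __post_init__(self) -> None:
        if self.total_rna <= 0 or self.total_ribosomes <= 0:
            raise ValueError("budget totals must be > 0")
        if not 0.0 < self.active_fraction <= 1.0:
            raise ValueError("active_fraction must be in (0,1]")

    def scaled(self, factor: float) -> "CellBudget":
        """Budget with totals scaled by ``factor`` (for reduced panels)."""
        return CellBudget(
            self.name, self.total_rna * factor, self.total_ribosomes * factor,
            self.active_fraction,
        )


#: Mid-range RNA and ribosome totals.
BALANCED = CellBudget("balanced", total_rna=26_000, total_ribosomes=187_000, active_fraction=0.85)
#: Few RNAs, many ribosomes.
DENSE = CellBudget("dense", total_rna=12_500, total_ribosomes=243_000, active_fraction=0.85)
#: Many RNAs, few ribosomes.
SPARSE = CellBudget("sparse", total_rna=60_000, total_ribosomes=131_000, active_fraction=0.70)

SCENARIOS = {b.name: b for b in (BALANCED, DENSE, SPARSE)}


@dataclass(frozen=True)
class CalibrationTarget:
    gene_id: str
    target_mean_ribosomes: float  # per active transcript copy
    scaled_copies: float  # active RNA molecules

    def __post_init__(self) -> None:
        if self.target_mean_ribosomes < 0 or self.scaled_copies < 0:
            raise ValueError(f"{self.gene_id}: negative target")


def scale_budgets(
    measurements: Sequence[GeneMeasurement], budget: CellBudget
) -> list[CalibrationTarget]:
    """Scale measured RNA copies and ribosome loads to a cell budget.

    scaled_copies_g = rna_copies_g * active_fraction_g * (total_rna / Σ rna_copies);
    per-copy ribosome targets get one global factor so that
    Σ scaled_copies_g * target_g = total_ribosomes * active_fraction.
    Relative per-gene values are preserved exactly.
    """
    total_rna_measured = sum(m.rna_copies for m in measurements)
    if total_rna_measured <= 0:
        raise ValueError("measured RNA total is zero")
    rna_factor = budget.total_rna / total_rna_measured
    copies = [m.rna_copies * m.active_fraction * rna_factor for m in measurements]
    load_total = sum(
        c * m.ribosomes_per_transcript for c, m in zip(copies, measurements)
    )
    if load_total <= 0:
        raise ValueError("measured ribosome total is zero")
    ribo_factor = budget.total_ribosomes * budget.active_fraction / load_total
    return [
        CalibrationTarget(
            gene_id=m.gene_id,
            target_mean_ribosomes=m.ribosomes_per_transcript * ribo_factor,
            scaled_copies=c,
        )
        for c, m in zip(copies, measurements)
    ]


@dataclass
class FitResult:
    gene_id: str
    initiation_rate: float
    achieved_mean_ribosomes: float
    target_mean_ribosomes: float
    converged: bool
    infeasible: bool
    n_evaluations: int


LAMBDA_FLOOR = 1e-6
LAMBDA_CEIL = 1e2


def _mean_load(transcript, config, lam, n_terminations, replicates, base_seed):
    vals = []
    for r in range(replicates):
        cfg = replace(
            config,
            initiation_rate=lam,
            monitored_terminations=n_terminations,
            seed=(base_seed + 7919 * r) % (2**31 - 1),
        )
        vals.append(
            simulate(transcript, cfg, track_profiles=False).mean_ribosomes
        )
    return float(np.mean(vals))


def fit_initiation_rate(
    transcript: Transcript,
    target_mean_ribosomes: float,
    config: SimConfig,
    *,
    tolerance: float = 0.02,
    replicates: int = 3,
    eval_terminations: int = 1000,
    max_iter: int = 40,
    seed: int | None = None,
) -> FitResult:
    """Fit λ so the simulated mean ribosome count matches the target.

    Bisection on log λ over [1e-6, 1e2] s⁻¹; each evaluation averages
    ``replicates`` short runs, and the returned λ is validated with one run
    at the configured full length.  A target above the lattice capacity, or
    above the saturation load at λ_max, is flagged infeasible.
    """
    if target_mean_ribosomes < 0:
        raise ValueError("target must be >= 0")
    base_seed = seed if seed is not None else gene_seed(config.seed, transcript.gene_id)
    gid = transcript.gene_id
    if target_mean_ribosomes == 0:
        return FitResult(gid, LAMBDA_FLOOR, 0.0, 0.0, True, False, 0)
    capacity = transcript.n_codons / config.ribosome_size
    if target_mean_ribosomes > capacity:
        return FitResult(gid, math.nan, math.nan, target_mean_ribosomes, False, True, 0)

    n_eval = 0
    lo, hi = LAMBDA_FLOOR, LAMBDA_CEIL
    f_hi = _mean_load(transcript, config, hi, eval_terminations, replicates, base_seed)
    n_eval += 1
    if f_hi < target_mean_ribosomes * (1 - tolerance):
        return FitResult(gid, math.nan, f_hi, target_mean_ribosomes, False, True, n_eval)

    lam = hi
    for _ in range(max_iter):
        lam = math.sqrt(lo * hi)
        f = _mean_load(transcript, config, lam, eval_terminations, replicates, base_seed)
        n_eval += 1
        if abs(f - target_mean_ribosomes) <= tolerance * target_mean_ribosomes:
            break
        if f < target_mean_ribosomes:
            lo = lam
        else:
            hi = lam
        if hi / lo < 1 + tolerance / 4:
            break

    final = _mean_load(
        transcript, config, lam, config.monitored_terminations, 1, base_seed + 1
    )
    n_eval += 1
    converged = abs(final - target_mean_ribosomes) <= 3 * tolerance * target_mean_ribosomes
    return FitResult(gid, lam, final, target_mean_ribosomes, converged, False, n_eval)


def infer_targets_from_seq(
    ribo_rpkm: Mapping[str, float],
    rna_rpkm: Mapping[str, float],
    orf_lengths: Mapping[str, int],
    budget: CellBudget = BALANCED,
) -> list[CalibrationTarget]:
    """Estimate calibration targets from Ribo-seq / RNA-seq RPKM tables.

    Per-gene ribosome load ∝ (ribo_rpkm / rna_rpkm) × ORF length; RNA copies
    ∝ rna_rpkm; both are then scaled to the budget exactly as measured
    loads are.
    """
    shared = sorted(set(ribo_rpkm) & set(rna_rpkm) & set(orf_lengths))
    measurements = []
    for g in shared:
        if rna_rpkm[g] <= 0:
            logger.warning("%s: zero RNA-seq RPKM; skipped", g)
            continue
        measurements.append(
            GeneMeasurement(
                gene_id=g,
                ribosomes_per_transcript=ribo_rpkm[g] / rna_rpkm[g] * orf_lengths[g],
                rna_copies=rna_rpkm[g],
                active_fraction=1.0,
            )
        )
    if not measurements:
        raise ValueError("no usable genes shared between RPKM tables")
    return scale_budgets(measurements, budget)
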