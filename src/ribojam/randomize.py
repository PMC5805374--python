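"""Null genome models and the optimality statistics built on them.

Two nulls are used to judge whether observed ribosome traffic is lower or
higher than chance: (1) shuffling the order of synonymous codons within each
gene (controls for codon order while fixing amino-acid sequence and codon
counts) and (2) permuting the 61 decoding times globally across codon
identities (controls for the overall assignment of rates).  Initiation rates
are refit per null genome to the same per-gene ribosome load before
simulating, so the nulls differ from the real genome only in codon placement
or rate assignment, not in ribosomal load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .calibration import fit_initiation_rate
from .engine import gene_seed, simulate
from .io import CodonRateTable, SimConfig, Transcript
from .stats import bh_fdr, hypergeom_tail

logger = logging.getLogger("ribojam")

__all__ = [
    "NullGenomeSpec",
    "shuffle_synonymous",
    "permute_global_rates",
    "null_panel",
    "empirical_pvalue",
    "zscore_optimality",
    "ramp_score",
    "extreme_sets_and_overlap",
    "enrichment",
]

_FORWARD = CodonTable.unambiguous_dna_by_id[1].forward_table  # standard code


def _synonym_families() -> dict[str, list[str]]:
    fam: dict[str, list[str]] = {}
    for codon, aa in _FORWARD.items():
        fam.setdefault(aa, []).append(codon)
    return fam


@dataclass(frozen=True)
class NullGenomeSpec:
    model: str  # "synonymous_shuffle" | "global_rate_permutation"
    n_genomes: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("synonymous_shuffle", "global_rate_permutation"):
            raise ValueError(f"unknown null model {self.model!r}")
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")


def shuffle_synonymous(transcript: Transcript, rng: np.random.Generator) -> Transcript:
    """Permute synonymous codon positions within the gene.

    The amino-acid sequence and the per-family codon multisets are preserved
    exactly; within each family the arrangement is uniform.  Stop codons are
    outside the lattice and never participate.
    """
    codons = list(transcript.codons)
    by_aa: dict[str, list[int]] = {}
    for i, c in enumerate(codons):
        by_aa.setdefault(_FORWARD[c], []).append(i)
    for positions in by_aa.values():
        vals = [codons[i] for i in positions]
        perm = rng.permutation(len(vals))
        for slot, j in zip(positions, perm):
            codons[slot] = vals[j]
    return replace(transcript, codons=tuple(codons), site_rates=None, termination_rate=None)


def permute_global_rates(
    rate_table: CodonRateTable, rng: np.random.Generator
) -> CodonRateTable:
    """Reassign the 61 decoding times to codons by a uniform permutation."""
    codons = list(rate_table.times)
    times = np.array([rate_table.times[c] for c in codons])
    perm = rng.permutation(len(codons))
    return CodonRateTable({c: float(times[j]) for c, j in zip(codons, perm)})


def null_panel(
    transcripts: Sequence[Transcript],
    rate_table: CodonRateTable,
    targets: Mapping[str, float],
    spec: NullGenomeSpec,
    config: SimConfig,
    statistic_fns: Mapping[str, Callable] | None = None,
    *,
    fit_kwargs: dict | None = None,
) -> list[dict[str, dict[str, float]]]:
    """Simulate ``spec.n_genomes`` null genomes matched to real ribosome loads.

    For each genome, transcripts (or the rate table) are randomized, λ is
    refit per gene to ``targets[gene]`` and the gene is simulated; the same
    summary statistics as for the real genome are recorded.  Infeasible
    refits are logged and excluded (pairwise per gene).

    Returns one dict per genome: gene_id -> {statistic: value}.
    """
    from .io import apply_rates  # local import to avoid cycles

    if statistic_fns is None:
        statistic_fns = default_statistics()
    fit_kwargs = fit_kwargs or {}
    panels = []
    for g in range(spec.n_genomes):
        rng = np.random.default_rng((spec.seed + 1000003 * g) % (2**31 - 1))
        if spec.model == "global_rate_permutation":
            table_g = permute_global_rates(rate_table, rng)
            genes = [apply_rates(t, table_g) for t in transcripts]
        else:
            genes = [apply_rates(shuffle_synonymous(t, rng), rate_table) for t in transcripts]
        genome: dict[str, dict[str, float]] = {}
        for t in genes:
            target = targets.get(t.gene_id)
            if target is None:
                continue
            fit = fit_initiation_rate(
                t, target, config,
                seed=gene_seed(config.seed + 13 * (g + 1), t.gene_id),
                **fit_kwargs,
            )
            if fit.infeasible or not np.isfinite(fit.initiation_rate):
                logger.warning("null genome %d: %s infeasible; excluded", g, t.gene_id)
                continue
            cfg = replace(
                config,
                initiation_rate=fit.initiation_rate,
                seed=gene_seed(config.seed + 13 * (g + 1) + 1, t.gene_id),
            )
            res = simulate(t, cfg)
            genome[t.gene_id] = {name: fn(res) for name, fn in statistic_fns.items()}
        panels.append(genome)
    return panels


def default_statistics() -> dict[str, Callable]:
    """Per-gene summaries recorded for real and null genomes."""
    return {
        "translation_rate": lambda r: r.translation_rate,
        "mean_delay_time": lambda r: r.mean_delay_time,
        "queue_probability": lambda r: r.queue_probability,
        "qfr": lambda r: r.qfr,
        "qfr_first100": lambda r: r.regional_qfr(1, min(100, r.n_codons)),
    }


def empirical_pvalue(observed: float, null_values, tail: str = "lower") -> float:
    """Add-one empirical p-value: (1 + #{null as-or-more extreme}) / (1 + n).

    ``tail="lower"`` asks how unusually small the observation is.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size == 0:
        raise ValueError("need at least one null value")
    if tail == "lower":
        extreme = int(np.sum(null <= observed))
    elif tail == "upper":
        extreme = int(np.sum(null >= observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (1 + extreme) / (1 + null.size)


def zscore_optimality(observed: float, null_values) -> float:
    """Sequence-optimality z-score: (observed - mean(null)) / sd(null).

    The sd uses the n-1 denominator; zero-sd nulls are flagged as NaN.
    """
    null = np.asarray(null_values, dtype=float)
    if null.size < 2:
        raise ValueError("need >= 2 null values")
    sd = null.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float((observed - null.mean()) / sd)


def ramp_score(
    queued_profile: np.ndarray,
    density_profile: np.ndarray | None = None,
    *,
    region: int = 100,
) -> float:
    """Ramp strength: QFR over the first 100 codons over QFR of the middle
    (codons 101..N-100).  Undefined (ValueError) for ORFs <= 200 codons;
    a zero middle with queueing in the ramp yields +inf as a flagged
    sentinel.
    """
    q = np.asarray(queued_profile, dtype=float)
    n = len(q)
    if n <= 2 * region:
        raise ValueError(f"ramp score needs > {2 * region} codons (got {n})")
    d = np.ones_like(q) if density_profile is None else np.asarray(density_profile, dtype=float)
    first_d, first_q = d[:region].sum(), q[:region].sum()
    mid_d, mid_q = d[region : n - region].sum(), q[region : n - region].sum()
    first = first_q / first_d if first_d > 0 else 0.0
    mid = mid_q / mid_d if mid_d > 0 else 0.0
    if mid == 0:
        return float("inf") if first > 0 else float("nan")
    return first / mid


def extreme_sets_and_overlap(
    stat_a: Mapping[str, float],
    stat_b: Mapping[str, float],
    *,
    q: float = 0.05,
    tail_a: str = "upper",
    tail_b: str = "upper",
) -> dict:
    """Extreme top/bottom-q gene sets of two statistics and their overlap.

    Returns the two sets, their intersection, and the hypergeometric tail
    p-value of the overlap on the shared gene universe.
    """
    universe = sorted(set(stat_a) & set(stat_b))
    if not universe:
        raise ValueError("disjoint gene universes")
    if len(universe) < 40:
        raise ValueError("need >= 40 shared genes")

    def extreme(stat: Mapping[str, float], tail: str) -> set[str]:
        vals = np.array([stat[g] for g in universe])
        if tail == "upper":
            thr = np.quantile(vals, 1 - q)
            return {g for g in universe if stat[g] >= thr}
        thr = np.quantile(vals, q)
        return {g for g in universe if stat[g] <= thr}

    set_a = extreme(stat_a, tail_a)
    set_b = extreme(stat_b, tail_b)
    overlap = set_a & set_b
    p = hypergeom_tail(len(overlap), len(set_a), len(set_b), len(universe))
    return {
        "set_a": set_a,
        "set_b": set_b,
        "overlap": overlap,
        "p_value": p,
        "universe_size": len(universe),
    }


def enrichment(
    gene_sets: Mapping[str, set],
    annotations: Mapping[str, set],
    universe: set,
) -> "pd.DataFrame":
    """Hypergeometric term enrichment per gene set, BH-adjusted within set."""
    import pandas as pd

    rows = []
    for set_name, genes in gene_sets.items():
        genes = set(genes) & universe
        term_rows = []
        for term, term_genes in annotations.items():
            tg = set(term_genes) & universe
            if not tg:
                continue
            k = len(genes & tg)
            p = hypergeom_tail(k, len(tg), len(genes), len(universe))
            term_rows.append(
                {"set": set_name, "term": term, "overlap": k,
                 "term_size": len(tg), "set_size": len(genes), "p": p}
            )
        if term_rows:
            q = bh_fdr([r["p"] for r in term_rows])
            for r, qv in zip(term_rows, q):
                r["q"] = float(qv)
            rows.extend(term_rows)
    return pd.DataFrame(rows)
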