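"""Synthetic yeast-like inputs with known ground truth.

Everything the package consumes can be generated here: in-frame coding
sequences with controlled codon-usage bias (optionally 5'-ramped), a
codon decoding-time table, per-gene ribosome-load measurements obtained by
actually simulating each gene at its planted initiation rate (so calibration
round-trips are exact by construction), gene feature tables, positioned
footprint reads sampled from simulated footprint densities, and sucrose
gradient traces with known component areas.

Default conditions mirror a budding-yeast cell: ORF lengths log-normal
around ~400 codons, initiation rates log-normal with median 0.09 s⁻¹
(10th/90th percentiles ≈ 0.02/0.29 s⁻¹), mean codon decoding time ≈ 0.2 s
(≈5 aa/s) with a 3–5-fold fast-to-slow spread, ~85% of RNA copies actively
translated.  The decoding-time table is synthetic: it reproduces the shape
of fitted yeast codon times, not any published per-codon values.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import SimResult, gene_seed, simulate
from .gradient import GradientProfile
from .io import (
    CodonRateTable,
    GeneFeatures,
    GeneMeasurement,
    SENSE_CODONS,
    SimConfig,
    Transcript,
    write_cds_fasta,
    write_measurements,
    write_rate_table,
)
from .profiles import OccupancyProfile
from .randomize import _FORWARD

__all__ = [
    "FixtureSpec",
    "make_rate_table",
    "make_transcriptome",
    "make_reads",
    "make_gradient",
    "save_transcriptome",
]


@dataclass
class FixtureSpec:
    """Conditions of the synthetic transcriptome."""

    n_genes: int = 200
    median_length: int = 400  # codons, log-normal
    length_sigma: float = 0.55
    min_length: int = 120
    max_length: int = 1500
    median_initiation_rate: float = 0.09  # s^-1
    initiation_sigma: float = 0.9
    median_codon_time: float = 0.18  # s; mean ≈ 0.2 s after log-normal spread
    codon_time_sigma: float = 0.4
    mean_rna_copies: float = 4.5
    rna_copies_sigma: float = 0.7
    active_fraction: float = 0.85
    ramp: bool = False  # enrich slow codons in the first `ramp_region` codons
    ramp_region: int = 100
    ramp_strength: float = 1.0
    measure_terminations: int = 2000  # run length used to measure planted loads
    seed: int = 0


def make_rate_table(spec: FixtureSpec) -> CodonRateTable:
    """Synthetic decoding-time table (seconds) over the 61 sense codons."""
    rng = np.random.default_rng(gene_seed(spec.seed, "rate_table"))
    times = np.exp(rng.normal(np.log(spec.median_codon_time), spec.codon_time_sigma, len(SENSE_CODONS)))
    times = np.clip(times, 0.04, 0.8)
    return CodonRateTable(dict(zip(SENSE_CODONS, times.astype(float))))


def _families() -> dict[str, list[str]]:
    fam: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        fam.setdefault(_FORWARD[codon], []).append(codon)
    return fam


def _gene_codons(rng, length, table, bias, spec):
    """Random CDS: uniform amino acids, codons within a family chosen with
    probability ∝ speed^bias; the 5'-ramp region flips the exponent sign."""
    fams = _families()
    aas = list(fams)
    speed = {c: 1.0 / table.times[c] for c in SENSE_CODONS}
    codons = ["ATG"]
    aa_draws = rng.choice(len(aas), size=length - 1)
    for idx, ai in enumerate(aa_draws):
        fam = fams[aas[ai]]
        pos = idx + 1
        b = bias
        if spec.ramp and pos < spec.ramp_region:
            b = -spec.ramp_strength  # prefer slow codons near the 5' end
        w = np.array([speed[c] ** b for c in fam])
        codons.append(fam[rng.choice(len(fam), p=w / w.sum())])
    return tuple(codons)


def _tai(codons, table) -> float:
    """tAI-like adaptation score: geometric mean of per-codon relative speed."""
    speeds = np.array([1.0 / table.times[c] for c in codons])
    w = speeds / speeds.max()
    return float(np.exp(np.mean(np.log(np.clip(w, 1e-9, None)))))


def make_transcriptome(
    spec: FixtureSpec,
    config: SimConfig | None = None,
) -> tuple[list[Transcript], list[GeneMeasurement], list[GeneFeatures], dict[str, float]]:
    """Generate transcripts (with rates), measurements, features and the
    planted per-gene initiation rates.

    Measured ribosome loads come from simulating each gene at its planted
    rate, so refitting those loads recovers the planted rates.
    """
    from .io import apply_rates

    rng = np.random.default_rng(gene_seed(spec.seed, "transcriptome"))
    table = make_rate_table(spec)
    config = config or SimConfig()
    lengths = np.clip(
        np.exp(rng.normal(np.log(spec.median_length), spec.length_sigma, spec.n_genes)),
        spec.min_length,
        spec.max_length,
    ).astype(int)
    lambdas = np.clip(
        np.exp(rng.normal(np.log(spec.median_initiation_rate), spec.initiation_sigma, spec.n_genes)),
        1e-3,
        2.0,
    )
    copies = np.exp(rng.normal(np.log(spec.mean_rna_copies) - spec.rna_copies_sigma**2 / 2,
                               spec.rna_copies_sigma, spec.n_genes))
    biases = rng.uniform(0.0, 2.0, spec.n_genes)

    transcripts, measurements, features = [], [], []
    planted: dict[str, float] = {}
    for i in range(spec.n_genes):
        gid = f"gene{i:04d}"
        t = Transcript(gene_id=gid, codons=_gene_codons(rng, lengths[i], table, biases[i], spec))
        t = apply_rates(t, table, config.termination_multiplier)
        cfg = replace(
            config,
            initiation_rate=float(lambdas[i]),
            monitored_terminations=spec.measure_terminations,
            seed=gene_seed(spec.seed, gid),
        )
        res = simulate(t, cfg, track_profiles=False)
        planted[gid] = float(lambdas[i])
        measurements.append(
            GeneMeasurement(
                gene_id=gid,
                ribosomes_per_transcript=res.mean_ribosomes,
                rna_copies=float(copies[i]),
                active_fraction=spec.active_fraction,
            )
        )
        pa = res.translation_rate * copies[i] * np.exp(rng.normal(0.0, 0.3))
        features.append(
            GeneFeatures(
                gene_id=gid,
                tai=_tai(t.codons, table),
                protein_abundance=float(pa),
                rna_copies=float(copies[i]),
                orf_length=int(lengths[i]),
                initiation_rate=float(lambdas[i]),
            )
        )
        transcripts.append(t)
    return transcripts, measurements, features, planted


def make_reads(
    sim_results: Sequence[SimResult],
    copies: dict[str, float],
    depth: int,
    footprint_class: str = "mRPF",
    *,
    spacing: int = 0,
    seed: int = 0,
) -> list[OccupancyProfile]:
    """Sample positioned footprint reads from simulated footprint densities.

    Reads are drawn multinomially across all gene positions with probability
    proportional to the time-averaged footprint density (monosomes for mRPF,
    disomes anchored at the upstream ribosome for dRPF) weighted by active
    RNA copies, until the requested depth is reached.
    """
    k_idx = {"mRPF": 0, "dRPF": 1}[footprint_class]
    rng = np.random.default_rng(seed)
    weights, slices, gene_ids, lengths = [], [], [], []
    start = 0
    for res in sim_results:
        fp = res.footprint_profiles[spacing]
        dens = fp[k_idx] if k_idx < fp.shape[0] else np.zeros(res.n_codons)
        w = dens * copies.get(res.gene_id, 0.0)
        weights.append(w)
        slices.append((start, start + len(w)))
        gene_ids.append(res.gene_id)
        lengths.append(len(w))
        start += len(w)
    flat = np.concatenate(weights) if weights else np.array([])
    total = flat.sum()
    if depth > 0 and total <= 0:
        raise ValueError("zero total footprint density")
    counts = (
        rng.multinomial(depth, flat / total) if depth > 0 else np.zeros(len(flat), dtype=int)
    )
    return [
        OccupancyProfile(g, footprint_class, counts[a:b].astype(float))
        for g, (a, b) in zip(gene_ids, slices)
    ]


def read_lengths_for_class(footprint_class: str, n: int, rng: np.random.Generator) -> np.ndarray:
    """Read lengths consistent with the footprint class (nt)."""
    if footprint_class == "mRPF":
        return rng.integers(28, 31, n)
    return rng.integers(57, 64, n)


def make_gradient(
    means: Sequence[float],
    sds: Sequence[float],
    weights: Sequence[float],
    *,
    noise_sd: float = 0.0,
    n_points: int = 400,
    x_range: tuple[float, float] | None = None,
    seed: int = 0,
) -> tuple[GradientProfile, dict]:
    """Sum-of-Gaussians absorbance trace with the true area ratio recorded.

    Component order is (mRPF, dRPF, ...); the ground truth carries
    ``true_ratio`` = weight(dRPF)/weight(mRPF) and the component parameters.
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if len(means) < 2:
        raise ValueError("need >= 2 components")
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)
    if x_range is None:
        x_range = (means.min() - 4 * sds.max(), means.max() + 4 * sds.max())
    x = np.linspace(*x_range, n_points)
    a = np.zeros_like(x)
    for m, s, w in zip(means, sds, weights):
        a += w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
    if noise_sd > 0:
        a = np.clip(a + rng.normal(0.0, noise_sd * a.max(), len(a)), 0.0, None)
    truth = {
        "true_ratio": float(weights[1] / weights[0]),
        "means": means.tolist(),
        "sds": sds.tolist(),
        "weights": weights.tolist(),
    }
    return GradientProfile(x=x, absorbance=a), truth


def save_transcriptome(
    out_dir: str | Path,
    transcripts: Sequence[Transcript],
    measurements: Sequence[GeneMeasurement],
    features: Sequence[GeneFeatures],
    planted: dict[str, float],
    rate_table: CodonRateTable,
) -> None:
    """Write fixture inputs plus their ground truth as plain-text tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_cds_fasta(transcripts, out / "cds.fa")
    write_rate_table(rate_table, out / "rates.tsv")
    write_measurements(measurements, out / "measurements.tsv")
    pd.DataFrame(
        [
            {
                "gene_id": f.gene_id,
                "tai": f.tai,
                "protein_abundance": f.protein_abundance,
                "rna_copies": f.rna_copies,
                "orf_length": f.orf_length,
                "initiation_rate": f.initiation_rate,
            }
            for f in features
        ]
    ).to_csv(out / "features.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"gene_id": list(planted), "planted_initiation_rate": list(planted.values())}
    ).to_csv(out / "ground_truth.tsv", sep="\t", index=False)
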