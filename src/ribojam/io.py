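"""Domain types and readers/writers shared by all modules.

Coding sequences are handled as codon-site lattices: position 1 is the first
sense codon of the ORF, the trailing stop codon is not part of the lattice
(termination is the jump out of the last site).  Codon positions are 1-based
throughout the public API; nucleotide coordinates, where they appear, are
0-based half-open and converted at I/O boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("ribojam")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons of the standard nuclear code, lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)


@dataclass
class Transcript:
    """A CDS as a codon lattice with optional per-site elongation rates.

    ``site_rates[i]`` is the elongation (jump) rate out of codon site ``i+1``
    in events/second; the jump out of the last site is termination and uses
    ``termination_rate``.
    """

    gene_id: str
    codons: tuple[str, ...]
    site_rates: np.ndarray | None = None
    termination_rate: float | None = None

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError(f"{self.gene_id}: empty codon list")
        if self.site_rates is not None:
            self.site_rates = np.asarray(self.site_rates, dtype=float)
            if self.site_rates.shape != (len(self.codons),):
                raise ValueError(f"{self.gene_id}: site_rates length mismatch")
            if not np.all(self.site_rates > 0):
                raise ValueError(f"{self.gene_id}: non-positive site rate")
        if self.termination_rate is not None and not self.termination_rate > 0:
            raise ValueError(f"{self.gene_id}: termination_rate must be > 0")

    @property
    def n_codons(self) -> int:
        return len(self.codons)

    @property
    def has_rates(self) -> bool:
        return self.site_rates is not None and self.termination_rate is not None


@dataclass(frozen=True)
class CodonRateTable:
    """Mean decoding time per sense codon, seconds."""

    times: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.times)
        extra = set(self.times) - set(SENSE_CODONS)
        if missing or extra:
            raise ValueError(
                "rate table must cover exactly the 61 sense codons "
                f"(missing {sorted(missing)[:3]}, extra {sorted(extra)[:3]})"
            )
        if any(t <= 0 for t in self.times.values()):
            raise ValueError("all decoding times must be > 0")

    @property
    def fastest_rate(self) -> float:
        """Rate (1/time) of the fastest codon in the table."""
        return 1.0 / min(self.times.values())

    def rate(self, codon: str) -> float:
        return 1.0 / self.times[codon]


@dataclass
class SimConfig:
    """Simulation knobs.

    ribosome_size
        Footprint length L in codons (even); two A-sites must be >= L apart.
    initiation_rate
        λ, initiation attempt rate in events/second.
    spacing
        Maximal number of free codons joining two ribosomes into one
        footprint; profiles are tracked for every spacing in
        ``0..spacing``.
    termination_multiplier
        Termination rate relative to the fastest codon's decoding rate.
    """

    ribosome_size: int = 10
    initiation_rate: float = 0.1
    warmup_terminations: int = 100
    monitored_terminations: int = 10_000
    spacing: int = 0
    seed: int = 0
    termination_multiplier: float = 1.0
    max_events: int = 1_000_000_000
    utr_default_nt: int = 500  # recorded for completeness; UTRs are not modelled

    def __post_init__(self) -> None:
        if self.ribosome_size < 2 or self.ribosome_size % 2:
            raise ValueError("ribosome_size must be even and >= 2")
        if not self.initiation_rate > 0:
            raise ValueError("initiation_rate must be > 0")
        if self.spacing < 0 or self.spacing > 4:
            raise ValueError("spacing must be in 0..4")
        if self.warmup_terminations < 1 or self.monitored_terminations < 1:
            raise ValueError("termination counts must be >= 1")


@dataclass(frozen=True)
class GeneMeasurement:
    """Measured ribosome association of one transcript species."""

    gene_id: str
    ribosomes_per_transcript: float
    rna_copies: float
    active_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.ribosomes_per_transcript < 0 or self.rna_copies < 0:
            raise ValueError(f"{self.gene_id}: negative measurement")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError(f"{self.gene_id}: active_fraction outside [0,1]")


@dataclass(frozen=True)
class GeneFeatures:
    """Expression/translation features of a gene used in correlation analyses."""

    gene_id: str
    tai: float
    protein_abundance: float
    rna_copies: float
    orf_length: int
    initiation_rate: float | None = None

    def __post_init__(self) -> None:
        if self.orf_length < 1:
            raise ValueError(f"{self.gene_id}: orf_length must be >= 1")
        if not 0.0 < self.tai <= 1.0:
            raise ValueError(f"{self.gene_id}: tAI outside (0,1]")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_cds_fasta(path: str | Path) -> list[Transcript]:
    """Read in-frame coding sequences into codon lattices (rates unset).

    Records whose length is not a multiple of 3, or that contain ambiguous
    nucleotides or an internal stop codon, are rejected with a logged
    warning.  A trailing stop codon is trimmed.
    """
    transcripts: list[Transcript] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper().replace("U", "T")
        if len(seq) % 3:
            logger.warning("%s: length %d not a multiple of 3; rejected", record.id, len(seq))
            continue
        if set(seq) - set("ACGT"):
            logger.warning("%s: ambiguous nucleotides; rejected", record.id)
            continue
        codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
        if codons and codons[-1] in STOP_CODONS:
            codons = codons[:-1]
        if not codons:
            logger.warning("%s: no sense codons; rejected", record.id)
            continue
        if any(c in STOP_CODONS for c in codons):
            logger.warning("%s: internal stop codon; rejected", record.id)
            continue
        transcripts.append(Transcript(gene_id=record.id, codons=tuple(codons)))
    return transcripts


def write_cds_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            fh.write(f">{t.gene_id}\n{''.join(t.codons)}\n")


# ---------------------------------------------------------------------------
# Rate table
# ---------------------------------------------------------------------------

def read_rate_table(path: str | Path) -> CodonRateTable:
    """Read a two-column TSV (codon, time_s) into a :class:`CodonRateTable`."""
    df = pd.read_csv(path, sep="\t")
    if not {"codon", "time_s"} <= set(df.columns):
        raise ValueError("rate table must have columns 'codon' and 'time_s'")
    return CodonRateTable(dict(zip(df["codon"].str.upper(), df["time_s"].astype(float))))


def write_rate_table(table: CodonRateTable, path: str | Path) -> None:
    pd.DataFrame(
        {"codon": list(table.times), "time_s": list(table.times.values())}
    ).to_csv(path, sep="\t", index=False)


def apply_rates(
    transcript: Transcript,
    rate_table: CodonRateTable,
    termination_multiplier: float = 1.0,
) -> Transcript:
    """Attach per-site elongation rates λ_i = 1/t_i and the termination rate.

    The termination rate is ``termination_multiplier`` times the rate of the
    fastest codon in the table.  Idempotent and independent of gene order.
    """
    try:
        rates = np.array([rate_table.rate(c) for c in transcript.codons])
    except KeyError as exc:
        raise KeyError(
            f"{transcript.gene_id}: codon {exc.args[0]} missing from rate table"
        ) from None
    return replace(
        transcript,
        site_rates=rates,
        termination_rate=termination_multiplier * rate_table.fastest_rate,
    )


# ---------------------------------------------------------------------------
# Measurements / features / traffic tables
# ---------------------------------------------------------------------------

def read_measurements(path: str | Path) -> list[GeneMeasurement]:
    df = pd.read_csv(path, sep="\t")
    return [
        GeneMeasurement(
            gene_id=str(r.gene_id),
            ribosomes_per_transcript=float(r.ribosomes_per_transcript),
            rna_copies=float(r.rna_copies),
            active_fraction=float(getattr(r, "active_fraction", 1.0)),
        )
        for r in df.itertuples(index=False)
    ]


def write_measurements(measurements: Iterable[GeneMeasurement], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "gene_id": m.gene_id,
                "ribosomes_per_transcript": m.ribosomes_per_transcript,
                "rna_copies": m.rna_copies,
                "active_fraction": m.active_fraction,
            }
            for m in measurements
        ]
    ).to_csv(path, sep="\t", index=False)


TRAFFIC_COLUMNS = (
    "gene_id",
    "initiation_rate",
    "mean_ribosomes",
    "translation_rate",
    "translation_time",
    "delay_time",
    "qfr",
    "ramp_score",
)


def write_traffic_table(results: Sequence[Mapping[str, float]], path: str | Path) -> None:
    """Write the per-gene traffic summary table (one row per gene).

    ``results`` rows must carry the keys in :data:`TRAFFIC_COLUMNS`.
    """
    df = pd.DataFrame(list(results), columns=list(TRAFFIC_COLUMNS))
    df.to_csv(path, sep="\t", index=False)


def read_traffic_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bedgraph(gene_id: str, values: np.ndarray, path: str | Path) -> None:
    """Write a per-codon profile as transcript-space bedGraph.

    Codon i (1-based) maps to the 0-based half-open nucleotide interval
    [3(i-1), 3i) on the transcript; zero-valued codons are skipped, runs of
    equal values are merged.
    """
    values = np.asarray(values, dtype=float)
    with open(path, "w") as fh:
        start = None
        current = 0.0
        for i, v in enumerate(values):
            if start is not None and v != current:
                if current != 0.0:
                    fh.write(f"{gene_id}\t{3 * start}\t{3 * i}\t{current:.6g}\n")
                start = None
            if start is None and v != 0.0:
                start, current = i, v
            elif start is None:
                current = 0.0
        if start is not None and current != 0.0:
            fh.write(f"{gene_id}\t{3 * start}\t{3 * len(values)}\t{current:.6g}\n")


def read_bedgraph(path: str | Path) -> dict[str, list[tuple[int, int, float]]]:
    """Read a bedGraph into {name: [(start, stop, value), ...]} (0-based)."""
    out: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "#")):
                continue
            name, start, stop, value = line.split("\t")
            out.setdefault(name, []).append((int(start), int(stop), float(value)))
    return out


def load_config(path: str | Path) -> SimConfig:
    """Load a YAML/JSON document into a :class:`SimConfig`."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return SimConfig(**data)
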