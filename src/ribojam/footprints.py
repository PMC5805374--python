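"""Grouping of ribosomes into footprints and the transcriptome RPF census.

Two ribosomes whose A-sites are ``gap = j - i - L`` free codons apart belong
to the same footprint when ``gap <= s``, the maximal allowed spacing; at
s = 0 directly adjacent ribosomes (no free codons between their footprints)
already pair.  A footprint of k ribosomes is positioned at its 5'-most
ribosome.  The census counts, transcriptome-wide and weighted by active RNA
copies, the time-averaged number of *ribosomes* residing in footprints of
each size; the dRPF:mRPF ratio is counts[2]/counts[1] in this
ribosome-count convention (a pair contributes two ribosomes).  The
footprint-count convention (counts[2]/2 pairs per isolated ribosome) is also
exposed for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "assign_footprints",
    "RpfCensus",
    "census",
    "ratio_drpf_mrpf",
    "missing_fraction",
]


def assign_footprints(
    a_site_positions: Sequence[int], L: int, s: int
) -> list[tuple[int, int]]:
    """Group sorted A-site positions into footprints at spacing ``s``.

    Returns a list of (size k, 5'-most position) per footprint.
    """
    positions = list(a_site_positions)
    if any(b < a for a, b in zip(positions, positions[1:])):
        raise ValueError("positions must be sorted ascending")
    if any(b - a < L for a, b in zip(positions, positions[1:])):
        raise ValueError("positions violate exclusion (gap < L)")
    out: list[tuple[int, int]] = []
    i = 0
    n = len(positions)
    while i < n:
        j = i
        while j + 1 < n and positions[j + 1] - positions[j] - L <= s:
            j += 1
        out.append((j - i + 1, positions[i]))
        i = j + 1
    return out


@dataclass
class RpfCensus:
    """Time-averaged ribosome counts by footprint multiplicity at one spacing."""

    spacing: int
    counts: dict[int, float]
    per_gene: dict[str, dict[int, float]] | None = None

    @property
    def total_ribosomes(self) -> float:
        return float(sum(self.counts.values()))


def census(
    sim_results: Sequence,
    copies: Mapping[str, float],
    s: int,
    *,
    keep_per_gene: bool = False,
) -> RpfCensus:
    """Transcriptome RPF census at spacing ``s``.

    Each gene's time-averaged footprint-state profiles m_i^k are weighted by
    its active RNA copy number; ``counts[k]`` is k times the mean number of
    size-k footprints (i.e. the number of ribosomes inside size-k
    footprints).
    """
    counts: dict[int, float] = {}
    per_gene: dict[str, dict[int, float]] = {}
    for res in sim_results:
        if s not in res.footprint_profiles:
            raise KeyError(
                f"{res.gene_id}: spacing {s} not simulated "
                f"(available: {sorted(res.footprint_profiles)})"
            )
        w = float(copies.get(res.gene_id, 0.0))
        fp = res.footprint_profiles[s]  # (kmax, N)
        gene_counts: dict[int, float] = {}
        for k_idx in range(fp.shape[0]):
            mean_fp = float(fp[k_idx].sum())  # mean number of size-(k_idx+1) footprints
            if mean_fp > 0:
                k = k_idx + 1
                gene_counts[k] = k * mean_fp
                counts[k] = counts.get(k, 0.0) + w * k * mean_fp
        if keep_per_gene:
            per_gene[res.gene_id] = gene_counts
    return RpfCensus(spacing=s, counts=counts, per_gene=per_gene or None)


def ratio_drpf_mrpf(census_: RpfCensus, *, convention: str = "ribosome") -> float:
    """dRPF:mRPF ratio.

    ``convention="ribosome"`` divides ribosomes-in-pairs by isolated
    ribosomes (counts[2]/counts[1]); ``"footprint"`` divides the number of
    disome footprints by the number of monosome footprints.
    """
    mono = census_.counts.get(1, 0.0)
    di = census_.counts.get(2, 0.0)
    if mono <= 0:
        raise ValueError("no isolated ribosomes in census; ratio undefined")
    if convention == "ribosome":
        return di / mono
    if convention == "footprint":
        return (di / 2.0) / mono
    raise ValueError(f"unknown convention {convention!r}")


def missing_fraction(census_: RpfCensus) -> float:
    """Fraction of ribosomes that are not isolated (k >= 2), hence invisible
    to monosome-only footprint sequencing."""
    total = census_.total_ribosomes
    if total <= 0:
        raise ValueError("empty census")
    paired = sum(v for k, v in census_.counts.items() if k >= 2)
    return paired / total
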