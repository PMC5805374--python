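"""Downstream analysis of positioned footprint reads.

Works on per-gene, per-codon occupancy profiles for two footprint classes:
monosome (mRPF) and disome (dRPF) footprints, the dRPF being anchored at the
decoding site of its 5'-proximal ribosome.  Provides A/P-site offset
detection, multimapped-read redistribution, RPKM and per-gene normalized
footprint counts (NFC), metagene analysis with an empirical re-anchoring
background, pause-peak calling, exact read downsampling, the missing-mRPF
rule, and partial-correlation feature analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import partial_spearman

logger = logging.getLogger("ribojam")

__all__ = [
    "OccupancyProfile",
    "MetageneResult",
    "detect_offset",
    "redistribute_multimapped",
    "rpkm",
    "nfc",
    "call_peaks",
    "metagene",
    "downsample",
    "missing_mrpf",
    "feature_correlations",
]


@dataclass
class OccupancyProfile:
    """Per-codon weighted read counts of one gene and one footprint class."""

    gene_id: str
    footprint_class: str  # "mRPF" | "dRPF"
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError(f"{self.gene_id}: counts must be 1-D")
        if np.any(self.counts < 0):
            raise ValueError(f"{self.gene_id}: negative counts")

    @property
    def n_codons(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def detect_offset(
    five_prime_metagene: Mapping[int, float] | pd.Series,
    *,
    window: tuple[int, int] = (5, 20),
    fallback: int | None = None,
) -> int | None:
    """Distance from read 5' end to the decoding site, for one read length.

    ``five_prime_metagene`` maps the signed position of read 5' ends relative
    to the start codon (negative = upstream) to counts.  If the global
    maximum lies ``window[0]..window[1]`` nt upstream of the start and no
    position outside that range ties or exceeds it, that distance is the
    offset; otherwise the read length is discarded (returns ``fallback``,
    which is None unless a dataset-level default — 15 nt in hard cases — is
    enabled).
    """
    series = pd.Series(dict(five_prime_metagene)).sort_index()
    if series.empty or series.max() <= 0:
        return fallback
    peak_pos = int(series.idxmax())
    lo, hi = -window[1], -window[0]
    if not lo <= peak_pos <= hi:
        return fallback
    peak_val = series.loc[peak_pos]
    outside = series[(series.index < lo) | (series.index > hi)]
    if len(outside) and outside.max() >= peak_val:
        return fallback
    return -peak_pos


def redistribute_multimapped(
    candidates: Sequence[tuple[str, int]],
    unique_profiles: Mapping[str, np.ndarray],
    *,
    window: int = 100,
) -> list[tuple[str, int, float]]:
    """Split one multimapped read across its M best alignments.

    Each candidate (gene, position) receives weight proportional to the
    unique-read count density RCD in a ``window``-wide window centred on the
    position; if every window is empty, the read splits uniformly.  Weights
    sum to 1 exactly.
    """
    if not candidates:
        return []
    half = window // 2
    rcd = []
    for gene, pos in candidates:
        prof = np.asarray(unique_profiles.get(gene, np.zeros(1)), dtype=float)
        lo = max(0, pos - half)
        hi = min(len(prof), pos + half + 1)
        rcd.append(float(prof[lo:hi].sum()) if hi > lo else 0.0)
    total = sum(rcd)
    if total <= 0:
        w = 1.0 / len(candidates)
        return [(g, p, w) for g, p in candidates]
    return [(g, p, r / total) for (g, p), r in zip(candidates, rcd)]


def rpkm(profile: OccupancyProfile, total_mapped_reads: float) -> float:
    """Reads per kilobase of ORF per million mapped reads."""
    if profile.n_codons == 0:
        raise ValueError("zero-length profile")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be > 0")
    kb = profile.n_codons * 3 / 1000.0
    return profile.total / (kb * total_mapped_reads / 1e6)


def nfc(profile: OccupancyProfile) -> np.ndarray | None:
    """Normalized footprint counts: per-position counts over the gene mean.

    Returns None (with a warning) for an all-zero profile.
    """
    mean = profile.counts.mean()
    if mean <= 0:
        logger.warning("%s: all-zero profile excluded from NFC", profile.gene_id)
        return None
    return profile.counts / mean


def call_peaks(profile: OccupancyProfile, k: float = 5.0) -> np.ndarray:
    """Pause peaks: positions >= mean + k*SD of the gene's nonzero counts.

    Mean and SD are computed over positions with at least one read, matching
    the convention that empty positions are ignored.  Returns 0-based codon
    positions; fewer than two nonzero positions yields no peaks.
    """
    counts = profile.counts
    nz = counts[counts > 0]
    if len(nz) < 2:
        logger.warning("%s: <2 nonzero positions, no peaks called", profile.gene_id)
        return np.array([], dtype=int)
    sd = nz.std(ddof=0)
    if sd == 0:  # flat coverage: no position can stand above the rest
        return np.array([], dtype=int)
    threshold = nz.mean() + k * sd
    return np.flatnonzero(counts >= threshold)


@dataclass
class MetageneResult:
    """Anchored metagene with an empirical re-anchoring background."""

    positions: np.ndarray  # relative positions
    mean_nfc: np.ndarray  # mean NFC per relative position across anchors
    observed_median: float  # median over anchors of window-mean NFC
    null_band: tuple[float, float]  # 2.5/97.5 percentiles of null medians
    background_ratio: float  # observed_median / median(null medians)
    p_value: float  # empirical one-sided enrichment p
    n_anchors: int


def _window_matrix(nfc_profiles, anchors, upstream, downstream):
    rows = []
    used = 0
    for gene, pos in anchors:
        prof = nfc_profiles.get(gene)
        if prof is None:
            continue
        lo, hi = pos - upstream, pos + downstream + 1
        if lo < 0 or hi > len(prof):
            continue  # window exceeds ORF bounds: anchor skipped
        rows.append(prof[lo:hi])
        used += 1
    if not rows:
        return None
    return np.vstack(rows)


def metagene(
    nfc_profiles: Mapping[str, np.ndarray],
    anchors: Sequence[tuple[str, int]],
    *,
    window: tuple[int, int] = (30, 30),
    n_resamples: int = 1000,
    seed: int = 0,
) -> MetageneResult:
    """Metagene analysis around anchor positions with an empirical null.

    The observed statistic is the median over anchors of the window-mean NFC.
    The null re-anchors the same number of windows at uniformly random valid
    positions of the same genes, ``n_resamples`` times, recording each
    resample's median; BR is the observed median over the median of null
    medians and the p-value is the add-one empirical tail.
    """
    if not anchors:
        raise ValueError("empty anchor set")
    upstream, downstream = window
    mat = _window_matrix(nfc_profiles, anchors, upstream, downstream)
    if mat is None:
        raise ValueError("no anchor window fits inside its ORF")
    observed_median = float(np.median(mat.mean(axis=1)))

    rng = np.random.default_rng(seed)
    genes = [g for g, _ in anchors if g in nfc_profiles]
    null_medians = np.empty(n_resamples)
    # Pre-extract valid position ranges per anchor gene.
    ranges = []
    for g in genes:
        n = len(nfc_profiles[g])
        lo, hi = upstream, n - downstream - 1
        if hi >= lo:
            ranges.append((g, lo, hi))
    if not ranges:
        raise ValueError("no gene long enough for the requested window")
    for i in range(n_resamples):
        means = np.empty(len(ranges))
        for j, (g, lo, hi) in enumerate(ranges):
            pos = int(rng.integers(lo, hi + 1))
            prof = nfc_profiles[g]
            means[j] = prof[pos - upstream : pos + downstream + 1].mean()
        null_medians[i] = np.median(means)

    band = (
        float(np.percentile(null_medians, 2.5)),
        float(np.percentile(null_medians, 97.5)),
    )
    null_mid = float(np.median(null_medians))
    br = observed_median / null_mid if null_mid > 0 else float("inf")
    p = (1 + int(np.sum(null_medians >= observed_median))) / (1 + n_resamples)
    return MetageneResult(
        positions=np.arange(-upstream, downstream + 1),
        mean_nfc=mat.mean(axis=0),
        observed_median=observed_median,
        null_band=band,
        background_ratio=float(br),
        p_value=float(p),
        n_anchors=mat.shape[0],
    )


def downsample(
    profiles: Sequence[OccupancyProfile], target_total: int, seed: int = 0
) -> list[OccupancyProfile]:
    """Sample reads without replacement down to an exact total.

    Counts must be integers; reads are drawn multivariate-hypergeometrically
    over all positions of all profiles, so expected per-position counts scale
    by target/total and the returned totals match the target exactly.
    """
    counts = [np.round(p.counts).astype(np.int64) for p in profiles]
    flat = np.concatenate(counts) if counts else np.array([], dtype=np.int64)
    total = int(flat.sum())
    if target_total > total:
        raise ValueError(f"target {target_total} exceeds available reads {total}")
    rng = np.random.default_rng(seed)
    if target_total == total:
        sampled = flat
    else:
        sampled = rng.multivariate_hypergeometric(flat, target_total, method="marginals")
    out = []
    start = 0
    for p, c in zip(profiles, counts):
        stop = start + len(c)
        out.append(
            OccupancyProfile(p.gene_id, p.footprint_class, sampled[start:stop].astype(float))
        )
        start = stop
    return out


def missing_mrpf(
    mrpf: OccupancyProfile,
    drpf: OccupancyProfile,
    *,
    q_low: float = 0.10,
    q_high: float = 0.10,
    coverage_min: float = 0.10,
    region: int = 100,
) -> tuple[np.ndarray, dict[str, float]] | None:
    """Positions where monosome footprints are conspicuously missing.

    A position is flagged when its mRPF count is in the bottom ``q_low`` of
    the gene (the fraction of positions with a count <= its own is at most
    ``q_low``) while its dRPF count is in the top ``q_high`` (the fraction
    of positions with a count >= its own is at most ``q_high``).  This
    empirical-CDF rule is deterministic under ties: a value shared by more
    than ``q`` of the gene is never "extreme".  Genes with dRPF coverage
    (fraction of codons with >= 1 dRPF read) below ``coverage_min`` are
    excluded (returns None).  Also reports the flagged fraction in the first
    ``region`` codons, the last ``region`` codons and the middle.
    """
    if mrpf.n_codons != drpf.n_codons:
        raise ValueError("mRPF and dRPF profiles must have equal length")
    n = drpf.n_codons
    coverage = float(np.count_nonzero(drpf.counts)) / n
    if coverage < coverage_min:
        return None
    m = mrpf.counts
    d = drpf.counts
    frac_leq_m = np.searchsorted(np.sort(m), m, side="right") / n
    frac_geq_d = 1.0 - np.searchsorted(np.sort(d), d, side="left") / n
    flagged = (frac_leq_m <= q_low) & (frac_geq_d <= q_high)
    positions = np.flatnonzero(flagged)

    first = slice(0, min(region, n))
    last = slice(max(0, n - region), n)
    mid = slice(min(region, n), max(0, n - region))
    if n < 2 * region:
        logger.info("%s: shorter than %d codons, regions truncated", mrpf.gene_id, 2 * region)

    def frac(sl: slice) -> float:
        length = sl.stop - sl.start
        return float(flagged[sl].sum()) / length if length > 0 else float("nan")

    fractions = {
        "all": float(flagged.sum()) / n,
        "first": frac(first),
        "middle": frac(mid),
        "last": frac(last),
    }
    return positions, fractions


def feature_correlations(
    per_gene_stat: Mapping[str, float],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Partial Spearman correlation of a per-gene statistic with each feature.

    ``features`` is indexed by gene with one column per feature; for each
    feature the partial correlation controls for all remaining features.
    Constant features are dropped with a warning; complete cases only.
    """
    stat = pd.Series(per_gene_stat, dtype=float)
    df = features.join(stat.rename("__stat__"), how="inner").dropna()
    if len(df) < 10:
        raise ValueError(f"need >= 10 complete cases, have {len(df)}")
    cols = [c for c in features.columns]
    keep = []
    for c in cols:
        if df[c].nunique() <= 1:
            logger.warning("feature %s is constant; dropped", c)
        else:
            keep.append(c)
    rows = []
    for c in keep:
        controls = df[[k for k in keep if k != c]].to_numpy()
        rho, p = partial_spearman(df["__stat__"].to_numpy(), df[c].to_numpy(), controls)
        rows.append({"feature": c, "rho": rho, "p": p, "n": len(df)})
    return pd.DataFrame(rows).set_index("feature")
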