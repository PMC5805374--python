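"""End-to-end orchestration: calibrate → simulate → census → traffic table.

All intermediates are plain-text files; a manifest (config hash, seeds, input
checksums, per-stage status) accompanies every run so that a rerun with the
same manifest reproduces stochastic outputs bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import SCENARIOS, fit_initiation_rate, scale_budgets
from .engine import gene_seed, simulate
from .footprints import census, missing_fraction, ratio_drpf_mrpf
from .io import (
    SimConfig,
    apply_rates,
    read_cds_fasta,
    read_measurements,
    read_rate_table,
    write_traffic_table,
)
from .randomize import ramp_score

logger = logging.getLogger("ribojam")


def simulate_calibrated_panel(
    transcripts,
    measurements,
    *,
    config: SimConfig,
    budget=None,
    fit_kwargs: dict | None = None,
):
    """Calibrate λ per gene against (budget-scaled) measured loads, simulate
    each gene at its fitted rate, and return (results, fits, copies).

    ``budget`` is a :class:`~ribojam.calibration.CellBudget`; None keeps the
    measured loads unscaled.  Infeasible genes are dropped.
    """
    from .calibration import CellBudget

    if budget is None:
        total_rna = sum(m.rna_copies for m in measurements)
        total_rib = sum(
            m.rna_copies * m.active_fraction * m.ribosomes_per_transcript
            for m in measurements
        )
        budget = CellBudget("measured", total_rna, max(total_rib, 1e-9), 1.0)
        # identity scaling up to the active fraction folded into copies
    targets = scale_budgets(measurements, budget)
    by_id = {t.gene_id: t for t in transcripts}
    results, fits, copies = [], [], {}
    for target in targets:
        t = by_id.get(target.gene_id)
        if t is None:
            continue
        fit = fit_initiation_rate(
            t, target.target_mean_ribosomes, config, **(fit_kwargs or {})
        )
        if fit.infeasible or not np.isfinite(fit.initiation_rate):
            logger.warning("%s: infeasible target %.3g; dropped",
                           target.gene_id, target.target_mean_ribosomes)
            continue
        cfg = replace(config, initiation_rate=fit.initiation_rate,
                      seed=gene_seed(config.seed, target.gene_id))
        results.append(simulate(t, cfg))
        fits.append(fit)
        copies[target.gene_id] = target.scaled_copies
    return results, fits, copies


def panel_traffic_summary(results, copies):
    """Transcriptome-level queue statistics of a simulated panel.

    Gene-level medians (queue probability, QFR, delay time) plus the
    copy-weighted global delayed fraction and regional QFR medians over
    genes longer than 200 codons.
    """
    qp = np.array([r.queue_probability for r in results])
    qfr = np.array([r.qfr for r in results])
    delay = np.array([r.mean_delay_time for r in results])
    w = np.array([copies.get(r.gene_id, 0.0) for r in results])
    queued_mass = np.array([r.queued_profile.sum() for r in results])
    dens_mass = np.array([r.density_profile.sum() for r in results])
    global_delayed = float((w * queued_mass).sum() / (w * dens_mass).sum())
    first, mid, last = [], [], []
    for r in results:
        n = r.n_codons
        if n <= 200:
            continue
        first.append(r.regional_qfr(1, 100))
        mid.append(r.regional_qfr(101, n - 100))
        last.append(r.regional_qfr(n - 99, n))
    return {
        "median_queue_probability": float(np.median(qp)),
        "median_qfr": float(np.median(qfr)),
        "median_delay_time_s": float(np.median(delay)),
        "global_delayed_fraction": global_delayed,
        "median_regional_qfr_first100": float(np.median(first)) if first else float("nan"),
        "median_regional_qfr_middle": float(np.median(mid)) if mid else float("nan"),
        "median_regional_qfr_last100": float(np.median(last)) if last else float("nan"),
        "n_genes": len(results),
        "n_genes_regional": len(first),
    }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    fasta: str | Path,
    rates: str | Path,
    measurements: str | Path,
    out_dir: str | Path,
    *,
    scenario: str = "balanced",
    config: SimConfig | None = None,
    scale_budget_to_panel: bool = True,
    fit_kwargs: dict | None = None,
) -> dict:
    """Run calibration, simulation and the census; write traffic.tsv,
    census.tsv and manifest.json under ``out_dir``.  Returns the manifest.
    """
    fasta, rates, measurements = Path(fasta), Path(rates), Path(measurements)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or SimConfig(spacing=4)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {p.name: _sha256(p) for p in (fasta, rates, measurements)},
        "stages": {},
    }

    transcripts = read_cds_fasta(fasta)
    table = read_rate_table(rates)
    transcripts = [apply_rates(t, table, config.termination_multiplier) for t in transcripts]
    meas = read_measurements(measurements)
    manifest["stages"]["load"] = {"n_genes": len(transcripts), "status": "ok"}

    budget = SCENARIOS[scenario]
    if scale_budget_to_panel:
        # reduced panels: shrink the cell budget in proportion to panel size
        budget = budget.scaled(len(meas) / 5700)
    targets = {t.gene_id: t for t in scale_budgets(meas, budget)}
    manifest["stages"]["calibrate"] = {"scenario": scenario, "status": "ok"}

    by_id = {t.gene_id: t for t in transcripts}
    rows, results, copies = [], [], {}
    n_infeasible = 0
    for gid, target in targets.items():
        t = by_id.get(gid)
        if t is None:
            continue
        fit = fit_initiation_rate(
            t, target.target_mean_ribosomes, config, **(fit_kwargs or {})
        )
        if fit.infeasible or not np.isfinite(fit.initiation_rate):
            n_infeasible += 1
            continue
        cfg = replace(config, initiation_rate=fit.initiation_rate,
                      seed=gene_seed(config.seed, gid))
        res = simulate(t, cfg)
        results.append(res)
        copies[gid] = target.scaled_copies
        try:
            ramp = ramp_score(res.queued_profile, res.density_profile)
        except ValueError:
            ramp = float("nan")
        rows.append(
            {
                "gene_id": gid,
                "initiation_rate": fit.initiation_rate,
                "mean_ribosomes": res.mean_ribosomes,
                "translation_rate": res.translation_rate,
                "translation_time": res.mean_translation_time,
                "delay_time": res.mean_delay_time,
                "qfr": res.qfr,
                "ramp_score": ramp,
            }
        )
    write_traffic_table(rows, out / "traffic.tsv")
    manifest["stages"]["simulate"] = {
        "n_simulated": len(rows), "n_infeasible": n_infeasible, "status": "ok",
    }

    census_rows = []
    for s in range(config.spacing + 1):
        c = census(results, copies, s)
        census_rows.append(
            {
                "spacing": s,
                "total_ribosomes": c.total_ribosomes,
                "drpf_mrpf_ratio": ratio_drpf_mrpf(c),
                "drpf_mrpf_footprint_ratio": ratio_drpf_mrpf(c, convention="footprint"),
                "missing_fraction": missing_fraction(c),
            }
        )
    pd.DataFrame(census_rows).to_csv(out / "census.tsv", sep="\t", index=False)
    manifest["stages"]["census"] = {"spacings": config.spacing + 1, "status": "ok"}

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
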