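# ribojam

Quantifying ribosome queuing on mRNAs: a stochastic TASEP simulator of
translation with queue and footprint bookkeeping, together with the
companion analyses of disome (dRPF) and monosome (mRPF) ribosome-profiling
data and sucrose-gradient profile decomposition.

Standard ribosome profiling sequences fragments protected by a *single*
ribosome (~30 nt), so ribosomes sitting directly behind another — queued
ribosomes — are systematically invisible.  `ribojam` is for researchers who
want to quantify that blind spot: how many ribosomes are part of disomes or
larger clusters, where queues form along ORFs, and whether coding sequences
look selected to avoid them.

## The model

Translation on an ORF of N codons is a totally asymmetric simple exclusion
process (ℓ-TASEP).  Each ribosome decodes the codon at its A-site and covers
L = 10 codons; two A-sites must satisfy |i − j| ≥ L.  Events and rates:

- initiation at rate λ onto site 1, if no ribosome occupies a site ≤ L;
- a jump i → i+1 at rate λᵢ = 1/tᵢ (tᵢ the codon's mean decoding time), if
  no downstream ribosome sits at a site ≤ i + L — a failed jump marks the
  ribosome *queued* (dᵢ = 1) until its next successful jump;
- termination: the jump out of site N, as fast as the fastest codon.

Waiting times are exponential with rate μ = λ + Σᵢ nᵢλᵢ; an event is an
initiation attempt with probability λ/μ and a jump of the ribosome at i
with probability nᵢλᵢ/μ.  Time-averaging the state yields density and
queued-density profiles, footprint-size profiles at ribosome spacings 0–4,
the queue probability P(any dᵢ = 1), the queued fraction of ribosomes
(QFR = Σ queued density / Σ density), and per-protein translation and delay
times.  Per-gene initiation rates are calibrated so simulated ribosome
loads match measurements scaled to a whole-cell budget of RNAs and
ribosomes.  Two null genomes (synonymous-codon shuffling; global permutation
of the 61 decoding times) provide empirical p-values and per-gene optimality
z-scores.  See `docs/methods.md` for the full account.

## Worked example

Simulate one synthetic yeast-like gene at its planted initiation rate and
census its footprints:

```python
from ribojam import SimConfig, simulate
from ribojam.fixtures import FixtureSpec, make_transcriptome
from ribojam.footprints import census, missing_fraction, ratio_drpf_mrpf

spec = FixtureSpec(n_genes=3, median_length=300, min_length=250,
                   max_length=400, measure_terminations=500, seed=7)
transcripts, measurements, features, planted = make_transcriptome(spec)
t = transcripts[0]
res = simulate(t, SimConfig(initiation_rate=planted[t.gene_id], spacing=4, seed=7))
print(f"translation_rate={res.translation_rate:.4f} proteins/s")
print(f"mean_ribosomes={res.mean_ribosomes:.2f}")
print(f"queue_probability={res.queue_probability:.3f}")
print(f"QFR={100*res.qfr:.2f}%")
c0 = census([res], {t.gene_id: 1.0}, 0)
c4 = census([res], {t.gene_id: 1.0}, 4)
print(f"dRPF:mRPF(s=0)={ratio_drpf_mrpf(c0):.3f} missing={100*missing_fraction(c0):.1f}%")
print(f"dRPF:mRPF(s=4)={ratio_drpf_mrpf(c4):.3f} missing={100*missing_fraction(c4):.1f}%")
```

prints

```
translation_rate=0.0748 proteins/s
mean_ribosomes=3.44
queue_probability=0.053
QFR=1.60%
dRPF:mRPF(s=0)=0.032 missing=3.2%
dRPF:mRPF(s=4)=0.139 missing=13.5%
```

Read: this 250-codon gene initiates at 0.088 s⁻¹ and completes a protein
every ~13 s of simulated time per transcript copy (rate 0.0748 s⁻¹ — slightly
below λ because some attempts find the entry region blocked).  On average
3.44 ribosomes translate it; at least one of them is stuck behind a
neighbour 5.3% of the time, and 1.6% of ribosome-time is spent queued.
Counting footprints, 3.2% of ribosomes sit directly adjacent to another
(and would be missed by monosome-only sequencing); allowing up to 4 free
codons between ribosomes in one footprint raises that to 13.5%, with a
disome-to-monosome ratio of 0.139.

The same workflow runs from the shell:

```
ribojam fixtures --out fx --n-genes 50 --seed 1
ribojam run --fasta fx/cds.fa --rates fx/rates.tsv \
            --measurements fx/measurements.tsv --out run1 --scenario balanced
ribojam gradient --trace trace.tsv --mono-x 2.0 --di-x 5.0
```

`run` writes a per-gene traffic table (initiation rate, mean ribosomes,
translation rate, translation time, delay time, QFR, ramp score), the
footprint census per spacing, and a manifest that makes the run bit-for-bit
reproducible.

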