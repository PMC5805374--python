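# Methods

## The traffic model

Translation elongation is modelled as a totally asymmetric simple exclusion
process (ℓ-TASEP) on the codon lattice of one ORF.  An mRNA of N sense codons
is a lattice of N sites; each ribosome decodes the codon at its A-site and
covers L = 10 codons in total, so two A-sites must be at least L apart.  The
dynamics consist of three event types:

1. **Initiation.**  A free ribosome attaches at site 1 at rate λ
   (events s⁻¹), provided no ribosome occupies a site ≤ L.
2. **Elongation.**  The ribosome at site i jumps to i+1 at rate
   λᵢ = 1/tᵢ, where tᵢ is the mean decoding time of codon i, provided no
   downstream ribosome sits at a site ≤ i+L.  A failed jump marks the
   ribosome *queued* (dᵢ := 1); a successful jump clears the mark.
3. **Termination.**  The jump out of site N removes the ribosome.  Its rate
   is the decoding rate of the fastest codon in the table times a
   configurable multiplier (default 1): slower termination was found not to
   change the behaviour appreciably, so termination is as fast as the
   fastest codon.

Waiting times are exponential with total rate μ = λ + Σᵢ nᵢλᵢ, where
nᵢ ∈ {0,1} is the occupancy of site i; a particular event is an initiation
attempt with probability λ/μ and a jump attempt of the ribosome at i with
probability nᵢλᵢ/μ.  Blocked ribosomes keep contributing their full rate to
μ and generate null (failed) jump events — this is deliberate, because the
failed attempts are what set the queued flags.

The exclusion convention deserves one note: the A-site of an entering
ribosome is site 1 and initiation requires no ribosome at any site ≤ L; a
jump from i requires no downstream ribosome at j ≤ i+L.  Under this
convention the post-move state never violates the pairwise A-site distance
≥ L.  Conventions that shift the blocking window by one codon exist in the
literature; the difference is a single codon of effective footprint and does
not change any qualitative behaviour.

### Monitored features

Each run starts from an empty lattice, reaches steady state over a warm-up
of 100 terminations (configurable), then integrates over a further 10,000
monitored terminations (configurable):

- per-site occupancy nᵢ → the density profile; its sum is the mean ribosome
  count (this identity holds to float precision and is asserted in tests);
- per-site queued state dᵢ → the queued-density profile; the queued fraction
  of ribosomes (QFR) is Σ queued density / Σ density, computable per region;
- footprint states mᵢᵏ: at every event, consecutive ribosomes whose
  free-codon gap (j − i − L) is ≤ s are merged into one footprint; mᵢᵏ = 1
  at the 5'-most ribosome of each size-k footprint.  Profiles are kept for
  every spacing s in 0..4 simultaneously;
- the transcript queue flag q = max dᵢ → the queue probability (fraction of
  time at least one ribosome on the transcript is delayed);
- per-ribosome translation and delay clocks, averaged over monitored
  terminations, → mean translation and delay times per completed protein.

The engine is an event-driven Gillespie kernel compiled with numba; a
pure-Python backend implements the identical semantics from the elementary
operations (`total_event_rate`, `draw_event`, `apply_event`) and the two are
cross-checked statistically in the test-suite.  One RNG stream per gene is
derived from the global seed and the gene id (CRC-32 mix, kept below 2³¹),
so results are independent of scheduling and reproducible bit-for-bit.

### Exact oracle

For small lattices (N ≤ ~12) the same chain is solved exactly:
`exact_stationary` enumerates every reachable (positions, d-flags)
configuration, builds the continuous-time generator from the same event
rules, solves πQ = 0 and returns exact density, current and queue
probability.  The stochastic engine is validated against it over a grid of
L ∈ {2,4}, homogeneous/heterogeneous rates and λ ∈ {0.1,0.5,2}, within
3 Monte-Carlo standard errors.  One numerical caveat: runs of a fixed
*termination count* carry an O(1/K) ratio bias (time-averages divided by a
correlated random duration), so oracle comparisons use few long replicates
rather than many short ones.

## Calibration

Measured per-copy ribosome loads and RNA copy numbers are first scaled
globally to a cell budget.  Three scenarios are built in: balanced
(26,000 RNAs, 187,000 ribosomes, 85% actively translating), dense
(12,500 / 243,000 / 85%) and sparse (60,000 / 131,000 / 70%).  RNA copies
are scaled by one factor so that they total the budget's RNA count; per-copy
loads by another so that copies × loads total the active-ribosome count.
Relative per-gene values are preserved exactly.

Per-gene initiation rates are then fitted so that the simulated steady-state
mean ribosome count matches the scaled target: bisection on log λ over
[10⁻⁶, 10²] s⁻¹ (mean load is empirically monotone in λ), each evaluation
averaging 3 replicate runs of 1,000 monitored terminations (both
configurable), with a final run at full length.  Convergence tolerance is 2%
relative (configurable).  A target above the lattice capacity N/L, or above
the saturation load at λ_max, is reported infeasible rather than clamped.

## Footprint census and the dRPF:mRPF ratio

The census weights each gene's time-averaged footprint counts by its active
RNA copies and reports, per spacing s, the number of ribosomes residing in
footprints of each size k (k times the mean number of size-k footprints).
Ribosomes are conserved across k at every s.  The disome-to-monosome ratio
is counts[2]/counts[1] in the ribosome-count convention — a pair contributes
two ribosomes, matching the absorbance-area argument (gradient absorbance is
proportional to ribosome mass); the footprint-count convention
(counts[2]/2 : counts[1]) is also emitted.  The missing fraction
Σ_{k≥2} counts[k] / Σ counts[k] estimates the share of ribosomes invisible
to monosome-only sequencing.

## Ribosome-profiling analyses

- **Offset detection**: per read length, the distance from read 5' ends to
  the decoding site is the global maximum of the 5'-end metagene upstream of
  start codons, accepted only in the 5–20 nt window and only if nothing
  outside the window ties or beats it; otherwise the read length is
  discarded (a 15 nt dataset-level fallback can be enabled).
- **Multimapped reads** split across their M best alignments proportionally
  to the unique-read count density in a 100 nt window (uniformly if all
  windows are empty); read mass is conserved exactly.
- **NFC** divides a gene's per-codon counts by their mean; **RPKM** is reads
  per kilobase of ORF per million mapped reads.
- **Peak calling** flags positions ≥ mean + 5 SD of the gene's nonzero
  counts (both moments over nonzero positions; flat nonzero coverage yields
  no peaks, since no position can stand above the rest).
- **Metagene analysis** anchors NFC windows at supplied positions; the
  background re-anchors the same windows at uniform random positions of the
  same genes, 1,000 times, recording each resample's median window-mean.
  BR is the observed median over the median of null medians; the p-value is
  the add-one empirical tail.
- **Downsampling** draws reads without replacement
  (multivariate-hypergeometric over positions), hitting the target total
  exactly.
- **Missing-mRPF rule**: after downsampling mRPFs to dRPF totals, a position
  is flagged when its mRPF count is in the bottom 10% of the gene *and* its
  dRPF count is in the top 10%.  "Bottom 10%" uses the empirical CDF: a
  position qualifies iff the fraction of positions with a count ≤ its own is
  at most 10% (symmetrically for the top).  This tie rule is deterministic
  and implies that a value shared by more than 10% of the gene is never
  extreme — in particular, uniform profiles flag nothing.  Genes need dRPF
  coverage (nonzero fraction) ≥ 10%.  Flagged fractions are reported for the
  first 100 codons, last 100 codons and the middle.
- **Feature correlations** are partial Spearman correlations of a per-gene
  statistic with each feature (initiation rate, tAI, protein abundance, PA
  per RNA copy, ORF length) controlling for the remaining features.

## Gradient decomposition

A trace of absorbance versus particle size is discretized into 500 equally
spaced x-values carrying integer multiplicities round(100·a/a_max)
(round-half-up), then fitted with Gaussian mixtures by EM over k = 4..8
components (configurable), with random restarts plus one restart seeded at
detected absorbance peaks; the model is selected by BIC, and candidates
within 0.5% of the optimum are recorded in the fit for inspection (replacing
manual screening with an audit trail).  User-supplied anchor positions
(expected monosome and disome x; gradients have no absolute size axis) each
claim the component with the nearest mean — two anchors claiming one
component aborts with a re-fit error — and any remaining components are
assigned to the nearest anchor, so a fraction that EM split into co-located
components keeps its full weight.  The dRPF:mRPF ratio is the ratio of the
fractions' total weights.

The model-free alternative integrates raw absorbance under each
anchor-claimed peak between boundaries set per side by the earlier of the
half-height crossing or the second derivative turning positive.  Peak
positions and heights come from a lightly smoothed curve and the curvature
from a wide Savitzky–Golay second-derivative estimate: second differences of
raw traces at grid resolution are dominated by measurement noise, which
would otherwise collapse the integration bounds onto the peak.

## Null models and optimality scores

Two null genomes isolate different aspects of the codon-rate landscape:
shuffling synonymous codon order within each gene (preserves the amino-acid
sequence and per-family codon multisets) and permuting the 61 decoding times
across codon identities (preserves the multiset of rates).  For each of the
(default 100) null genomes, initiation rates are refit to the same per-gene
ribosome load before simulating, in both models, so nulls differ from the
real genome only in codon placement or rate assignment.  Empirical p-values
use the add-one estimator (1 + #extreme)/(1 + n), never zero; optimality
z-scores use the sample SD of the nulls.  The ramp score is the QFR of the
first 100 codons over the QFR of codons 101..N−100 (genes > 200 codons; a
queued ramp over an unqueued middle returns +inf as a flagged sentinel).
Extreme sets (top/bottom 5% by rank or z-score) are compared by the
hypergeometric tail on the shared universe, and term enrichment uses the
hypergeometric test with Benjamini–Hochberg adjustment within each set.

## Synthetic data: what it emulates and what it does not

The fixture generator produces every input with known ground truth.  Default
conditions are yeast-like and fixed once:

| quantity | default | basis |
| --- | --- | --- |
| ORF length | log-normal, median 400 codons (σ_log 0.55, clipped 120–1500) | typical yeast ORF lengths |
| initiation rate | log-normal, median 0.09 s⁻¹, 10th/90th pct ≈ 0.019/0.29 | reported fitted-rate distribution |
| codon decoding time | log-normal per codon, median 0.18 s (mean ≈ 0.2 s, ≈5 aa s⁻¹), σ_log 0.4, clipped 0.04–0.8 s | Little's-law consistency: ≈7 ribosomes per active copy on a 400-codon ORF at λ ≈ 0.09 s⁻¹ requires a ≈0.2 s mean step |
| RNA copies | log-normal, mean 4.5 per gene | budget-scaled copy numbers |
| active fraction | 0.85 | balanced budget scenario |
| ribosome size L | 10 codons | monosome footprint length |

Measured ribosome loads are produced by *simulating* each gene at its
planted rate, so calibration round-trips are exact by construction.  Codon
usage is biased within synonymous families by a per-gene exponent on codon
speed, giving a genuine tAI spread; an optional 5'-ramp mode prefers slow
codons in the first 100 codons.  Gradient traces are sums of Gaussians with
1% multiplicative-scale noise (clipped non-negative) and the true area ratio
recorded.

The generator does **not** emulate several features of the real
transcriptome: the heavy slow tail and inter-codon structure of fitted
decoding times, the coupling of expression level to initiation rate and
codon optimality, positional codon-order autocorrelation, or the natural
5'-end slow ramp (off by default).  Consequently the synthetic panel's
absolute queue magnitudes (QFR, queue probability, delay time, and the
zero-spacing disome share) run below genome-wide values even though relative
behaviour — monotone growth of the disome share with spacing, trisomes
several-fold rarer than disomes, queueing increasing with initiation rate —
matches.  Passing tests therefore demonstrate the correctness and
calibration of the machinery, not that the synthetic panel is the yeast
transcriptome.

## Numerical choices

- Per-gene RNG streams; exponential waiting times by inverse CDF; event
  choice by a single uniform against the cumulative rate vector (direct
  Gillespie, identical in law to the two-step description).
- 10⁹-event cap per gene guards infeasible parameter corners.
- Footprint bookkeeping allocates the exact maximal cluster size (⌊N/L⌋+1),
  so census conservation holds to float precision.
- Quantile/tie rules, rounding (round-half-up multiplicities), and the
  ECDF-based missing-mRPF rule are chosen for determinism and stated above.
- Midranks for all rank statistics; partial correlations via the inverse
  correlation matrix of ranks (the residualization route is algebraically
  identical and used as a test oracle); p-values from the t approximation
  with df = n − #controls − 2.

## Problem sizes used in the shipped analyses

The end-to-end analyses (acceptance script and suite) run a 100-gene panel
at 5,000 monitored terminations per gene (run-to-run reproducibility is
measured at 10,000, the production run length), with calibration
evaluations of 2 × 600 terminations.  These sizes keep full runs in the
minutes range while leaving Monte-Carlo noise on panel medians at the
few-percent level; all sizes are configurable upward.
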