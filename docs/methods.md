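# Methods

`ribocalc` computes absolute, per-gene translational parameters for a
cell in steady-state growth from four inputs: a paired mRNA-seq /
ribosome-footprint count table, CDS sequences, a tRNA decoding table
with gene copy numbers, and (optionally) relative mRNA half-lives.
This note records the model, its assumptions, the parameters that
matter, and the design choices made where the design was genuinely open.

## Model assumptions

1. All molecular pools (mRNA, tRNA, ribosomes, factors) are constant
   over the observation window and diffuse freely.
2. All transcripts of a gene share one sequence (no alternative
   isoforms or editing).
3. Elongation always runs to completion (yeast processivity is
   measured at ~99.8–99.9%, so premature drop-off is ignored).
4. Initiation follows the scanning model, and the ribosome–mRNA
   binding constant is the same for every transcript, so the relative
   binding rate Pz of a gene is proportional to its transcript
   concentration.
5. Footprints mapping outside the CDS (upstream ORFs) are not modelled.

## From read densities to absolute abundances

With X transcripts per cell (default 36,000), W ribosomes (200,000) and
active fraction q (0.85):

- `Pz_i = d_i / Σ d_j` where `d_i` is the gene's mRNA RPKM; `x_i = Pz_i · X`.
  The supplied RPKM column is authoritative (it encodes the upstream
  mappability normalisation); RPKM recomputed from raw counts is used
  only as a data-quality check, warning at >20% disagreement.
- `w_i = (f_i / Σ f_j) · W·q / x_i` where `f_i` is the gene's **raw**
  footprint count: the footprint share allocates the W·q busy ribosomes
  across transcript types, then divides by copy number.  The footprint
  RPKM column is retained for validation only.
- `g_i = 100 · w_i / L_i` ribosomes per 100 codons.  A ribosome covers
  ten codons, so `g > 10` is physically impossible and excludes the
  record.

Conservation (`Σ Pz = 1`, `Σ x = X`, `Σ w·x = W·q`) holds to machine
precision by construction and is enforced in tests.  `x` is kept
fractional: sub-unity copy numbers are meaningful averages over cells.

## Per-codon elongation times

Codon times come from diffusion-limited competition of cognate,
near-cognate and non-cognate aa-tRNAs for the A site (the random-walker
model of Fluitt, Jackson & Viljoen 2007, adapted to yeast).  The
cytoplasm of volume V is divided into `N = V/δ³` occupation sites; a
species with `n_j` molecules and hop time `t_j = δ²/(6 D_j)` first
arrives at a vacant site after `t_j · N / n_j` on average.  With
`R_near` and `R_non` the summed arrival-frequency ratios of near- and
non-cognates to cognates,

```
t_c = 1/Σ_cognate ω_j  +  τ1  +  R_near·τ2  +  R_non·τ3
```

where τ1 is the cognate insertion time and τ2, τ3 the delays of futile
near-/non-cognate sampling.  The packaged constants (ms) are:

| T (°C) | τ1   | τ2   | τ3  |
|--------|------|------|-----|
| 20     | 40.0 | 46.3 | 2.2 |
| 24     | 26.6 | 30.7 | 1.5 |
| 30     | 16.1 | 18.7 | 0.9 |
| 37     |  9.1 | 10.5 | 0.5 |

Only these four temperatures are supported; no Arrhenius interpolation
is offered because the underlying elementary rate constants are not
packaged.  Transpeptidation and translocation are treated as
instantaneous (A-site selection is rate-limiting).

**tRNA inventory.**  The cellular tRNA pool is sized by RNA-mass
bookkeeping — genome size × RNA:DNA ratio × tRNA fraction / mean tRNA
length = 2.8e7 × 50 × 0.15 / 74.5 ≈ 2,818,792 molecules — and divided
among isoacceptors proportionally to gene copy number (yeast tRNA
abundance tracks gene copy number closely; r ≈ 0.9).  Largest-remainder
rounding conserves the total exactly (ties broken by anticodon).  The
packaged yeast table lists 41 isoacceptors / 270 nuclear gene copies
with decoding specificities assigned by standard wobble rules in the
style of Percudani et al. (1997).

**Near-cognate rule.**  A species is near-cognate for a codon when its
anticodon pairs with it with a single mismatch in codon position 2
or 3; species decoding the codon through a wobble mismatch are cognate
and excluded from the near-cognate set.  First-position single
mismatches are non-cognate; the rule is applied as stated, not
"corrected".

**Physical defaults.**  δ = 5.9 nm (walker size; one value for all
species), V = 4.2e-17 m³ (cytoplasm volume of a haploid cell in
exponential growth), D = 8.3e-13 m²/s for every amino acid (cytoplasmic
macromolecule diffusion; the diffusion table accepts per-amino-acid
overrides).  With a uniform D the competition ratios reduce to molecule
-count ratios, and δ and V affect only the cognate arrival term.  These
defaults reproduce the observed scale of yeast codon times at 30 °C:
unweighted mean 234 ms over the 61 sense codons, 121 ms when weighted
by cognate tRNA copies (codon-optimal sequences), extremes 56–1018 ms.
Changing δ rescales N only; the defaults live in
`ribocalc/data/cell_model.yaml` and `diffusion.tsv`, not in code.

## Per-gene times

- `E = Σ t_c` over the CDS sense codons (terminal stop excluded;
  internal stops and ambiguous bases are errors), `mean_E = E/L`.
- `I = E / w`: with w ribosomes on L codons the mean inter-ribosome gap
  is `L/w` codons; since codon identities inside a gap are unknowable
  the gap is translated at the average codon time, giving
  `I = mean_E · (L/w) = E/w`.  This averaged-gap reading also applies
  at the packing limit (`w = L/10` gives `I = 10·mean_E`).
- `P = 1/I`; `T = I + E`.
- `Ps = (P/Pz) / max(P/Pz)` over the **retained** cohort (normalised
  after all filters), so the best-initiating gene scores exactly 1.
  Ps is comparable only within one analysis.

All time columns are stored in SI seconds; the writer adds `min:sec`
(T, I, E) and `h:min:sec` (h, m) companions.

## Ribosome queuing screen

A deterministic event-driven simulation launches a ribosome at the
start codon every I seconds.  A ribosome covers the ten codons ending
at its A site; it advances one codon after dwelling that codon's `t_c`
and only when the target codon is uncovered (adjacent packing allowed).
A stalled ribosome completes its dwell clock but waits, and the waiting
time counts toward its cumulative traversal time.  Classes: 0 — all
cumulative times equal (no queuing); 1 — trailing ribosomes slower
(queuing); 2 — an attachment attempt at t = k·I found the landing site
still covered (blocked 5′ end).  Classes 1 and 2 are excluded from the
parameter tables (optionally kept with their flag).

Open design points, resolved as follows:

- **Horizon**: `max(2·⌈w⌉+3, 5)` ribosomes must fully traverse —
  roughly twice the steady-state complement, enough for interference to
  express itself while bounded.
- **Attachment exclusion**: the landing ribosome's A site is codon 1
  and its body extends upstream, so the on-transcript vacancy check
  reduces to "the previous ribosome has cleared the footprint region"
  (A site past codon 10).  This is the only geometry under which the
  provable sufficient condition *I ≥ footprint · max dwell ⇒ class 0*
  holds, and it matches the class-2 definition (first ribosome still
  covering the AUG).
- **Ties**: simultaneous release and advance resolve downstream-most
  first.
- **Numerics**: the engine solves the blocking recurrence
  `leave[k] = max(leave[k-1]+dwell[k], prev_leave[k+footprint])` in
  closed form per ribosome; an epsilon of 1e-9 of the simulated span
  absorbs float-noise ties (genuine blocking delays are at least one
  codon dwell, many orders larger).  Cumulative times are compared at
  1e-9 relative tolerance.

The engine is cross-checked against an independent fixed-timestep
simulator (Δ = min dwell / 100) on randomized transcripts.

## Protein output

Relative half-lives are calibrated by a single anchor: HIS3 (YOR202W),
with independent absolute measurements of 7 min (24 °C) and 11 min
(30 °C); the default anchor is their 9 min midpoint
(`h_i = t0_i · 540 s / t0_anchor`), overridable in the config.  Then
`m = h/ln 2` (exponential decay), `b = m/I` initiations per transcript
lifetime (kept fractional), `B = b·x` per gene.  Proteome mass sums
`B · MW / N_A` using average amino-acid masses (monoisotopic masses
would be a one-line change; average is the appropriate choice for bulk
mass).  Steady-state turnover is assumed and protein degradation is not
modelled: B counts molecules produced during one transcript generation,
not molecules present.

## Filter cascade and normalisation bases

Order: (1) zero footprints → drop; (2) `g > 10` (strict) → drop;
(3) times; (4) queue classes 1/2 → drop; (5) Ps normalisation over the
retained set; (6) optional decay columns.  The ledger identity
`n_retained = n_input − n_no_footprints − n_density_excess − n_queue −
n_blocked` is enforced.  Zero-footprint genes still carry mRNA mass, so
they stay in the Pz/x denominators while being excluded from the
footprint allocation; this choice is recorded in the run summary
metadata.  RPKM length normalisation uses the annotated CDS length
including the stop codon; kinetics exclude it.

## Synthetic cohorts

The generator samples a ground truth and evaluates the forward model to
produce inputs, so the pipeline's inverse can be tested exactly:

- CDS lengths log-normal (median 430 codons, σ_log 0.594, truncated to
  37–4911) — the yeast transcriptome regime.
- Codon composition per gene: sampling weights ∝ (cognate gene
  copies)^s with s ~ Beta(2,2), emulating the spread of codon
  adaptation; compositions are resampled (≤40 tries) until the
  transcript's mean codon time lies in the observed 0.105–0.350 s
  window.
- Transcript fractions Dirichlet(0.6) (heavy-tailed); the draw is
  repeated with a flatter concentration if it cannot carry the
  busy-ribosome pool under the caps below, and errors honestly if
  infeasibility persists.
- Ribosome loads log-normal, then water-filled so `Σ w·x = W·q`
  exactly under per-gene caps `0.9·min(L/10, E/(10·max dwell))` — the
  packing limit and the no-queuing sufficient condition.
- Optional special genes: a queuing gene (ten-codon cluster of the
  slowest codon; launch interval set to eight slow dwells against a
  ten-dwell service time, so it classifies as queuing without backing
  the queue up to the start codon) and a zero-footprint gene.
- Counts: expected values (noise "none") or Poisson draws around them
  (noise "poisson"); RPKM columns recomputed from the emitted counts.
  Default depth 1e6 reads per library, 200 genes.
- Relative half-lives log-normal in arbitrary units, anchor included.

With noise "none" the pipeline recovers every parameter to better than
1e-9 relative error (observed ~1e-15).  What passing these tests does
*not* show: robustness to mappability bias, footprint-length variation,
UTR effects or non-Poisson overdispersion — none of which the generator
emulates.

## Problem sizes

The shipped tests and the acceptance script run cohorts of 20–200 genes
and ~100 queue-simulator cross-checks on transcripts of up to 200
codons, sizes chosen to exercise every code path at desk scale; the
pipeline itself is linear in total codons and handles genome-scale
cohorts (~5,000 genes) in seconds.

## Known limitations

- Decoding specificities and copy numbers are a curated snapshot;
  strains differ, and the table is a data file precisely so it can be
  replaced.
- The initiation time is an equilibrium read-out of ribosome spacing,
  not a mechanistic scanning model; it inherits any bias in the
  footprint densities.
- Only the four tabulated temperatures are supported.
- The queuing screen is deterministic; stochastic initiation would
  smear the class boundary for marginal transcripts.
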