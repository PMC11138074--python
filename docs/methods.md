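# Methods

This note documents the models, estimators, defaults and known limits of
the package. It describes what the code computes; every number quoted in
the README is produced by the code itself.

## Variant space and library model

An NNK degenerate codon (N = A/C/G/T, K = G/T) encodes all 20 amino
acids plus exactly one stop (TAG) in 32 codons. Mutagenizing one codon
at a time therefore yields 21 distinguishable protein-level outcomes per
residue — 19 missense, 1 nonsense, and 1 synonymous (the WT amino acid,
possibly via a different codon) — so an L-residue protein has 21·L
possible single-amino-acid outcomes (2709 for L = 129). Synonymous
outcomes are counted inside the space because the 21-per-site arithmetic
is only consistent with the library totals when they are. Residue
indexing is 1-based everywhere.

`snv_accessibility` reports the minimum number of single-nucleotide
substitutions from the reference codon to any codon of the target amino
acid, with transition (A↔G, C↔T) / transversion labels on every 1-step
path. For synonymous outcomes the reference codon itself is excluded
(distance is to *another* codon of the same amino acid); Met and Trp
have no such codon and raise an error rather than reporting a vacuous
distance.

## Synthetic assay generator

The generator (`sim_assay`) is first-class, tested code. Its defaults
are the study conditions of the emulated experiment:

| parameter | default | meaning |
|---|---|---|
| `protein_length` | 129 | residues in the subunit |
| `library_coverage` | 0.957 | fraction of the 21·L outcomes present |
| `n_barcodes_mean` | 30.7 | mean barcodes per variant (zero-truncated negative binomial, dispersion 8) |
| `barcode_length` | 18 nt | random barcode length |
| `n_replicates` | 3 | independent replicates |
| `reads_per_sample` | 10⁶ | sequencing depth per sorted bin / per day |
| `cells_per_replicate` | 3.2×10⁶ | sorted cells (≈ 8×10⁵ per bin) |
| `days` | (0, 8, 20) | depletion sampling times |
| `growth_coupling` σ | ln(10)/20 ≈ 0.115 d⁻¹ | selection rate per unit activity; a WT-like variant depletes 10-fold by day 20 |
| `fluorescence_sd` | 0.6 (ln units) | cell-level lognormal staining spread |
| `background_fluorescence` | 0.05 | autofluorescence floor |
| `abundance_sd` | 0.3 (ln units) | clonal abundance jitter per barcode |

Each variant carries two latent effects: surface expression τ and
functional activity φ, both anchored so synonymous ≈ 1 and severe loss
≈ 0. Latents are drawn from per-class normal components clipped at 0.
The component parameters were set from the published score
distributions before any recovery test was run: synonymous τ sd 0.08
(the printed synonymous trafficking band 0.83–1.18 is ≈ ±1.96 sd),
synonymous φ sd 0.2 (printed synonymous functional IQR 0.27), nonsense
components switching from loss-like to WT-like after residue 55
(trafficking) / 104 (function), and missense mixtures whose weights
approximate the printed category proportions (trafficking: 5% loss, 15%
partial, 67% normal, 13% gain; functional: 7.5% loss, 17.5% partial,
75% normal). Because most variants that cannot reach the surface also
cannot conduct, a missense variant in the τ-loss component is assigned
a φ-loss latent with probability 0.8 (and φ-partial otherwise),
matching the reported 80% overlap. Non-synonymous variants at residue 1
destroy the start codon and are forced into the loss component of both
latents.

**Sort-seq model.** Per replicate, cells are allotted to barcodes
multinomially (with lognormal clonal jitter); each cell's fluorescence
is (τ + background)·exp(sd·Z). The lognormal choice is not derived from
the emulated experiment — it is the standard positive, right-skewed
model for surface staining. Bins split the pooled cells at empirical
quartiles, so ~25% occupancy per bin holds by construction, and each
bin pool is sequenced multinomially to a fixed depth — hence simulated
count-matrix columns sum exactly to `reads_per_sample`.

**Depletion model.** Barcode frequency at day t is proportional to
f₀·exp(−σ·φ·t): the simplest selection model that reproduces the
qualitative published depletion curves (functional variants deplete,
null variants persist). Each day's sample is an independent multinomial
read draw.

One seed drives three independent substreams (library, sort, depletion),
so any stage can be regenerated without rerunning the others and every
output is byte-reproducible.

What the generator does **not** emulate: sequencing error and PCR
jackpotting, barcode collisions surviving subassembly, replicate batch
effects (bin-boundary drift, staining efficiency), cell-cycle or density
effects on selection, and day-dependent selection strength. Passing
recovery tests therefore demonstrate the estimators are correct and
well-calibrated under multinomial counting noise — not that real-data
systematics are handled.

## Scoring estimators

**Sort-seq.** Counts get a pseudocount of 0.5 per cell, are normalized
within each sample (depth), and each entity's four values are
renormalized to bin shares. The raw score is the weighted bin average
with equally spaced weights (0, 1/3, 2/3, 1) — the exact weighting used
by the emulated study is not public, so weights are configurable (e.g.
mean-fluorescence weights). The raw score is bounded in [0, 1],
monotone under upward mass shifts, and invariant to per-sample depth
rescaling (exactly so when the pseudocount is scaled with the sample).

**Depletion.** The raw statistic is the OLS slope of log2 frequency
against day over all three time points (pseudocount 0.5). Using the
regression rather than the endpoint log-ratio keeps the day-8
information; the two coincide for collinear series. Slopes are
invariant to per-day depth scaling.

**Aggregation.** A variant's replicate score is the unweighted mean of
its barcodes' scores — barcodes are independent clonal measurements, so
equal weighting is the natural choice; read-weighted means would let a
jackpotted barcode dominate.

**Normalization.** Within each replicate, x ↦ (x − m₀)/(m₁ − m₀) with
m₁ the synonymous median and m₀ the early-nonsense median, so the
anchors are exact by construction: synonymous median 1, early-nonsense
median 0. For the trafficking assay the early-nonsense anchor set is
nonsense variants at residues 1–55; for the functional assay it is
residues 1–104. The two sets coincide with the per-assay truncation
regimes (truncations before these boundaries abolish surface expression
and function respectively); anchoring the functional assay on its own
full loss plateau uses 66 more anchor variants than reusing the
trafficking set and keeps "early" meaning the same thing for anchoring
and regime reporting. All percentiles use linear interpolation
(Hyndman–Fan type 7).

**Confidence intervals.** 95% CIs come from a hierarchical percentile
bootstrap: resample barcodes with replacement within each replicate,
average replicate means, repeat (default 1000 draws, seeded). A variant
with one barcode and one replicate collapses to a degenerate interval.
This bootstrap captures barcode-level counting noise but not
replicate-level batch variance (which the generator does not model); on
simulated null variants its empirical coverage is ~93–95%.

## Classification

Cutoffs are data-derived: `lower` = 97.5th percentile of early-nonsense
scores, `mid_low`/`mid_high` = 2.5th/97.5th percentiles of synonymous
scores (the published values are 0.2/0.83/1.18 for trafficking and
0.09/0.44/1.53 for function). The decision tree, evaluated in order:

1. estimate < `lower` → **loss** (point estimate alone, as defined);
2. CI entirely below `mid_low` → **partial_loss**;
3. CI reaching below `mid_low` → **possible_loss**;
4. CI inside (`mid_low`, `mid_high`) → **normal**;
5. CI crossing `mid_high` → **possible_gain**;
6. CI entirely above `mid_high` → **gain**.

The published verbal definitions leave "point estimate near the cutoff"
undefined; operationalizing the possible categories purely by
CI-spanning makes the tree total, deterministic, and monotone (shifting
estimate and CI upward never moves a variant toward loss), which the
suite verifies exhaustively on a grid and by property test. Inverted or
degenerate cutoffs (e.g. a zero-width synonymous band) are a hard
error: they indicate data pathology, not a classifiable situation.

## Calibration

Controls are curated with ClinVar priority: P/LP → presumed pathogenic
and B/LB → presumed benign regardless of frequency; otherwise ≥1
literature case at gnomAD AF < 2.5×10⁻⁵ → pathogenic, and estimated
penetrance < 10% (cases / [literature carriers + gnomAD allele count])
at AF > 3×10⁻⁵ → benign. Frequent but penetrant variants are excluded.

Readouts use the calibration cutoff pair (0.44, 1.43) — the synonymous
2.5th/97.5th percentiles of the calibration analysis, kept deliberately
distinct from the classification module's 1.53; the source analyses
print both and the package preserves the discrepancy rather than
silently reconciling it. A readout is abnormal only when the estimate
and the whole CI clear a cutoff; CIs overlapping a cutoff are
indeterminate and drop out of every OddsPath denominator.

OddsPath follows the ClinGen SVI two-proportion form. P1 is the
pathogenic fraction of determinate controls; P2 is the pathogenic
fraction within a readout class; the likelihood ratio is
[P2(1 − P1)]/[(1 − P2)P1], algebraically the ratio of posterior to
prior odds (the test suite checks this equivalence on all small
contingency tables). When a cell of a readout class is empty, one
hypothetical control is added to that cell for that class's P2 only —
P1 is never corrected. This is the unique rule consistent with the
published worked example (3/1 pathogenic, 0/7 benign → 5.25 and 0.25)
and it also keeps ratios finite when a concordant cell is empty.
Strength thresholds: PS3 at > 2.1 / 4.3 / 18.7 / 350
(supporting/moderate/strong/very strong) and BS3 at < 0.48 / 0.23 /
0.053 / 0.0029.

## Downstream statistics and contacts

Deleterious means *low* score throughout, so ROC curves count
`score < threshold` as a positive call; AUC is trapezoidal and
invariant under monotone transforms. Rank-sum contrasts use the exact
Mann-Whitney null for groups of ≤ 10 and the continuity-corrected
normal approximation otherwise. Category cross-tabulations are tested
with Pearson's chi-square without continuity correction. A residue is
intolerant when strictly more than 70% of its scored missense variants
are loss/partial-loss, tolerant when strictly more than 50% are normal.
Splice flags compare precomputed delta scores against 0.5 (recommended)
and 0.2 (high recall), strict inequality.

Contacts use heavy atoms only (hydrogens ignored), first model,
altlocs resolved by highest occupancy per atom name, minimum Euclidean
atom-pair distance per residue, and a strict < 5 Å cutoff. Whether the
original analysis used heavy or all atoms is not stated; heavy atoms
are the declared default and the cutoff is a parameter.

## Problem sizes and seeds

The test suite validates estimators on closed-form fixtures and runs
two simulation scales: a 25-residue shared fixture for module tests and
one full-scale (129-residue, default depth, seed 11, 500 bootstrap
draws) recovery experiment asserting rank correlation ≥ 0.9 between
estimated scores and true latents, ≥ 90% of planted-loss variants
recovered as loss/partial-loss, ≥ 90% of synonymous variants classified
normal, and bootstrap coverage within 95% ± 2% on 1000 identical-latent
variants (whose analytic raw score is exactly 0.5 under quartile
binning). These sizes keep the full suite under a minute while leaving
the recovery margins comfortably clear of their thresholds.

## Known limitations

- The generator's independence assumptions (no batch effects, no
  overdispersion beyond the negative-binomial barcode counts) make
  simulated CIs slightly conservative relative to real data.
- The sort model assumes bin boundaries at exact pooled quartiles;
  drifting gates between replicates are not modeled.
- Subassembly rejects rather than repairs: no gapped alignment, no
  error-correcting barcode clustering (merging barcodes within Hamming
  distance 1 is future work).
- The depletion assay convention (1 = depletes like WT) means the assay
  cannot distinguish gain-of-function from WT-like behavior — the
  emulated experiment has the same blind spot.
- Nucleotide-level (c.) HGVS naming, multi-codon variants, and indels
  are out of scope.
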