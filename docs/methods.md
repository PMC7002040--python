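# Methods

This note documents the models and procedures `ribomito` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real data.

## Translational-efficiency (TE) scoring

Polysome profiling separates mRNAs on a sucrose gradient by the number of
bound ribosomes.  Fractions are pooled into a *light* pool (1 to
`boundary` ribosomes, default `boundary = 3`), a *heavy* pool (more than
`boundary` ribosomes) and a *sub-polysomal* pool (0 ribosomes), and each
pool is sequenced (`polysome.pool_fractions`).  The TE score of transcript
*t* in one replicate is

    TE_t = (heavy relative abundance of t) / (light relative abundance of t)

where relative abundance is the within-sample proportion
`(count + pseudocount) / Σ(count + pseudocount)`.  Per-condition TE is the
arithmetic mean of the replicate TEs (a geometric-mean option exists, not
default, because the source protocol averages the ratios directly).  The
change in TE between knockdown and control is analysed as
`log2(TE_kd / TE_ctrl)`; a log2 change of ±1 means TE doubled or halved,
which is the only scale on which the conventional ±1 shift thresholds are
coherent, so binning and correlation also operate on log2 ΔTE.  The shift
classes use strict inequalities (`down` iff log2 ΔTE < −1, `up` iff > 1).

Defaults with no counterpart in the source protocol, reported in every
output: `pseudocount = 0.5` (half-count convention, keeps zero-count
pool entries finite) and `min_total = 10` (drops transcripts whose total
count across samples is below 10; dropped ids are listed, never silent).

### Light-pool boundary

The boundary between light and heavy is stated ambiguously in the assay
tradition ("less than three" vs "three or less" ribosomes); the default is
≤ 3 ribosomes in the light pool and the parameter is exposed.

## 5'UTR features

The 5'UTR of a transcript is the exonic sequence strictly 5' of the first
CDS base, spliced in transcript order, reverse-complemented on the minus
strand.  GTF coordinates (1-based, inclusive) are converted to half-open
0-based intervals inside the reader only.  GC content is
(G+C)/(A+C+G+T), case-insensitive, with N excluded from the denominator;
an empty or all-N UTR is flagged undefined and excluded from association
tests (the exclusion count is reported).  The TOP (5'-terminal
oligopyrimidine) motif is taken as the canonical description — a
cap-adjacent C followed by an uninterrupted run of 4–15 pyrimidines —
with both run bounds configurable, since no formal definition exists in
the source analysis.

## Association analysis

* `pearson_test`: product-moment r with the t transform
  `t = r·sqrt((n−2)/(1−r²))`, two-sided p from the t distribution with
  n−2 df (matching R's `cor.test`).  p-values below 2.2e-16 are printed as
  "< 2.2e-16" in text output but stored as computed.
* `bin_profile`: feature mean ± SE in contiguous log2 ΔTE bins whose edges
  are multiples of the window (default 0.5); empty in-range bins retained.
* `mann_whitney`: exact distribution when both groups have ≤ 8
  observations and no ties, otherwise the normal approximation with tie
  and continuity corrections (delegated to scipy; the exact branch is
  cross-checked against full enumeration in the test suite).
* `enrichment_2x2`: upper hypergeometric tail (one-sided) and Fisher's
  exact test (two-sided) for motif enrichment among shifted transcripts.

## Proteomics statistics

The pipeline mirrors the standard Perseus treatment of MaxQuant
proteinGroups tables.

**Filtering** removes, in a fixed audited order: decoy / contaminant /
identified-by-site rows; rows annotated with an excluded GO term (default
`{"blood microparticle"}`); rows with more than `max_zeros = 3` zero
intensities counted across all samples.  Removal counts are reported per
rule so alternative orders are auditable.

**Imputation.** After log2 transformation (zeros → missing), each missing
cell is drawn from `Normal(mean_obs − 1.8·sd_obs, (0.3·sd_obs)²)`, the
down-shifted narrowed normal that models missing-not-at-random dropout of
low-abundance proteins.  Scope defaults to per-sample (column) statistics,
the Perseus default; a `global` scope is provided because "SD of the data"
is ambiguous between the two.  The imputation mask and imputed fraction
are always returned.

**s0-moderated permutation test.** For groups 1 and 2,

    d_i = (mean2_i − mean1_i) / (se_i + s0)

with `se` from the Welch (default) or pooled variance model.  s0 enters
additively on the standard-error scale (the SAM convention, as Perseus
implements it): it damps the significance of small absolute differences,
interpolating between a pure t-test (s0 = 0) and a pure fold-change
ranking (s0 → ∞).  Null statistics come from relabelings of the sample
columns.  The identity labelling and its mirror are excluded: they
reproduce every true effect and, for any dataset containing real
differences, would drive the estimated FDR towards 1 by construction.  A
3-vs-3 design therefore has 18 usable labelings; when more than `n_perm`
(default 250) exist, that many are sampled without replacement.  For a
symmetric threshold t,

    FDR(t) = mean over labelings of #{|d*| ≥ t} / #{|d| ≥ t},  capped at 1,

with π0 fixed at 1 (conservative), and `q_i = min{ FDR(t) : t ≤ |d_i| }`,
which makes q monotone non-increasing in |d|.

*Power regimes.*  With only 18 relabelings of a 3-vs-3 design and a
non-trivial fraction of true effects, the mixed relabelings of affected
proteins inflate the permutation null.  At small s0 (s0 comparable to a
tenth of the replicate SD) this caps achievable recall well below what
the same effects would yield in a larger design; in the fold-change
weighted regime (s0 of the order of twice the replicate SD) the mixed
relabelings are additionally damped by their inflated group variances and
recall above 90% is reached for 4-SD effects at 5% prevalence.  The test
suite exercises both regimes; `s0` is always an explicit per-dataset
argument (published analyses use 0.1 and 0.2 on log2 LFQ data) and is
never hard-coded.

**Proteomic ruler.** The summed histone MS signal is assumed to report a
protein mass equal to the cellular DNA mass, giving

    mass_i  = intensity_i / Σ histone intensity × DNA mass [pg]
    copies_i = mass_i[g] / (MW_i[g/mol]) × N_A

DNA mass is a required input (or derived from genome size:
`genome_bp × ploidy × 615.8771 Da / N_A`, with 615.8771 Da the average
mass of a base pair).  Organelle mass fractions split multi-localised
proteins equally across their compartments and collect unmapped mass
under "unassigned"; percentages sum to 100 exactly.

## Physiology metrics

Closed-form, unit-documented pure functions: RER = VCO₂/VO₂; energy
expenditure = 3.815·VO₂ + 1.232·VCO₂ (unit-agnostic in the gas volumes —
the output scale follows the input units, which the calorimeter
determines); FS = (LVDD−LVSD)/LVDD × 100; RWT = (IVSD+LVPWD)/LVDD, where
the first argument is the interventricular septal thickness in diastole;
QTc = QT/√RR with seconds in and out (a millisecond wrapper lives at the
CLI); RCR = OXPHOS/LEAK.  The Mendelian goodness-of-fit test is the
χ² statistic against expected ratio weights (default 1:2:1) with df =
classes − 1; an exact multinomial tail (outcomes ordered by χ², ties
fully included) is available for totals ≤ 100.  Being discrete, the exact
p can differ from the χ² p by the tie-class mass (a few percent near
χ² = 0) even at totals around 50–100.

## Synthetic data

The generators produce data with the statistical structure the analyses
assume, plus ground truth for recovery tests.

**Transcriptome.**  UTR GC targets uniform on (0.2, 0.9); lengths
log-uniform on [10, 2000] bp; exactly `n_mito` transcripts (default 13,
the number of protein-coding genes on the mitochondrial genome) flagged
mitochondrial; a 5% subset carries a constructed TOP tract, and the
stored flag is re-derived from the sequence so flag and detector agree.
GC and length are drawn independently (they are treated as separate axes
downstream).  A mini genome is laid out alongside: alternating strands,
every third transcript's UTR split by a 50 bp intron, so the GTF/FASTA
round-trip exercises splicing and both strands.

**Polysome experiment.**  Control heavy-pool share
`p_t = logistic(α_t)`, `α_t ~ Normal(0, 0.75)`; knockdown logit shift
`δ_t = beta_gc·(GC_t − mean GC) + beta_mito·[mito] + Normal(0, noise_sd)`.
Each pooled sample is an independent library: expected counts are
`library_size` × within-sample relative abundance, drawn negative
binomial with variance `m + φm²`.  Ground truth is
`log2 ΔTE = δ_t / ln 2`, exact because TE equals the heavy/light odds at
equal library sizes.  A uniform global shift is absorbed by the
within-sample normalisation (both pools are renormalised to the library
size), so recovery experiments shift a subset (e.g. the mitochondrial
transcripts) against an unshifted background.

Depth and dispersion are free parameters of the generator, not estimates
of any particular dataset: defaults are 5e6 reads per pooled sample
(typical bulk RNA-seq order) and φ = 0.01 (biological coefficient of
variation 0.1, the conventional order for cell-line replicates).  The
analytic-recovery checks additionally use the Poisson limit (φ → 0)
because the logit/log2 identity is exact only without overdispersion.
`noise_sd_for_target_correlation` inverts the population correlation
formula `r = β·sd(GC) / sqrt(β²·sd(GC)² + noise²)` to choose the
transcript-level noise giving a desired GC–ΔTE correlation.

**Proteomics.**  Per-protein log2 abundance Normal(25, 2) with replicate
SD 0.3 (typical LFQ scales); an `effect_fraction` subset shifted by
`effect_size` log2 units (random sign) in group 2; dropout probability
`logistic((τ − x)/κ)` with τ = 21.5, κ = 0.8, so missingness concentrates
in the low-intensity tail (missing encoded as intensity 0, the MaxQuant
convention); four high-abundance histone anchors; organelle labels with
~5% dual localisation and ~5% unmapped; small fractions of decoy /
contaminant / site-only rows to exercise the filters.

**What passing tests do not show.**  The generators are deliberately
simple: no isoform ambiguity, positional/fragment bias or read-level
error in the RNA-seq arm; no peptide-level structure, shared-peptide
ambiguity or between-run normalisation drift in the proteomics arm;
effects are additive on the logit/log2 scales with Gaussian noise.
Recovery and calibration results therefore validate the estimators under
their own model assumptions, not robustness to the full messiness of
real datasets.

## Numerical choices

* Determinism: every stochastic routine takes an explicit seed; the
  generators derive independent streams from one master seed.
* Degenerate inputs raise typed errors (`InputError`, exit code 2;
  `ConfigError`, exit code 3) naming the offending field, rather than
  propagating NaNs; zero or undefined TE is flagged and excluded, not
  dropped.
* Values exactly at a shift threshold classify as `none` (strict
  inequalities).
* The problem sizes used by `scripts/acceptance.py` (2000–10 000
  transcripts, 2000 proteins, 20 null matrices, 2000 correlation
  replicates) are chosen so every recovery statistic has a Monte-Carlo
  error well inside the property bands it is checked against.
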