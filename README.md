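# ribomito

Tools for asking how ribosome programming shapes mitochondrial gene
expression, built for three kinds of data that usually meet in one study:
polysome-profiling RNA-seq, label-free (LFQ) proteomics, and small
physiological measurement tables.

It is aimed at analysts who have heavy/light polysome pool counts and
MaxQuant `proteinGroups` tables and want the standard derived statistics —
translational-efficiency scores, Perseus-style differential tests,
proteomic-ruler copy numbers, cardiac/metabolic indices — as tested,
scriptable functions rather than spreadsheet steps.

## What it computes

**Translational efficiency (TE).**  With transcripts pooled into a light
(≤ 3 ribosomes) and a heavy (> 3 ribosomes) polysome fraction, the TE
score of transcript *t* in a replicate is its relative abundance in the
heavy pool divided by its relative abundance in the light pool; condition
TE averages the replicate ratios, and the knockdown effect is
`Δ = log2(TE_kd / TE_ctrl)`, with |Δ| > 1 (TE doubled or halved) marking
shifted transcripts.  Downstream: binned feature profiles over Δ, the
Pearson test of Δ against 5'UTR GC content, subset analyses (e.g. the 13
mitochondrially encoded transcripts), and TOP-motif enrichment among
shifted transcripts — with the 5'UTR sequences themselves extracted
strand-aware from GTF + genome FASTA.

**Proteomics.**  The Perseus-equivalent stack for LFQ tables: QC
filtering, log2 transform, missing-not-at-random imputation from
`Normal(mean − 1.8·SD, (0.3·SD)²)` of the observed values, the
s0-moderated test `d = Δmean / (se + s0)` with permutation-based FDR,
histone-anchored proteomic-ruler absolute quantification
(`mass_i = intensity_i / Σ histone intensity × DNA mass`), and organelle
mass partitioning.

**Physiology.**  RER, energy expenditure (3.815·VO₂ + 1.232·VCO₂),
fractional shortening, relative wall thickness, Bazett QTc, respiratory
control ratio, and a χ²/exact test of genotype counts against a Mendelian
segregation ratio.

**Synthetic data.**  `ribomito.synth` simulates transcriptomes (with an
emittable mini genome FASTA + GTF), negative-binomial polysome count
matrices with a GC-dependent knockdown shift on the logit scale of the
heavy-pool share, and LFQ intensity matrices with intensity-dependent
dropout — each with ground truth, so every stage of the pipeline is
testable end to end without external downloads.  See `docs/methods.md`
for models, parameters and limitations.

## Worked example

Simulate a 2000-transcript experiment in which the knockdown disfavours
low-GC 5'UTRs (logit slope −1.0 per GC unit) and halves the TE of the 13
mitochondrially encoded transcripts (logit shift −ln 2), with
transcript-level noise:

```python
import math
from ribomito import synth, polysome, association

cfg = synth.SynthConfig(seed=7, n_transcripts=2000,
                        beta_gc=-1.0, beta_mito=-math.log(2),
                        noise_sd=0.5)
ts = synth.generate_transcriptome(cfg)
exp, truth = synth.simulate_polysome_experiment(ts, cfg)

te = polysome.change_in_te(polysome.compute_te(exp.counts, exp.sheet))
cls, counts = polysome.classify_te_shift(te.log2_change)
print("shift classes:", counts)

feats = ts.table.set_index("transcript_id")
est = te.log2_change.dropna()
print(association.pearson_test(feats["gc"].reindex(est.index).to_numpy(),
                               est.to_numpy()))

mito = feats["is_mito"].reindex(est.index)
res = association.subset_shift_summary(est.to_numpy(), mito.to_numpy())
print(f"mito median log2 dTE = {res.subset.median:.3f} "
      f"(fraction negative {res.subset.fraction_negative:.2f}), "
      f"Mann-Whitney p = {res.p:.2e}")
```

prints

```
shift classes: {'down': 225, 'up': 212, 'none': 1563}
Pearson r = -0.3960 (n = 2000), t = -19.275, p < 2.2e-16
mito median log2 dTE = -0.986 (fraction negative 0.92), Mann-Whitney p = 2.71e-05
```

Read: 225 transcripts lost more than half their TE; the negative Pearson
r says low-GC 5'UTRs are preferentially hit; and the mitochondrial subset
recovers its simulated ~50% TE reduction (median log2 change ≈ −1) and
separates from the rest of the transcriptome.

The same chains run from the shell:

```sh
ribomito simulate --seed 7 --n-transcripts 2000 --out sim/
ribomito te --counts sim/counts.tsv --samples sim/samples.tsv --out te.tsv
ribomito utr --gtf sim/annotation.gtf --fasta sim/genome.fa --out utr.tsv
ribomito associate --te-table te.tsv --utr-table utr.tsv --out profile.tsv
ribomito proteomics --protein-groups proteinGroups.tsv --s0 0.1 \
    --dna-mass-pg 6.5 --out differential.tsv
ribomito physio --measurements echo.tsv --out metrics.tsv
ribomito run --config config.yaml --out results/
```

Exit codes: 0 success, 2 input error, 3 configuration error.

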