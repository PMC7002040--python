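"""Synthetic data generation with known ground truth.

Three generators emulate the data types the downstream analyses consume:

* a small transcriptome with 5'UTR sequences (GC content, length, TOP
  motifs, a fixed number of mitochondrially-encoded transcripts) that can
  be written out as a mini genome FASTA + GTF;
* a polysome-profiling experiment — heavy/light pooled RNA-seq counts for
  two conditions (control and knockdown siRNA, three replicates each)
  where the knockdown shifts each transcript's heavy-polysome share on the
  logit scale as a function of 5'UTR GC and mitochondrial identity;
* a label-free proteomics intensity matrix (3 vs 3) with
  intensity-dependent (missing-not-at-random) dropout, histone anchor
  proteins for the proteomic ruler, and organelle labels.

Every generator is deterministic given ``SynthConfig.seed``.  The analytic
link used for ground truth is ``log2 TE = logit(heavy share) / ln 2``:
with equal library sizes the translational-efficiency score reduces to the
odds of a read sitting in the heavy pool, so a logit shift of delta is a
change in log2 TE of delta/ln 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigError
from .utr import detect_top_motif, gc_content, reverse_complement

MITO_PROTEIN_CODING_GENES = 13  # mitochondrial genome: 13 respiratory-complex subunits

LN2 = math.log(2.0)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic study.

    Transcriptome / polysome fields
    -------------------------------
    seed
        Master seed; every generator derives an independent stream from it.
    n_transcripts, n_mito
        Number of transcripts and how many of them are flagged as
        mitochondrially encoded (13 by default, the number of
        protein-coding genes on the mitochondrial genome).
    n_replicates
        Replicates per condition (3, matching the siRNA study design).
    library_size
        Expected reads per pooled sample (sequencing depth).
    nb_dispersion
        Negative-binomial dispersion phi, variance m + phi * m**2.
    beta_gc
        Logit-scale slope of the knockdown shift on centred 5'UTR GC.
    beta_mito
        Extra logit-scale shift applied to mitochondrial transcripts.
    noise_sd
        SD of transcript-level Gaussian noise added to the logit shift.
    top_fraction
        Fraction of transcripts built with a 5'TOP motif.
    baseline_logit_sd
        Spread of the control-condition heavy-share logits.
    simulate_subpolysomal
        Also emit a sub-polysomal pooled sample per replicate (collected
        by the assay but unused by the analyses).

    Proteomics fields
    -----------------
    groups, group_names
        Per-group replicate counts and labels (3 vs 3 by default).
    effect_fraction, effect_size
        Fraction of proteins truly changed in group 2 and the magnitude of
        that change in log2 units (random sign per protein).
    mnar_tau, mnar_kappa
        Midpoint and scale of the logistic missingness curve on the log2
        intensity axis: P(missing | x) = logistic((mnar_tau - x) / mnar_kappa).
    prot_base_mean, prot_base_sd, prot_rep_sd
        Between-protein mean/SD of log2 abundance and within-protein
        replicate SD.
    n_histones
        Number of histone anchor proteins (simulated as high abundance).
    """

    seed: int = 0
    # transcriptome
    n_transcripts: int = 2000
    n_mito: int = MITO_PROTEIN_CODING_GENES
    top_fraction: float = 0.05
    # polysome experiment
    n_replicates: int = 3
    library_size: float = 5e6
    nb_dispersion: float = 0.01
    beta_gc: float = 0.0
    beta_mito: float = 0.0
    noise_sd: float = 0.0
    baseline_logit_sd: float = 0.75
    simulate_subpolysomal: bool = False
    # proteomics
    n_proteins: int = 2000
    groups: tuple[int, int] = (3, 3)
    group_names: tuple[str, str] = ("control", "knockout")
    effect_fraction: float = 0.05
    effect_size: float = 1.0
    mnar_tau: float = 21.5
    mnar_kappa: float = 0.8
    prot_base_mean: float = 25.0
    prot_base_sd: float = 2.0
    prot_rep_sd: float = 0.3
    n_histones: int = 4
    organelles: tuple[str, ...] = (
        "mitochondrion", "nucleus", "cytosol", "endoplasmic reticulum",
    )

    def __post_init__(self):
        def bad(name, why):
            raise ConfigError(f"SynthConfig.{name}: {why}")

        if self.n_transcripts < 1:
            bad("n_transcripts", "must be >= 1")
        if self.n_mito < 0 or self.n_mito > self.n_transcripts:
            bad("n_mito", "must satisfy 0 <= n_mito <= n_transcripts")
        if self.n_replicates < 2:
            bad("n_replicates", "need at least 2 replicates per condition")
        if self.library_size <= 0:
            bad("library_size", "must be positive")
        if self.nb_dispersion <= 0:
            bad("nb_dispersion", "dispersion phi must be > 0")
        if self.noise_sd < 0:
            bad("noise_sd", "must be >= 0")
        if not 0 <= self.top_fraction <= 1:
            bad("top_fraction", "must be a fraction in [0, 1]")
        if self.n_proteins < 1:
            bad("n_proteins", "must be >= 1")
        if len(self.groups) != 2 or any(g < 2 for g in self.groups):
            bad("groups", "need two groups with >= 2 replicates each")
        if not 0 <= self.effect_fraction <= 1:
            bad("effect_fraction", "must be a fraction in [0, 1]")
        if self.mnar_kappa < 0:
            bad("mnar_kappa", "must be >= 0")
        if self.n_histones < 1:
            bad("n_histones", "the proteomic ruler needs >= 1 histone")

    def with_(self, **kw) -> "SynthConfig":
        return replace(self, **kw)


@dataclass
class TrueEffects:
    """Ground truth of a simulation: one row per feature.

    ``table`` columns for a polysome experiment: transcript_id,
    true_log2_dte, affected; for proteomics: protein_id, true_log2_fc,
    affected.
    """

    table: pd.DataFrame

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _rng(cfg: SynthConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, stream)))


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    if length == 0:
        return ""
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=probs))


# ---------------------------------------------------------------------------
# transcriptome


@dataclass
class TranscriptSet:
    """Per-transcript annotation plus the mini genome it was laid out on.

    ``table`` columns: transcript_id, utr_sequence, utr_length, gc,
    is_top, is_mito.  ``gc`` is the realised GC fraction of the stored UTR
    sequence.  ``genome`` maps chromosome name to sequence and ``gtf``
    holds the exon/CDS features (1-based inclusive) so the set round-trips
    through a GTF/FASTA extractor.
    """

    table: pd.DataFrame
    genome: dict[str, str] = field(default_factory=dict)
    gtf: pd.DataFrame | None = None

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_gtf(self, path) -> None:
        if self.gtf is None:
            raise ConfigError("TranscriptSet has no genome layout to write")
        with open(path, "w") as fh:
            for row in self.gtf.itertuples(index=False):
                attrs = (f'gene_id "{row.transcript_id}_g"; '
                         f'transcript_id "{row.transcript_id}";')
                fh.write("\t".join([
                    row.chrom, "ribomito", row.feature,
                    str(row.start), str(row.end), ".", row.strand, ".", attrs,
                ]) + "\n")

    def write_utr_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for row in self.table.itertuples(index=False):
                fh.write(f">{row.transcript_id}\n{row.utr_sequence}\n")


def _build_cds(rng: np.random.Generator, n_codons: int = 10) -> str:
    body = "".join(rng.choice(_BASES, size=3 * n_codons))
    return "ATG" + body + "TAA"


def generate_transcriptome(cfg: SynthConfig) -> TranscriptSet:
    """Draw a transcriptome with UTR GC ~ U(0.2, 0.9) and UTR lengths
    log-uniform on [10, 2000].

    Exactly ``cfg.n_mito`` transcripts (the first ones, ids ``MT-T0001``…)
    are flagged mitochondrial.  A ``cfg.top_fraction`` subset of the
    nuclear transcripts is built with a leading TOP motif; the stored
    ``is_top`` flag is re-derived from the sequence with
    :func:`ribomito.utr.detect_top_motif`, so flag and detector agree by
    construction.  A mini genome is laid out at the same time: every third
    transcript has its UTR split across two exons by a 50 bp intron, and
    alternating transcripts sit on the minus strand, so the GTF/FASTA
    round-trip exercises splicing and strand handling.
    """
    rng = _rng(cfg, 0)
    n = cfg.n_transcripts
    gc_target = rng.uniform(0.2, 0.9, size=n)
    lengths = np.exp(rng.uniform(np.log(10), np.log(2000), size=n)).astype(int)
    lengths = np.clip(lengths, 10, 2000)
    is_mito = np.zeros(n, dtype=bool)
    is_mito[: cfg.n_mito] = True
    want_top = (~is_mito) & (rng.uniform(size=n) < cfg.top_fraction)

    ids, seqs = [], []
    for i in range(n):
        tid = f"MT-T{i + 1:04d}" if is_mito[i] else f"T{i + 1:05d}"
        seq = _random_seq(rng, int(lengths[i]), gc_target[i])
        if want_top[i]:
            run = int(rng.integers(4, 9))
            tract = "C" + "".join(rng.choice(["C", "T"], size=run)) + "A"
            seq = tract + seq[len(tract):]
        ids.append(tid)
        seqs.append(seq)

    table = pd.DataFrame({
        "transcript_id": ids,
        "utr_sequence": seqs,
        "utr_length": [len(s) for s in seqs],
        "gc": [gc_content(s) for s in seqs],
        "is_top": [detect_top_motif(s) for s in seqs],
        "is_mito": is_mito,
    })

    # --- genome layout ---------------------------------------------------
    chrom = "chrS"
    genome_parts: list[str] = []
    gtf_rows: list[dict] = []
    pos = 0  # 0-based cursor into the chromosome

    def add_piece(seq: str) -> tuple[int, int]:
        nonlocal pos
        genome_parts.append(seq)
        start, end = pos, pos + len(seq)
        pos = end
        return start, end

    for i, (tid, utr) in enumerate(zip(ids, seqs)):
        strand = "+" if i % 2 == 0 else "-"
        cds = _build_cds(rng)
        split = i % 3 == 0 and len(utr) >= 20
        if split:
            m = len(utr) // 2
            intron = _random_seq(rng, 50, 0.5)
            tx_pieces = [("exon", utr[:m]), ("intron", intron),
                         ("exon", utr[m:] + cds)]
        else:
            tx_pieces = [("exon", utr + cds)]
        # transcript-orientation genomic segment
        seg = "".join(p for _, p in tx_pieces)
        if strand == "-":
            seg = reverse_complement(seg)
        add_piece(_random_seq(rng, 20, 0.5))  # spacer
        seg_start, _seg_end = add_piece(seg)
        seg_len = len(seg)

        # exon intervals in transcript orientation (offsets within seg)
        off = 0
        exon_offsets = []
        for kind, p in tx_pieces:
            if kind == "exon":
                exon_offsets.append((off, off + len(p)))
            off += len(p)
        cds_off = (off - len(cds), off)  # CDS occupies the tail of the last exon

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return seg_start + a, seg_start + b
            return seg_start + seg_len - b, seg_start + seg_len - a

        for a, b in exon_offsets:
            gs, ge = to_genomic(a, b)
            gtf_rows.append(dict(chrom=chrom, feature="exon",
                                 start=gs + 1, end=ge, strand=strand,
                                 transcript_id=tid))
        gs, ge = to_genomic(*cds_off)
        gtf_rows.append(dict(chrom=chrom, feature="CDS",
                             start=gs + 1, end=ge, strand=strand,
                             transcript_id=tid))

    genome = {chrom: "".join(genome_parts)}
    gtf = pd.DataFrame(gtf_rows).sort_values(
        ["chrom", "start", "end"]).reset_index(drop=True)
    return TranscriptSet(table=table, genome=genome, gtf=gtf)


# ---------------------------------------------------------------------------
# polysome experiment


@dataclass
class PolysomeExperiment:
    """Pooled-count matrix plus its sample sheet.

    ``counts``: transcripts x samples (integer); ``sheet`` columns:
    sample_id, condition, replicate, pool.
    """

    counts: pd.DataFrame
    sheet: pd.DataFrame
    true_effects: TrueEffects | None = None

    def write_counts(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="transcript_id")

    def write_sheet(self, path) -> None:
        self.sheet.to_csv(path, sep="\t", index=False)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) with variance mean + phi * mean**2 (gamma-Poisson)."""
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def simulate_polysome_experiment(
    ts: TranscriptSet, cfg: SynthConfig
) -> tuple[PolysomeExperiment, TrueEffects]:
    """Simulate heavy/light pooled counts for control and knockdown.

    Control heavy share: p_t = logistic(alpha_t) with alpha_t ~
    Normal(0, baseline_logit_sd).  Knockdown logit shift:
    delta_t = beta_gc * (GC_t - mean GC) + beta_mito * [mito]
    + Normal(0, noise_sd).  Each pooled sample is an independent
    sequencing library: expected counts are ``library_size`` times the
    within-sample relative abundance, drawn NB(mean, phi).  Ground truth
    is ``true_log2_dte = delta_t / ln 2`` (TE equals the heavy/light odds
    at equal library sizes).
    """
    if len(ts.table) == 0:
        raise ConfigError("TranscriptSet is empty")
    rng = _rng(cfg, 1)
    tab = ts.table
    n = len(tab)
    gc = tab["gc"].to_numpy(float)
    is_mito = tab["is_mito"].to_numpy(bool)

    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n)
    w = abundance / abundance.sum()
    alpha = rng.normal(0.0, cfg.baseline_logit_sd, size=n)
    delta_det = cfg.beta_gc * (gc - gc.mean()) + cfg.beta_mito * is_mito
    delta = delta_det + (rng.normal(0.0, cfg.noise_sd, size=n)
                         if cfg.noise_sd > 0 else 0.0)

    p = {"control": expit(alpha), "knockdown": expit(alpha + delta)}

    cols, sheet_rows = {}, []
    pools = ["heavy", "light"] + (
        ["subpolysomal"] if cfg.simulate_subpolysomal else [])
    for cond in ("control", "knockdown"):
        for rep in range(1, cfg.n_replicates + 1):
            for pool in pools:
                if pool == "heavy":
                    mass = w * p[cond]
                elif pool == "light":
                    mass = w * (1.0 - p[cond])
                else:
                    mass = w
                mean = cfg.library_size * mass / mass.sum()
                sid = f"{cond}_{rep}_{pool}"
                cols[sid] = _nb_draw(rng, mean, cfg.nb_dispersion)
                sheet_rows.append(dict(sample_id=sid, condition=cond,
                                       replicate=rep, pool=pool))

    counts = pd.DataFrame(cols, index=tab["transcript_id"])
    sheet = pd.DataFrame(sheet_rows)
    truth = TrueEffects(pd.DataFrame({
        "transcript_id": tab["transcript_id"],
        "true_log2_dte": delta / LN2,
        "affected": delta_det != 0.0,
    }))
    return PolysomeExperiment(counts=counts, sheet=sheet, true_effects=truth), truth


def noise_sd_for_target_correlation(
    beta_gc: float, target_r: float, gc_sd: float = 0.7 / math.sqrt(12.0)
) -> float:
    """Noise SD giving a population GC/log2-dTE correlation of ``target_r``.

    With delta = beta_gc * (GC - mean) + eps, the population correlation is
    beta_gc * sd(GC) / sqrt(beta_gc**2 sd(GC)**2 + noise_sd**2) (the 1/ln 2
    scaling cancels).  Solving for noise_sd requires
    |target_r| <= 1 and sign(target_r) == sign(beta_gc).
    """
    if target_r == 0 or beta_gc == 0:
        raise ConfigError("target_r and beta_gc must be nonzero")
    if np.sign(target_r) != np.sign(beta_gc):
        raise ConfigError("target_r and beta_gc must share a sign")
    if abs(target_r) > 1:
        raise ConfigError("|target_r| must be <= 1")
    signal_var = (beta_gc * gc_sd) ** 2
    total_var = signal_var / target_r ** 2
    return math.sqrt(total_var - signal_var)


# ---------------------------------------------------------------------------
# proteomics


@dataclass
class ProteinGroups:
    """Protein-group table in the MaxQuant dialect used downstream.

    ``table`` columns: protein_id, gene_name, mol_weight_kda, is_histone,
    localisation (';'-separated, may be empty), go_terms (';'-separated),
    reverse / contaminant / site_only booleans, and one nonnegative
    intensity column per sample (0 encodes a missing value).
    """

    table: pd.DataFrame
    intensity_cols: list[str]

    @property
    def intensities(self) -> pd.DataFrame:
        return self.table.set_index("protein_id")[self.intensity_cols]

    def sample_groups(self) -> dict[str, str]:
        """sample column -> group label, parsed from the column naming."""
        return {c: c.rsplit("_", 1)[0] for c in self.intensity_cols}


def simulate_proteomics(cfg: SynthConfig) -> tuple[ProteinGroups, TrueEffects]:
    """Simulate a label-free intensity matrix with MNAR dropout.

    Log2 intensities are Normal per protein; an ``effect_fraction`` subset
    is shifted by ``effect_size`` (random sign) in group 2.  A value is
    missing with probability logistic((mnar_tau - x) / mnar_kappa), i.e.
    low-abundance values drop out preferentially; missing values are
    encoded as intensity 0.  The first ``n_histones`` proteins are histone
    anchors (high abundance, never affected); organelle labels are drawn
    from ``cfg.organelles`` with ~5% dual localisation and ~5% unmapped.
    """
    rng = _rng(cfg, 2)
    n = cfg.n_proteins
    n1, n2 = cfg.groups
    g1, g2 = cfg.group_names

    is_histone = np.zeros(n, dtype=bool)
    is_histone[: cfg.n_histones] = True

    mu = rng.normal(cfg.prot_base_mean, cfg.prot_base_sd, size=n)
    mu[is_histone] = cfg.prot_base_mean + 2.5 * cfg.prot_base_sd

    affected = (~is_histone) & (rng.uniform(size=n) < cfg.effect_fraction)
    sign = rng.choice([-1.0, 1.0], size=n)
    log2_fc = np.where(affected, sign * cfg.effect_size, 0.0)

    cols = {}
    sample_names = [f"{g1}_{r + 1}" for r in range(n1)] + \
                   [f"{g2}_{r + 1}" for r in range(n2)]
    for j, sname in enumerate(sample_names):
        shift = log2_fc if j >= n1 else 0.0
        x = mu + shift + rng.normal(0.0, cfg.prot_rep_sd, size=n)
        if cfg.mnar_kappa > 0:
            p_miss = expit((cfg.mnar_tau - x) / cfg.mnar_kappa)
        else:
            p_miss = (x < cfg.mnar_tau).astype(float)
        missing = rng.uniform(size=n) < p_miss
        intensity = np.where(missing, 0.0, 2.0 ** x)
        cols[sname] = intensity

    mw = np.round(rng.lognormal(np.log(40.0), 0.5, size=n), 2)
    mw[is_histone] = np.round(rng.uniform(11.0, 15.0, size=cfg.n_histones), 2)

    organelles = list(cfg.organelles)
    loc_idx = rng.integers(0, len(organelles), size=n)
    localisation = []
    for i in range(n):
        u = rng.uniform()
        if u < 0.05:
            localisation.append("")  # unmapped
        elif u < 0.10:
            other = organelles[(loc_idx[i] + 1) % len(organelles)]
            localisation.append(f"{organelles[loc_idx[i]]};{other}")
        else:
            localisation.append(organelles[loc_idx[i]])

    go_terms = np.where(rng.uniform(size=n) < 0.01, "blood microparticle", "")
    reverse = rng.uniform(size=n) < 0.02
    contaminant = rng.uniform(size=n) < 0.02
    site_only = rng.uniform(size=n) < 0.02
    for flag in (reverse, contaminant, site_only):
        flag[is_histone] = False

    ids = [f"H{i + 1:04d}" if is_histone[i] else f"P{i + 1:05d}"
           for i in range(n)]
    genes = [f"HIST{i + 1}" if is_histone[i] else f"GENE{i + 1:05d}"
             for i in range(n)]
    table = pd.DataFrame({
        "protein_id": ids, "gene_name": genes, "mol_weight_kda": mw,
        "is_histone": is_histone, "localisation": localisation,
        "go_terms": go_terms, "reverse": reverse,
        "contaminant": contaminant, "site_only": site_only, **cols,
    })
    truth = TrueEffects(pd.DataFrame({
        "protein_id": ids, "true_log2_fc": log2_fc, "affected": affected,
    }))
    return ProteinGroups(table=table, intensity_cols=sample_names), truth
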