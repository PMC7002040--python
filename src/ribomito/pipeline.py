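"""End-to-end analysis chains with provenance logging.

Two chains mirror the study design:

* ``te``: simulate (or load) a polysome experiment, compute per-transcript
  TE and its change, join 5'UTR features, and run the association tests;
* ``proteomics``: simulate (or load) a protein-groups table, filter,
  log2-transform, impute, run the s0 permutation test, and apply the
  proteomic ruler with organelle mass partitioning.

Every stage's parameters, seeds and record counts are written to a run
manifest so identical config + seed reproduces identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__, association, io, polysome, proteomics, synth
from .errors import ConfigError, InputError

log = logging.getLogger("ribomito")


def _manifest_base(config: dict) -> dict:
    return {
        "ribomito_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "config": config,
        "stages": {},
    }


def run_te_chain(config: dict, out_dir: Path) -> dict:
    """Synthetic polysome experiment -> TE -> UTR features -> association."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_base(config)
    cfg = synth.SynthConfig(**config.get("synth", {}))

    ts = synth.generate_transcriptome(cfg)
    exp, truth = synth.simulate_polysome_experiment(ts, cfg)
    exp.write_counts(out_dir / "counts.tsv")
    exp.write_sheet(out_dir / "samples.tsv")
    truth.write_tsv(out_dir / "true_effects.tsv")
    ts.write_gtf(out_dir / "annotation.gtf")
    ts.write_fasta(out_dir / "genome.fa")
    manifest["stages"]["simulate"] = {
        "seed": cfg.seed, "n_transcripts": cfg.n_transcripts,
        "n_samples": exp.counts.shape[1],
    }
    log.info("simulated %d transcripts, %d samples",
             cfg.n_transcripts, exp.counts.shape[1])

    te_params = config.get("te", {})
    te = polysome.compute_te(exp.counts, exp.sheet, **te_params)
    te = polysome.change_in_te(te)
    cls, counts = polysome.classify_te_shift(
        te.log2_change, threshold=config.get("shift_threshold", 1.0))
    te.shift_class = cls
    te.write_tsv(out_dir / "te.tsv")
    manifest["stages"]["te"] = {
        **te.params, "n_scored": int(len(te.te_mean)),
        "n_dropped_low_count": len(te.dropped_low_count),
        "n_undefined": len(te.undefined), "shift_counts": counts,
    }
    log.info("TE scored for %d transcripts (%d dropped, %d undefined)",
             len(te.te_mean), len(te.dropped_low_count), len(te.undefined))

    feats = ts.table.set_index("transcript_id")
    joined = te.to_frame().join(feats, how="inner").dropna(
        subset=["log2_change", "gc"])
    manifest["stages"]["utr_join"] = {"n_joined": int(len(joined))}

    corr = association.pearson_test(joined["gc"], joined["log2_change"])
    profile = association.bin_profile(
        joined["log2_change"], joined["gc"],
        window=config.get("bin_window", 0.5))
    profile.to_csv(out_dir / "gc_profile.tsv", sep="\t", index=False)
    mito = association.subset_shift_summary(
        joined["log2_change"], joined["is_mito"])
    top_shift = joined["shift_class"] == "down"
    enr = association.enrichment_2x2(
        int((joined["is_top"] & top_shift).sum()),
        int(joined["is_top"].sum()),
        int(top_shift.sum()), int(len(joined)))
    report = {
        "pearson_r": corr.r, "pearson_n": corr.n, "pearson_p": corr.p,
        "mito_median_dte": mito.subset.median,
        "mito_fraction_negative": mito.subset.fraction_negative,
        "mito_vs_rest_p": mito.p,
        "top_enrichment_odds": enr.odds_ratio,
        "top_enrichment_p": enr.p_two_sided,
    }
    pd.DataFrame([report]).to_csv(out_dir / "association.tsv",
                                  sep="\t", index=False)
    manifest["stages"]["association"] = report
    _write_manifest(manifest, out_dir)
    return manifest


def run_proteomics_chain(config: dict, out_dir: Path) -> dict:
    """Synthetic proteinGroups -> filter -> impute -> test -> ruler."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_base(config)
    cfg = synth.SynthConfig(**config.get("synth", {}))

    pg, truth = synth.simulate_proteomics(cfg)
    io.write_protein_groups(pg, out_dir / "proteinGroups.tsv")
    truth.write_tsv(out_dir / "true_effects.tsv")
    manifest["stages"]["simulate"] = {
        "seed": cfg.seed, "n_proteins": cfg.n_proteins,
        "groups": list(cfg.groups),
    }

    design = pg.sample_groups()
    filt, removed = proteomics.filter_protein_groups(
        pg, design, max_zeros=config.get("max_zeros", 3))
    manifest["stages"]["filter"] = {
        "removed": removed, "n_kept": int(len(filt.table))}
    log.info("filtering removed %s", removed)

    logmat = proteomics.log2_transform(filt.intensities)
    imp = proteomics.impute_downshifted(
        logmat, seed=cfg.seed,
        width=config.get("impute_width", 0.3),
        shift=config.get("impute_shift", 1.8))
    manifest["stages"]["impute"] = {
        "fraction_imputed": imp.fraction_imputed,
        "width": config.get("impute_width", 0.3),
        "shift": config.get("impute_shift", 1.8),
    }

    diff = proteomics.s0_permutation_test(
        imp.matrix, design, s0=config.get("s0", 0.1),
        n_perm=config.get("n_perm", 250),
        fdr=config.get("fdr", 0.05), seed=cfg.seed)
    diff.write_tsv(out_dir / "differential.tsv")
    manifest["stages"]["s0_test"] = {
        "s0": diff.s0, "n_permutations": diff.n_permutations,
        "n_significant": int(diff.table["significant"].sum()),
        "n_up": int((diff.table["significant"]
                     & (diff.table["log2_fc"] > 0)).sum()),
        "n_down": int((diff.table["significant"]
                       & (diff.table["log2_fc"] < 0)).sum()),
    }

    tab = filt.table.set_index("protein_id")
    mean_intensity = tab[filt.intensity_cols].mean(axis=1)
    ruler = proteomics.proteomic_ruler(
        mean_intensity, tab["mol_weight_kda"], tab["is_histone"],
        dna_mass_pg=config.get("dna_mass_pg", 6.5))
    fractions = proteomics.organelle_mass_fractions(
        ruler.mass_pg, tab["localisation"])
    pd.DataFrame({"mass_pg": ruler.mass_pg,
                  "copies": ruler.copies}).to_csv(
        out_dir / "ruler.tsv", sep="\t", index_label="protein_id")
    fractions.rename("mass_percent").to_csv(
        out_dir / "organelle_mass.tsv", sep="\t", index_label="compartment")
    manifest["stages"]["ruler"] = {
        "total_mass_pg": ruler.total_mass_pg,
        "dna_mass_pg": ruler.dna_mass_pg,
        "n_skipped": len(ruler.skipped),
        "mass_percent": fractions.to_dict(),
    }
    _write_manifest(manifest, out_dir)
    return manifest


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the chain(s) named in ``config["chain"]`` ("te", "proteomics"
    or "both")."""
    chain = config.get("chain", "both")
    if chain not in ("te", "proteomics", "both"):
        raise ConfigError(f"chain: unknown value {chain!r}")
    out_dir = Path(out_dir)
    manifests = {}
    try:
        if chain in ("te", "both"):
            manifests["te"] = run_te_chain(config, out_dir / "te")
        if chain in ("proteomics", "both"):
            manifests["proteomics"] = run_proteomics_chain(
                config, out_dir / "proteomics")
    except (InputError, ConfigError):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline chain {chain!r} failed: {exc}") from exc
    return manifests


def _write_manifest(manifest: dict, out_dir: Path) -> None:
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
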