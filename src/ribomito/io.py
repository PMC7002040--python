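"""Tabular readers and writers.

TSV is the universal interchange format (matching the MaxQuant / Perseus
ecosystem); FASTA and GTF cover sequence and annotation.  The MaxQuant
proteinGroups dialect is configurable through :class:`PGDialect`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .errors import InputError
from .synth import ProteinGroups


def read_counts(path) -> pd.DataFrame:
    """Read a transcript x sample count matrix.

    First column is the transcript id; remaining columns must be integer
    counts.  Duplicate ids and empty files are rejected.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty count table") from None
    if df.empty and df.columns.empty:
        raise InputError(f"{path}: empty count table")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise InputError(f"{path}: duplicate transcript id {dup!r}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() | (converted != converted.round())
        if bad.any():
            row = df.index[bad][0]
            raise InputError(
                f"{path}: non-integer count at row {row!r}, column {col!r}")
        df[col] = converted.astype(int)
    return df


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id")


def read_sample_sheet(path) -> pd.DataFrame:
    try:
        sheet = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty sample sheet") from None
    return sheet


def read_table(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty table") from None


@dataclass(frozen=True)
class PGDialect:
    """Column naming of a proteinGroups-style TSV.

    Flag columns use "+" for true (the MaxQuant convention); intensity
    columns are found by prefix.  ``histone_pattern`` classifies histone
    anchor proteins from the gene name.
    """

    id_col: str = "Protein IDs"
    gene_col: str = "Gene names"
    mw_col: str = "Mol. weight [kDa]"
    reverse_col: str = "Reverse"
    contaminant_col: str = "Potential contaminant"
    site_col: str = "Only identified by site"
    go_col: str = "Gene ontology (GO)"
    localisation_col: str = "Subcellular localisation"
    intensity_prefix: str = "LFQ intensity "
    histone_pattern: str = r"(?i)^HIST|^H1-\d|^H2A|^H2B|^H3|^H4"


def read_protein_groups(path, dialect: PGDialect = PGDialect()) -> ProteinGroups:
    """Parse a proteinGroups-dialect TSV into a :class:`ProteinGroups`.

    "+" flags become booleans, absent intensities become 0, and optional
    columns (GO terms, localisation) default to empty strings.
    """
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty protein groups table") from None
    for col in (dialect.id_col, dialect.mw_col):
        if col not in raw.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    intensity_raw = [c for c in raw.columns
                     if c.startswith(dialect.intensity_prefix)]
    if not intensity_raw:
        raise InputError(
            f"{path}: no columns with intensity prefix "
            f"{dialect.intensity_prefix!r}")

    def flag(col: str) -> pd.Series:
        if col not in raw.columns:
            return pd.Series(False, index=raw.index)
        return raw[col].fillna("").str.strip() == "+"

    def text(col: str) -> pd.Series:
        if col not in raw.columns:
            return pd.Series("", index=raw.index)
        return raw[col].fillna("")

    genes = text(dialect.gene_col)
    pat = re.compile(dialect.histone_pattern)
    table = pd.DataFrame({
        "protein_id": raw[dialect.id_col],
        "gene_name": genes,
        "mol_weight_kda": pd.to_numeric(raw[dialect.mw_col], errors="raise"),
        "is_histone": genes.map(lambda g: bool(pat.search(g)) if g else False),
        "localisation": text(dialect.localisation_col),
        "go_terms": text(dialect.go_col),
        "reverse": flag(dialect.reverse_col),
        "contaminant": flag(dialect.contaminant_col),
        "site_only": flag(dialect.site_col),
    })
    sample_names = []
    for col in intensity_raw:
        sample = col[len(dialect.intensity_prefix):]
        vals = pd.to_numeric(raw[col], errors="coerce").fillna(0.0)
        if (vals < 0).any():
            raise InputError(f"{path}: negative intensity in column {col!r}")
        table[sample] = vals
        sample_names.append(sample)
    return ProteinGroups(table=table, intensity_cols=sample_names)


def write_protein_groups(pg: ProteinGroups, path,
                         dialect: PGDialect = PGDialect()) -> None:
    tab = pg.table
    out = pd.DataFrame({
        dialect.id_col: tab["protein_id"],
        dialect.gene_col: tab["gene_name"],
        dialect.mw_col: tab["mol_weight_kda"],
        dialect.go_col: tab["go_terms"],
        dialect.localisation_col: tab["localisation"],
        dialect.reverse_col: tab["reverse"].map({True: "+", False: ""}),
        dialect.contaminant_col: tab["contaminant"].map({True: "+", False: ""}),
        dialect.site_col: tab["site_only"].map({True: "+", False: ""}),
    })
    for sample in pg.intensity_cols:
        out[dialect.intensity_prefix + sample] = tab[sample]
    out.to_csv(path, sep="\t", index=False)


def read_localisation_map(path) -> pd.Series:
    """protein_id -> ';'-separated compartment labels."""
    df = read_table(path)
    if df.shape[1] < 2:
        raise InputError(f"{path}: need protein_id and compartment columns")
    return df.set_index(df.columns[0])[df.columns[1]].fillna("")


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
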