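"""Label-free proteomics statistics.

A from-scratch implementation of the standard Perseus-style pipeline for
MaxQuant proteinGroups tables:

1.  filtering (decoy / contaminant / identified-by-site rows, rows with
    too many zero intensities, rows carrying excluded GO terms);
2.  log2 transformation with zeros treated as missing;
3.  missing-not-at-random imputation from a width-shrunk, down-shifted
    normal distribution fitted to the observed values;
4.  an s0-moderated t-test with permutation-based FDR (the SAM / Perseus
    convention: s0 is added to the standard error in the denominator, and
    the FDR at a symmetric threshold is the mean permuted exceedance count
    over the observed one);
5.  proteomic-ruler absolute quantification (histone MS signal is assumed
    to equal cellular DNA mass) and partitioning of total protein mass
    across subcellular compartments.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .synth import ProteinGroups

AVOGADRO = 6.02214076e23
MEAN_BP_MASS_DA = 615.8771  # average mass of a DNA base pair


# ---------------------------------------------------------------------------
# filtering and transformation


def filter_protein_groups(
    pg: ProteinGroups,
    group_design: dict[str, str] | None = None,
    max_zeros: int = 3,
    excluded_go: frozenset[str] | set[str] = frozenset({"blood microparticle"}),
) -> tuple[ProteinGroups, dict[str, int]]:
    """Apply the standard QC filters in a fixed, audited order.

    Order: decoy/contaminant/site-only flags, then GO-term exclusion, then
    the zero-count rule (rows with more than ``max_zeros`` zero intensities
    counted across all samples).  Returns the filtered table and the number
    of rows removed by each rule, keyed in application order.
    """
    if group_design is not None:
        unknown = set(group_design) - set(pg.intensity_cols)
        if unknown:
            raise InputError(f"unknown samples in design: {sorted(unknown)}")
        lacking = set(pg.intensity_cols) - set(group_design)
        if lacking:
            raise InputError(
                f"design does not cover samples: {sorted(lacking)}")
    tab = pg.table
    removed: dict[str, int] = {}

    flagged = tab["reverse"] | tab["contaminant"] | tab["site_only"]
    removed["decoy_contaminant_site"] = int(flagged.sum())
    tab = tab[~flagged]

    if excluded_go:
        def has_excluded(terms: str) -> bool:
            return any(t.strip() in excluded_go
                       for t in str(terms).split(";") if t.strip())
        go_hit = tab["go_terms"].map(has_excluded)
        removed["excluded_go"] = int(go_hit.sum())
        tab = tab[~go_hit]
    else:
        removed["excluded_go"] = 0

    zeros = (tab[pg.intensity_cols] == 0).sum(axis=1)
    too_many = zeros > max_zeros
    removed["too_many_zeros"] = int(too_many.sum())
    tab = tab[~too_many]

    return ProteinGroups(table=tab.reset_index(drop=True),
                         intensity_cols=list(pg.intensity_cols)), removed


def log2_transform(intensities: pd.DataFrame) -> pd.DataFrame:
    """log2 of positive intensities; zeros become NaN (missing).

    Negative intensities are rejected.
    """
    if (intensities < 0).any().any():
        raise InputError("intensities must be nonnegative")
    return pd.DataFrame(
        np.where(intensities > 0, np.log2(np.where(intensities > 0,
                                                   intensities, 1.0)), np.nan),
        index=intensities.index, columns=intensities.columns)


# ---------------------------------------------------------------------------
# imputation


@dataclass
class ImputationResult:
    matrix: pd.DataFrame
    mask: pd.DataFrame  # True where a value was imputed
    fraction_imputed: float


def impute_downshifted(matrix: pd.DataFrame, width: float = 0.3,
                       shift: float = 1.8, scope: str = "per_sample",
                       seed: int | None = 0) -> ImputationResult:
    """Replace missing values by draws from a down-shifted normal.

    Each missing cell is drawn from
    ``Normal(mean_obs - shift * sd_obs, (width * sd_obs)**2)`` where the
    mean and SD are computed from the observed values of its scope —
    per column (``per_sample``, the Perseus default) or over the whole
    matrix (``global``).  Returns the imputed matrix, a boolean mask of
    imputed cells, and the fraction of cells imputed.
    """
    if width <= 0 or shift < 0:
        raise ConfigError("width must be > 0 and shift >= 0")
    if scope not in ("per_sample", "global"):
        raise ConfigError(f"scope: unknown value {scope!r}")
    rng = np.random.default_rng(seed)
    mat = matrix.to_numpy(dtype=float, copy=True)
    miss = np.isnan(mat)
    if scope == "global":
        obs = mat[~miss]
        if obs.size < 2:
            raise InputError("fewer than 2 observed values; filter first")
        mu, sd = obs.mean(), obs.std(ddof=1)
        mat[miss] = rng.normal(mu - shift * sd, width * sd, size=int(miss.sum()))
    else:
        for j in range(mat.shape[1]):
            col_miss = miss[:, j]
            obs = mat[~col_miss, j]
            if col_miss.any() and obs.size < 2:
                raise InputError(
                    f"column {matrix.columns[j]!r} has fewer than 2 observed "
                    "values; filter first")
            if col_miss.any():
                mu, sd = obs.mean(), obs.std(ddof=1)
                mat[col_miss, j] = rng.normal(
                    mu - shift * sd, width * sd, size=int(col_miss.sum()))
    return ImputationResult(
        matrix=pd.DataFrame(mat, index=matrix.index, columns=matrix.columns),
        mask=pd.DataFrame(miss, index=matrix.index, columns=matrix.columns),
        fraction_imputed=float(miss.mean()),
    )


# ---------------------------------------------------------------------------
# s0-moderated permutation test


def _group_stats(mat: np.ndarray, idx1: np.ndarray, idx2: np.ndarray,
                 s0: float, variance: str) -> tuple[np.ndarray, np.ndarray]:
    """(log2 fold change, moderated d statistic) for one labelling."""
    g1, g2 = mat[:, idx1], mat[:, idx2]
    n1, n2 = g1.shape[1], g2.shape[1]
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1 = g1.var(axis=1, ddof=1)
    v2 = g2.var(axis=1, ddof=1)
    if variance == "welch":
        se = np.sqrt(v1 / n1 + v2 / n2)
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    fc = m2 - m1
    return fc, fc / (se + s0)


def _permutation_labelings(n1: int, n2: int, n_perm: int,
                           rng: np.random.Generator) -> list[np.ndarray]:
    """Distinct relabelings (as index arrays for pseudo-group 1).

    The identity labelling and its mirror are excluded so that genuine
    effects do not contaminate the null.  If the remaining labelings are
    no more than ``n_perm`` they are all used; otherwise ``n_perm`` are
    sampled without replacement.
    """
    n = n1 + n2
    all_idx = frozenset(range(n))
    identity = tuple(range(n1))
    mirror = tuple(sorted(all_idx - set(identity)))[:n1] if n1 == n2 else None
    combos = [c for c in combinations(range(n), n1)
              if c != identity and (mirror is None or c != mirror)]
    if len(combos) > n_perm:
        pick = rng.choice(len(combos), size=n_perm, replace=False)
        combos = [combos[i] for i in sorted(pick)]
    return [np.array(c, dtype=int) for c in combos]


@dataclass
class DifferentialResult:
    """Per-protein differential-abundance calls.

    ``table`` columns: log2_fc (group2 - group1 means), d (s0-moderated
    statistic), q (permutation FDR), significant (q < fdr threshold).
    """

    table: pd.DataFrame
    s0: float
    fdr: float
    n_permutations: int
    params: dict = field(default_factory=dict)

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="protein_id")


def s0_permutation_test(matrix: pd.DataFrame, group_design: dict[str, str],
                        s0: float = 0.1, n_perm: int = 250,
                        fdr: float = 0.05, variance: str = "welch",
                        seed: int | None = 0) -> DifferentialResult:
    """s0-moderated two-group test with permutation-based FDR.

    ``d_i = (mean2 - mean1) / (se_i + s0)`` with the standard error from
    the Welch (default) or pooled variance model.  Null statistics come
    from relabelings of the sample columns; for a symmetric threshold t,
    ``FDR(t) = mean_perm #{|d*| >= t} / #{|d| >= t}`` capped at 1, and
    ``q_i`` is the minimum FDR over thresholds t <= |d_i| (so q is
    monotone non-increasing in |d|).  pi0 is fixed at 1 (conservative).
    """
    if s0 < 0:
        raise ConfigError("s0: must be >= 0")
    if variance not in ("welch", "pooled"):
        raise ConfigError(f"variance: unknown model {variance!r}")
    if not 0 < fdr < 1:
        raise ConfigError("fdr: must be in (0, 1)")
    if matrix.isna().any().any():
        raise InputError("matrix contains missing values; impute first")
    groups = sorted(set(group_design.values()))
    if len(groups) != 2:
        raise InputError(f"need exactly 2 groups, got {groups}")
    cols = list(matrix.columns)
    unknown = set(group_design) - set(cols)
    if unknown:
        raise InputError(f"unknown samples in design: {sorted(unknown)}")
    idx1 = np.array([i for i, c in enumerate(cols)
                     if group_design.get(c) == groups[0]])
    idx2 = np.array([i for i, c in enumerate(cols)
                     if group_design.get(c) == groups[1]])
    if idx1.size < 2 or idx2.size < 2:
        raise InputError("each group needs >= 2 replicates")

    mat = matrix.to_numpy(dtype=float)
    # columns reordered so the first n1 belong to group 1
    order = np.concatenate([idx1, idx2])
    mat = mat[:, order]
    n1, n2 = idx1.size, idx2.size
    a1, a2 = np.arange(n1), np.arange(n1, n1 + n2)

    fc, d = _group_stats(mat, a1, a2, s0, variance)

    rng = np.random.default_rng(seed)
    labelings = _permutation_labelings(n1, n2, n_perm, rng)
    all_cols = np.arange(n1 + n2)
    null_abs = []
    for lab in labelings:
        comp = np.setdiff1d(all_cols, lab)
        _, d_star = _group_stats(mat, lab, comp, s0, variance)
        null_abs.append(np.abs(d_star))
    null_abs = np.concatenate(null_abs)
    n_lab = len(labelings)

    abs_d = np.abs(d)
    order_desc = np.argsort(-abs_d, kind="stable")
    sorted_abs = abs_d[order_desc]
    # observed exceedances at each threshold t = sorted_abs[k]: k + 1
    obs_count = np.arange(1, abs_d.size + 1)
    null_sorted = np.sort(null_abs)
    null_count = null_abs.size - np.searchsorted(null_sorted, sorted_abs,
                                                 side="left")
    fdr_at = np.minimum((null_count / n_lab) / obs_count, 1.0)
    # q_i = min FDR over thresholds t <= |d_i|, i.e. a suffix minimum over
    # the descending-|d| order
    q_sorted = np.minimum.accumulate(fdr_at[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order_desc] = q_sorted

    table = pd.DataFrame({
        "log2_fc": fc, "d": d, "q": q, "significant": q < fdr,
    }, index=matrix.index)
    return DifferentialResult(table=table, s0=s0, fdr=fdr,
                              n_permutations=n_lab,
                              params=dict(variance=variance, seed=seed,
                                          groups=groups))


def welch_t(matrix: pd.DataFrame, group_design: dict[str, str]
            ) -> np.ndarray:
    """Plain Welch t statistic (group2 - group1), the s0 = 0 limit."""
    groups = sorted(set(group_design.values()))
    cols = list(matrix.columns)
    idx1 = np.array([i for i, c in enumerate(cols)
                     if group_design.get(c) == groups[0]])
    idx2 = np.array([i for i, c in enumerate(cols)
                     if group_design.get(c) == groups[1]])
    _, d = _group_stats(matrix.to_numpy(float), idx1, idx2, 0.0, "welch")
    return d


# ---------------------------------------------------------------------------
# proteomic ruler


def dna_mass_from_genome(genome_bp: float, ploidy: float = 2.0) -> float:
    """DNA mass per cell in picograms from genome size and ploidy."""
    if genome_bp <= 0 or ploidy <= 0:
        raise ConfigError("genome_bp and ploidy must be positive")
    return genome_bp * ploidy * MEAN_BP_MASS_DA / AVOGADRO * 1e12


@dataclass
class RulerResult:
    """Absolute per-protein quantification via the proteomic ruler.

    ``mass_pg``: protein mass per cell (pg); ``copies``: copy number per
    cell; ``total_mass_pg``: summed protein mass per cell; ``skipped``:
    protein ids dropped for zero/absent molecular weight.
    """

    mass_pg: pd.Series
    copies: pd.Series
    total_mass_pg: float
    dna_mass_pg: float
    skipped: list = field(default_factory=list)


def proteomic_ruler(intensity: pd.Series, mol_weight_kda: pd.Series,
                    is_histone: pd.Series,
                    dna_mass_pg: float | None = None,
                    genome_bp: float | None = None,
                    ploidy: float = 2.0) -> RulerResult:
    """Histone-anchored copy-number estimation.

    The summed histone MS signal is assumed to report a protein mass equal
    to the cellular DNA mass, so
    ``mass_i = intensity_i / sum(histone intensities) * dna_mass_pg`` and
    ``copies_i = mass_i[g] / (MW_i[g/mol]) * N_A``.  Either ``dna_mass_pg``
    or ``genome_bp`` (+ ``ploidy``) must be given.
    """
    if dna_mass_pg is None:
        if genome_bp is None:
            raise ConfigError("provide dna_mass_pg or genome_bp")
        dna_mass_pg = dna_mass_from_genome(genome_bp, ploidy)
    if dna_mass_pg <= 0:
        raise ConfigError("dna_mass_pg: must be positive")
    intensity = intensity.astype(float)
    histone_signal = intensity[np.asarray(is_histone, dtype=bool)].sum()
    if histone_signal <= 0:
        raise InputError("no histone signal: the proteomic ruler needs >= 1 "
                         "histone-flagged protein with nonzero intensity")
    mw = mol_weight_kda.astype(float)
    bad = ~(mw > 0)
    skipped = list(intensity.index[bad])
    if skipped:
        warnings.warn(f"skipping {len(skipped)} proteins with nonpositive "
                      "molecular weight", stacklevel=2)
    keep = ~bad
    mass = intensity[keep] / histone_signal * dna_mass_pg
    copies = mass * 1e-12 / (mw[keep] * 1000.0) * AVOGADRO
    return RulerResult(mass_pg=mass, copies=copies,
                       total_mass_pg=float(mass.sum()),
                       dna_mass_pg=float(dna_mass_pg), skipped=skipped)


def organelle_mass_fractions(mass_pg: pd.Series,
                             localisation: pd.Series) -> pd.Series:
    """Percentage of total protein mass per subcellular compartment.

    Multi-localised proteins (';'-separated labels) split their mass
    equally across compartments; unmapped mass goes to "unassigned".
    Percentages sum to 100.
    """
    total = mass_pg.sum()
    if total <= 0:
        raise InputError("total protein mass is zero")
    acc: dict[str, float] = {}
    loc = localisation.reindex(mass_pg.index).fillna("")
    for pid, mass in mass_pg.items():
        labels = [t.strip() for t in str(loc.loc[pid]).split(";") if t.strip()]
        if not labels:
            labels = ["unassigned"]
        share = mass / len(labels)
        for lab in labels:
            acc[lab] = acc.get(lab, 0.0) + share
    pct = pd.Series(acc).sort_index() / total * 100.0
    return pct


__all__ = [
    "filter_protein_groups", "log2_transform", "impute_downshifted",
    "ImputationResult", "s0_permutation_test", "DifferentialResult",
    "welch_t", "proteomic_ruler", "RulerResult", "dna_mass_from_genome",
    "organelle_mass_fractions", "AVOGADRO", "MEAN_BP_MASS_DA",
]
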