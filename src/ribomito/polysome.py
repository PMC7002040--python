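"""Polysome translational-efficiency (TE) scoring.

A transcript's TE score is its relative abundance in the heavy polysome
pool (more than ``boundary`` ribosomes) divided by its relative abundance
in the light pool, computed within each replicate and then averaged across
replicates per condition.  The change in TE between knockdown and control
is analysed on the log2 scale, where the shift-classification thresholds
of +/-1 correspond to a doubling or halving of TE.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

POOLS = ("heavy", "light", "subpolysomal")
CONDITIONS = ("control", "knockdown")


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check the sample sheet contract.

    Requires columns sample_id/condition/replicate/pool, unique
    (condition, replicate, pool) triples, and a heavy and a light sample
    for every (condition, replicate) pair.  Raises :class:`InputError`
    naming the offending replicate.
    """
    required = {"sample_id", "condition", "replicate", "pool"}
    missing = required - set(sheet.columns)
    if missing:
        raise InputError(f"sample sheet lacks columns: {sorted(missing)}")
    bad_pool = set(sheet["pool"]) - set(POOLS)
    if bad_pool:
        raise InputError(f"unknown pool labels: {sorted(bad_pool)}")
    dup = sheet.duplicated(["condition", "replicate", "pool"])
    if dup.any():
        row = sheet[dup].iloc[0]
        raise InputError(
            f"duplicate sample for condition={row.condition} "
            f"replicate={row.replicate} pool={row.pool}")
    hl = sheet[sheet["pool"].isin(["heavy", "light"])]
    for (cond, rep), grp in hl.groupby(["condition", "replicate"]):
        pools = set(grp["pool"])
        if pools != {"heavy", "light"}:
            lacking = {"heavy", "light"} - pools
            raise InputError(
                f"condition={cond} replicate={rep} lacks a "
                f"{sorted(lacking)[0]} sample")
    return sheet


def pool_fractions(per_fraction_counts: pd.DataFrame,
                   fraction_ribosome_map: dict[str, int],
                   boundary: int = 3) -> pd.DataFrame:
    """Pool per-fraction counts into heavy / light / subpolysomal.

    ``fraction_ribosome_map`` annotates each fraction column with its
    ribosome count.  Fractions with 1..boundary ribosomes are pooled as
    light, fractions with more than ``boundary`` ribosomes as heavy, and
    0-ribosome fractions as subpolysomal; column sums are conserved.
    """
    unknown = set(per_fraction_counts.columns) - set(fraction_ribosome_map)
    if unknown:
        raise InputError(f"fractions without ribosome annotation: {sorted(unknown)}")
    for frac, ribo in fraction_ribosome_map.items():
        if ribo < 0:
            raise InputError(f"fraction {frac!r} has negative ribosome count")
    def pool_of(frac: str) -> str:
        ribo = fraction_ribosome_map[frac]
        if ribo == 0:
            return "subpolysomal"
        return "light" if ribo <= boundary else "heavy"

    mapping = {frac: pool_of(frac) for frac in per_fraction_counts.columns}
    pooled = per_fraction_counts.T.groupby(mapping).sum().T
    return pooled.reindex(columns=list(POOLS), fill_value=0)


@dataclass
class TEResult:
    """Per-transcript TE scores and their change between conditions.

    ``replicate_te``: columns are a MultiIndex (condition, replicate);
    ``te_mean``: one column per condition; ``log2_change`` and
    ``shift_class`` are filled in by :func:`change_in_te` and
    :func:`classify_te_shift`.  ``dropped_low_count`` lists transcripts
    removed by the min-total filter; ``undefined`` lists transcripts whose
    TE was zero or non-finite in some replicate (flagged and excluded from
    the change computation, never silently dropped).
    """

    replicate_te: pd.DataFrame
    te_mean: pd.DataFrame
    log2_change: pd.Series | None = None
    shift_class: pd.Series | None = None
    dropped_low_count: list = field(default_factory=list)
    undefined: list = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(index=self.te_mean.index)
        for cond in self.te_mean.columns:
            out[f"te_{cond}"] = self.te_mean[cond]
        if self.log2_change is not None:
            out["log2_change"] = self.log2_change
        if self.shift_class is not None:
            out["shift_class"] = self.shift_class
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="transcript_id")


def compute_te(counts: pd.DataFrame, sheet: pd.DataFrame,
               min_total: int = 10, pseudocount: float = 0.5,
               mean: str = "arithmetic") -> TEResult:
    """Per-replicate and per-condition TE from pooled heavy/light counts.

    Within each sample the relative abundance of a transcript is
    (count + pseudocount) / sum(count + pseudocount); the replicate TE is
    the heavy relative abundance divided by the light one, and the
    condition TE is the mean of the replicate TEs (arithmetic by default,
    ``mean="geometric"`` as an option).  Transcripts whose total raw count
    across all samples is below ``min_total`` are dropped and reported in
    ``TEResult.dropped_low_count``.
    """
    validate_sample_sheet(sheet)
    if mean not in ("arithmetic", "geometric"):
        raise ConfigError(f"mean: unknown averaging mode {mean!r}")
    if pseudocount < 0:
        raise ConfigError("pseudocount: must be >= 0")
    missing_cols = set(sheet["sample_id"]) - set(counts.columns)
    if missing_cols:
        raise InputError(f"count matrix lacks samples: {sorted(missing_cols)}")
    if (counts < 0).any().any():
        raise InputError("counts must be nonnegative")

    hl = sheet[sheet["pool"].isin(["heavy", "light"])]
    used = counts[list(hl["sample_id"])]
    keep = used.sum(axis=1) >= min_total
    dropped = list(used.index[~keep])
    used = used[keep]

    rel = (used + pseudocount) / (used + pseudocount).sum(axis=0)

    te_cols = {}
    for (cond, rep), grp in hl.groupby(["condition", "replicate"]):
        heavy = grp.loc[grp["pool"] == "heavy", "sample_id"].iloc[0]
        light = grp.loc[grp["pool"] == "light", "sample_id"].iloc[0]
        te_cols[(cond, rep)] = rel[heavy] / rel[light]
    replicate_te = pd.DataFrame(te_cols)
    replicate_te.columns = pd.MultiIndex.from_tuples(
        replicate_te.columns, names=["condition", "replicate"])

    if mean == "arithmetic":
        te_mean = replicate_te.T.groupby(level="condition").mean().T
    else:
        te_mean = np.exp(
            np.log(replicate_te).T.groupby(level="condition").mean().T)

    return TEResult(replicate_te=replicate_te, te_mean=te_mean,
                    dropped_low_count=dropped,
                    params=dict(min_total=min_total, pseudocount=pseudocount,
                                mean=mean))


def change_in_te(te: TEResult, control: str = "control",
                 knockdown: str = "knockdown") -> TEResult:
    """log2(TE_knockdown / TE_control) per transcript.

    Swapping the two condition arguments negates the result.  Transcripts
    with zero or non-finite TE in either condition are recorded in
    ``te.undefined`` and excluded (NaN), not silently dropped.
    """
    for cond in (control, knockdown):
        if cond not in te.te_mean.columns:
            raise InputError(f"condition {cond!r} absent from TE table")
    ratio = te.te_mean[knockdown] / te.te_mean[control]
    valid = (te.te_mean[control] > 0) & (te.te_mean[knockdown] > 0) \
        & np.isfinite(ratio)
    log2c = pd.Series(np.nan, index=te.te_mean.index, name="log2_change")
    log2c[valid] = np.log2(ratio[valid])
    te.log2_change = log2c
    te.undefined = list(te.te_mean.index[~valid])
    return te


def classify_te_shift(log2_change: pd.Series, threshold: float = 1.0
                      ) -> tuple[pd.Series, dict[str, int]]:
    """Strict threshold rule: down iff x < -threshold, up iff x > threshold,
    none otherwise (values exactly at the threshold are 'none').

    Returns the per-transcript class and a summary count per class.
    NaN entries (undefined changes) are excluded from the classification
    and from the counts; non-finite non-NaN input is rejected.
    """
    if threshold <= 0:
        raise ConfigError("threshold: must be > 0")
    x = pd.Series(log2_change)
    if np.isinf(x).any():
        raise InputError("log2_change contains non-finite values")
    cls = pd.Series("none", index=x.index, name="shift_class")
    cls[x < -threshold] = "down"
    cls[x > threshold] = "up"
    cls[x.isna()] = pd.NA
    counts = {
        "down": int((cls == "down").sum()),
        "up": int((cls == "up").sum()),
        "none": int((cls == "none").sum()),
    }
    return cls, counts
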