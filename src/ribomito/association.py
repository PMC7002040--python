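"""Association of change-in-TE with 5'UTR features.

Binned feature profiles across the log2 change-in-TE axis, the Pearson
correlation test, a Mann-Whitney comparison for subset shifts (e.g.
mitochondrially encoded transcripts vs all others), and a 2x2 enrichment
test for binary motifs (TOP) among shifted transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, InputError


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t: float
    p: float

    def __str__(self) -> str:  # text output mirrors R's cor.test
        p = "< 2.2e-16" if self.p < 2.2e-16 else f"= {self.p:.4g}"
        return f"Pearson r = {self.r:.4f} (n = {self.n}), t = {self.t:.3f}, p {p}"


def pearson_test(x, y) -> CorrelationResult:
    """Two-sided Pearson product-moment correlation test.

    ``t = r * sqrt((n - 2) / (1 - r^2))`` referred to a t distribution with
    n - 2 degrees of freedom.  The p-value is stored as computed, however
    small; the text rendering caps at "< 2.2e-16".
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be aligned 1-D vectors")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InputError("x and y must be finite")
    n = x.size
    if n < 3:
        raise InputError("need n >= 3 for a correlation test")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InputError("correlation undefined for a constant vector")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return CorrelationResult(r=r, n=n, t=float(t), p=float(p))


def bin_profile(delta, feature, window: float = 0.5) -> pd.DataFrame:
    """Mean +/- SE of a feature in contiguous change-in-TE bins.

    Bin edges are multiples of ``window`` covering the data range; empty
    bins within the range are retained with n = 0.  Returns columns
    bin_left, bin_right, bin_mid, n, mean, se.
    """
    if window <= 0:
        raise ConfigError("window: must be > 0")
    delta = np.asarray(delta, dtype=float)
    feature = np.asarray(feature, dtype=float)
    if delta.shape != feature.shape:
        raise InputError("delta and feature must be aligned")
    if not (np.isfinite(delta).all() and np.isfinite(feature).all()):
        raise InputError("delta and feature must be finite")
    lo = np.floor(delta.min() / window) * window
    hi = np.ceil(delta.max() / window) * window
    if hi == lo:
        hi = lo + window
    nbins = int(round((hi - lo) / window))
    edges = lo + window * np.arange(nbins + 1)
    idx = np.clip(np.floor((delta - lo) / window).astype(int), 0, nbins - 1)
    rows = []
    for b in range(nbins):
        sel = feature[idx == b]
        rows.append(dict(
            bin_left=edges[b], bin_right=edges[b + 1],
            bin_mid=(edges[b] + edges[b + 1]) / 2.0,
            n=int(sel.size),
            mean=float(sel.mean()) if sel.size else np.nan,
            se=float(sel.std(ddof=1) / np.sqrt(sel.size))
            if sel.size > 1 else np.nan,
        ))
    return pd.DataFrame(rows)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact p by enumeration of rank assignments when both groups have at
    most 8 observations and there are no ties; otherwise the normal
    approximation with tie and continuity correction.  Returns (U, p)
    where U counts pairs in which an ``a`` value exceeds a ``b`` value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be nonempty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = min(a.size, b.size) <= 8 and not has_ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if exact else "asymptotic", use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass(frozen=True)
class GroupSummary:
    n: int
    median: float
    q1: float
    q3: float
    fraction_negative: float


@dataclass(frozen=True)
class SubsetShift:
    subset: GroupSummary
    rest: GroupSummary
    u: float
    p: float


def _summarise(x: np.ndarray) -> GroupSummary:
    return GroupSummary(
        n=int(x.size),
        median=float(np.median(x)),
        q1=float(np.percentile(x, 25)),
        q3=float(np.percentile(x, 75)),
        fraction_negative=float((x < 0).mean()),
    )


def subset_shift_summary(delta, subset_mask) -> SubsetShift:
    """Distribution summary of a change-in-TE subset vs its complement,
    plus a Mann-Whitney p-value for the subset-vs-rest comparison."""
    delta = np.asarray(delta, dtype=float)
    mask = np.asarray(subset_mask, dtype=bool)
    if delta.shape != mask.shape:
        raise InputError("mask length must match delta")
    if not mask.any():
        raise InputError("subset is empty")
    if mask.all():
        raise InputError("complement is empty")
    sub, rest = delta[mask], delta[~mask]
    u, p = mann_whitney(sub, rest)
    return SubsetShift(subset=_summarise(sub), rest=_summarise(rest), u=u, p=p)


@dataclass(frozen=True)
class EnrichmentResult:
    odds_ratio: float
    p_upper: float
    p_two_sided: float


def enrichment_2x2(k: int, big_k: int, n: int, big_n: int) -> EnrichmentResult:
    """Enrichment of a binary feature in a selected set.

    ``k`` of ``n`` selected items carry the feature; ``big_k`` of
    ``big_n`` items carry it overall.  One-sided p is the upper
    hypergeometric tail P(X >= k); the two-sided p is Fisher's exact test
    (sum of table probabilities <= that of the observed table).
    """
    if not (0 <= k <= min(big_k, n) <= big_n) or n > big_n or big_k > big_n:
        raise InputError("inconsistent 2x2 margins")
    table = np.array([[k, n - k], [big_k - k, big_n - big_k - (n - k)]])
    if (table < 0).any():
        raise InputError("inconsistent 2x2 margins")
    odds, p_two = stats.fisher_exact(table, alternative="two-sided")
    p_upper = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
    return EnrichmentResult(odds_ratio=float(odds),
                            p_upper=min(p_upper, 1.0),
                            p_two_sided=float(min(p_two, 1.0)))
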