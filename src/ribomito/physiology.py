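"""Closed-form physiology metrics.

Pure functions for the standard indices derived from indirect
calorimetry (respiratory exchange ratio, energy expenditure),
echocardiography (fractional shortening, relative wall thickness),
electrocardiography (Bazett-corrected QT), high-resolution respirometry
(respiratory control ratio), and a goodness-of-fit test of offspring
genotype counts against an expected Mendelian segregation ratio.

Unit notes: RER and EE are unit-agnostic in the gas-volume inputs (the EE
coefficients 3.815 and 1.232 are the classical Lusk-style weights; the
output scale follows the VO2/VCO2 units supplied).  QTc takes and returns
seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from math import sqrt

import numpy as np
from scipy import stats

from .errors import InputError

EE_O2_COEF = 3.815
EE_CO2_COEF = 1.232


def rer(vo2: float, vco2: float) -> float:
    """Respiratory exchange ratio VCO2 / VO2."""
    if vo2 <= 0:
        raise InputError("vo2 must be > 0")
    return vco2 / vo2


def energy_expenditure(vo2: float, vco2: float) -> float:
    """Energy expenditure 3.815 * VO2 + 1.232 * VCO2 (kcal scale)."""
    if vo2 < 0 or vco2 < 0:
        raise InputError("gas volumes must be >= 0")
    return EE_O2_COEF * vo2 + EE_CO2_COEF * vco2


def fractional_shortening(lvdd: float, lvsd: float) -> float:
    """LV fractional shortening in percent: (LVDD - LVSD) / LVDD * 100."""
    if lvdd <= 0:
        raise InputError("lvdd must be > 0")
    return (lvdd - lvsd) / lvdd * 100.0


def relative_wall_thickness(ivs_d: float, lvpw_d: float, lvdd: float) -> float:
    """Relative wall thickness (IVSD + LVPWD) / LVDD.

    The first argument is the interventricular septum thickness in
    diastole (IVSD); together with the posterior wall thickness it forms
    the combined diastolic wall thickness referred to the cavity diameter.
    """
    if lvdd <= 0:
        raise InputError("lvdd must be > 0")
    return (ivs_d + lvpw_d) / lvdd


def qtc_bazett(qt_s: float, rr_s: float) -> float:
    """Bazett-corrected QT interval: QT / sqrt(RR), seconds in and out."""
    if rr_s <= 0:
        raise InputError("rr_s must be > 0")
    return qt_s / sqrt(rr_s)


def respiratory_control_ratio(oxphos: float, leak: float) -> float:
    """Respiratory control ratio OXPHOS / LEAK (coupling efficiency)."""
    if leak <= 0:
        raise InputError("leak must be > 0")
    return oxphos / leak


@dataclass(frozen=True)
class MendelianResult:
    chi2: float
    df: int
    p: float
    expected: tuple[float, ...]
    p_exact: float | None = None


def mendelian_gof(observed, weights=(1, 2, 1),
                  exact: bool = False) -> MendelianResult:
    """Chi-square goodness of fit of genotype counts to a segregation ratio.

    ``chi2 = sum (obs - exp)^2 / exp`` with ``exp = total * w / sum(w)``
    and ``df = classes - 1``.  With ``exact=True`` (supported for totals
    <= 100) an exact multinomial p is also computed by enumerating all
    outcomes and summing the probability of those at least as extreme
    (chi-square-ordered tail).
    """
    obs = np.asarray(observed)
    w = np.asarray(weights, dtype=float)
    if obs.shape != w.shape or obs.ndim != 1:
        raise InputError("observed counts and ratio weights must align")
    if (obs < 0).any() or not np.issubdtype(obs.dtype, np.integer):
        raise InputError("observed counts must be nonnegative integers")
    if (w <= 0).any():
        raise InputError("expected ratio weights must be > 0")
    total = int(obs.sum())
    if total == 0:
        raise InputError("total count must be > 0")
    probs = w / w.sum()
    exp = total * probs
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = obs.size - 1
    p = float(stats.chi2.sf(chi2, df))

    p_exact = None
    if exact:
        if total > 100:
            raise InputError("exact multinomial test supported for totals <= 100")
        p_exact = _multinomial_tail(obs, probs, chi2)
    return MendelianResult(chi2=chi2, df=df, p=p,
                           expected=tuple(exp), p_exact=p_exact)


def _multinomial_tail(obs: np.ndarray, probs: np.ndarray,
                      chi2_obs: float) -> float:
    """Sum of multinomial outcome probabilities with chi-square >= observed."""
    total = int(obs.sum())
    k = obs.size
    exp = total * probs
    tail = 0.0
    # enumerate all compositions of `total` into k parts
    ranges = [range(total + 1)] * (k - 1)
    for head in product(*ranges):
        s = sum(head)
        if s > total:
            continue
        counts = np.array(list(head) + [total - s])
        chi2 = float(((counts - exp) ** 2 / exp).sum())
        if chi2 >= chi2_obs - 1e-12:
            tail += float(stats.multinomial.pmf(counts, total, probs))
    return min(tail, 1.0)
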