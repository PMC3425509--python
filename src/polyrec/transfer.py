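"""Transfer functions: cation concentration -> misincorporation rate.

The headline quantity of a polymerase-as-sensor characterisation is the gain
of its transfer function: the ordinary-least-squares slope of the replicate-
averaged mean misincorporation rate (in percent) against the varied cation
concentration (in mM), i.e. %/mM.  Fold changes are reported with respect to
the lowest concentration in the titration.  A classical blue/white colony
assay error rate, f = -ln(F)/(d*b), is included for cross-method comparison
with bulk fidelity measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .miscall import RateEstimate
from .synthetic_data import CationCondition

__all__ = [
    "TitrationSeries",
    "TransferFit",
    "fit_gain",
    "CaResponse",
    "ca_response",
    "ColonyCounts",
    "colony_error_rate",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Replicate-averaged rates along a titration of one cation.

    ``points`` pairs each condition with its rate estimate (rates as
    fractions, not percent); the varied cation must be strictly increasing.
    """

    points: tuple[tuple[CationCondition, RateEstimate], ...]
    varied_cation: str  # 'mn' | 'mg' | 'ca'

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a titration needs at least two points")
        conc = self.concentrations_uM()
        if not np.all(np.diff(conc) > 0):
            raise ValueError("varied cation must be strictly increasing")

    def concentrations_uM(self) -> np.ndarray:
        return np.array([getattr(c, f"{self.varied_cation}_uM")
                         for c, _ in self.points])

    def rates(self) -> np.ndarray:
        return np.array([r.rate for _, r in self.points])


@dataclass(frozen=True)
class TransferFit:
    """OLS gain of rate (%) versus concentration (mM), plus the fold change
    of the rate at the highest versus the lowest concentration."""

    gain_pct_per_mM: float
    gain_se: float
    fold_change: float
    intercept_pct: float


def fit_gain(series: TitrationSeries) -> TransferFit:
    """Fit the transfer-function gain by unweighted ordinary least squares.

    Rates enter in percent and concentrations in mM, so the slope is the
    sensor gain in %/mM.  The fold change is rate(highest concentration) /
    rate(lowest concentration).
    """
    conc_mM = series.concentrations_uM() / 1000.0
    rate_pct = series.rates() * 100.0
    ok = np.isfinite(rate_pct)
    if ok.sum() < 2:
        raise ValueError("need at least two points with defined rates")
    res = sps.linregress(conc_mM[ok], rate_pct[ok])
    r = rate_pct[ok]
    fold = float(r[-1] / r[0]) if r[0] > 0 else float("inf")
    return TransferFit(float(res.slope), float(res.stderr), fold,
                       float(res.intercept))


@dataclass(frozen=True)
class CaResponse:
    """Fold change and percent change of the rate between two Ca2+
    endpoints; ``percent_decrease`` is NaN unless the rate decreased."""

    fold: float
    percent_change: float
    percent_decrease: float


def ca_response(series: TitrationSeries) -> CaResponse:
    """Response between the first and last Ca2+ points of a titration at a
    fixed Mn2+/Mg2+ background: fold = rate(high)/rate(low), and the percent
    decrease 100*(1 - fold) when the rate went down."""
    if series.varied_cation != "ca":
        raise ValueError("series must vary Ca2+")
    r = series.rates()
    lo, hi = r[0], r[-1]
    if not (np.isfinite(lo) and lo > 0):
        return CaResponse(float("nan"), float("nan"), float("nan"))
    fold = float(hi / lo)
    pct_change = 100.0 * (fold - 1.0)
    pct_decrease = 100.0 * (1.0 - fold) if fold < 1 else float("nan")
    return CaResponse(fold, pct_change, pct_decrease)


@dataclass(frozen=True)
class ColonyCounts:
    """Blue/white colony counts from a lacI-based PCR fidelity screen.

    ``d`` is the number of DNA duplications during amplification and ``b``
    the effective mutational target size in bp (349 detectable single-base
    substitution sites of the 1080 bp lacI gene).
    """

    blue: int
    white: int
    d: float
    b: float = 349.0

    def __post_init__(self) -> None:
        if self.blue < 0 or self.white < 0:
            raise ValueError("counts must be >= 0")
        if self.d <= 0 or self.b <= 0:
            raise ValueError("d and b must be > 0")


def colony_error_rate(counts: ColonyCounts) -> tuple[float, float]:
    """Bulk error rate per bp from colony counts: f = -ln(F) / (d*b).

    F is the fraction of white (non-mutant) colonies.  The uncertainty is
    propagated from Poisson counting statistics of the two colony counts
    (for large counts each is approximately Gaussian with variance equal to
    its mean).  F = 0 yields an infinite, flagged estimate.
    """
    total = counts.blue + counts.white
    if total == 0:
        raise ValueError("need at least one colony")
    F = counts.white / total
    if F == 0:
        return float("inf"), float("nan")
    f = -math.log(F) / (counts.d * counts.b)
    # delta method: var(F) from independent Poisson blue/white counts
    w, bl = counts.white, counts.blue
    var_F = (bl * bl * w + w * w * bl) / total ** 4
    se = math.sqrt(var_F) / (F * counts.d * counts.b)
    return f, se
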