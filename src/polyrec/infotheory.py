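"""Shannon information gain per base about a binary cation state.

A template position whose misincorporation probability differs between a
high- and a low-concentration state acts as a noisy one-bit channel: with
equal priors p(H) = p(L) = 1/2 there is one bit of missing information, and
observing whether the position was miscopied reduces the expected posterior
entropy.  The gain per base is

    gain = 1 - [ p(I) * H_incorrect + (1 - p(I)) * H_correct ],

where p(I) = p(I|H) p(H) + p(I|L) p(L) is the marginal misincorporation
probability, and H_incorrect / H_correct are the Shannon entropies of the
posterior over {H, L} after observing an incorrect / correct base (Bayes'
rule), with the 0*log2(0) = 0 convention throughout.  This equals the mutual
information between the cation state and the binary outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelSpec",
    "InfoResult",
    "info_gain",
    "info_profile",
    "capacity",
]


@dataclass(frozen=True)
class ChannelSpec:
    """Binary misincorporation channel: error probabilities at the high and
    low cation state, plus the state priors (default 1/2, 1/2)."""

    p_I_given_H: float
    p_I_given_L: float
    prior_H: float = 0.5
    prior_L: float = 0.5

    def __post_init__(self) -> None:
        for p in (self.p_I_given_H, self.p_I_given_L, self.prior_H, self.prior_L):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(self.prior_H + self.prior_L - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")


@dataclass(frozen=True)
class InfoResult:
    """Information gain (bits per base) with all intermediate quantities."""

    gain: float
    h_exp: float
    p_I: float
    p_H_given_I: float
    p_L_given_I: float
    p_H_given_C: float
    p_L_given_C: float
    H_incorrect: float
    H_correct: float


def _plog2p(p: float) -> float:
    return 0.0 if p <= 0.0 else p * math.log2(p)


def _entropy2(p: float) -> float:
    return -_plog2p(p) - _plog2p(1.0 - p)


def info_gain(spec: ChannelSpec) -> InfoResult:
    """Expected information gained about the cation state by observing
    whether one template position was miscopied."""
    pH, pL = spec.prior_H, spec.prior_L
    pIH, pIL = spec.p_I_given_H, spec.p_I_given_L
    p_I = pIH * pH + pIL * pL
    if p_I > 0:
        p_H_given_I = pIH * pH / p_I
    else:
        p_H_given_I = pH  # unobservable branch; posterior stays at the prior
    p_L_given_I = 1.0 - p_H_given_I
    p_C = 1.0 - p_I
    if p_C > 0:
        p_H_given_C = (1.0 - pIH) * pH / p_C
    else:
        p_H_given_C = pH
    p_L_given_C = 1.0 - p_H_given_C
    H_inc = _entropy2(p_H_given_I)
    H_cor = _entropy2(p_H_given_C)
    h_exp = p_I * H_inc + p_C * H_cor
    prior_bits = _entropy2(pH)
    return InfoResult(
        gain=prior_bits - h_exp,
        h_exp=h_exp,
        p_I=p_I,
        p_H_given_I=p_H_given_I,
        p_L_given_I=p_L_given_I,
        p_H_given_C=p_H_given_C,
        p_L_given_C=p_L_given_C,
        H_incorrect=H_inc,
        H_correct=H_cor,
    )


def info_profile(rates_high: np.ndarray, rates_low: np.ndarray,
                 prior_H: float = 0.5) -> np.ndarray:
    """Per-position information gain from two per-position rate profiles.

    Positions with an undefined rate in either profile are skipped (NaN in
    the output).  Returns gains in bits per base; the peak is simply
    ``np.nanmax`` of the result.
    """
    hi = np.asarray(rates_high, dtype=float)
    lo = np.asarray(rates_low, dtype=float)
    if hi.shape != lo.shape:
        raise ValueError("rate profiles must cover the same positions")
    out = np.full(hi.shape, np.nan)
    for i, (h, l) in enumerate(zip(hi, lo)):
        if np.isfinite(h) and np.isfinite(l):
            out[i] = info_gain(
                ChannelSpec(h, l, prior_H, 1.0 - prior_H)
            ).gain
    return out


def capacity(bits_per_base: float, template_length: float) -> float:
    """Total recording capacity in bytes of a template written at a given
    information density: bytes = bits_per_base * length / 8."""
    if not 0.0 <= bits_per_base <= 1.0:
        raise ValueError("bits_per_base must lie in [0, 1]")
    if template_length <= 0:
        raise ValueError("template_length must be > 0")
    return bits_per_base * template_length / 8.0
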