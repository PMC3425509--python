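"""Independent reference implementations used only for cross-checking.

These deliberately share no code with the package: a plain recursive
affine-gap alignment DP, a textbook Levenshtein DP, and a brute-force mutual
information over the 2x2 joint distribution of (cation state, outcome).
"""

from __future__ import annotations

import math
from functools import lru_cache


def align_score_oracle(a: str, b: str, match: float = 1.0, mismatch: float = 0.0,
                       gap_open: float = -10.0, gap_extend: float = -2.0) -> float:
    """Optimal global affine-gap alignment score by exhaustive three-state
    dynamic programming (end gaps scored)."""
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def step(i: int, j: int) -> tuple[float, float, float]:
        # returns best scores ending at (i, j) in state (M, Ix, Iy)
        # Ix: gap in b (consumes a), Iy: gap in a (consumes b)
        if i == 0 and j == 0:
            return 0.0, NEG, NEG
        M = Ix = Iy = NEG
        if i > 0 and j > 0:
            s = match if a[i - 1] == b[j - 1] else mismatch
            pm, px, py = step(i - 1, j - 1)
            M = max(pm, px, py) + s
        if i > 0:
            pm, px, py = step(i - 1, j)
            Ix = max(pm + gap_open, px + gap_extend, py + gap_open)
        if j > 0:
            pm, px, py = step(i, j - 1)
            Iy = max(pm + gap_open, px + gap_extend, py + gap_open)
        return M, Ix, Iy

    return max(step(len(a), len(b)))


def levenshtein_oracle(a: str, b: str) -> int:
    """Classic O(nm) edit-distance DP."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def mutual_information_oracle(p_I_given_H: float, p_I_given_L: float,
                              prior_H: float = 0.5) -> float:
    """I(state; outcome) in bits from the explicit 2x2 joint distribution."""
    prior_L = 1.0 - prior_H
    joint = {
        ("H", "I"): prior_H * p_I_given_H,
        ("H", "C"): prior_H * (1 - p_I_given_H),
        ("L", "I"): prior_L * p_I_given_L,
        ("L", "C"): prior_L * (1 - p_I_given_L),
    }
    p_state = {"H": prior_H, "L": prior_L}
    p_out = {o: joint[("H", o)] + joint[("L", o)] for o in ("I", "C")}
    mi = 0.0
    for (s, o), p in joint.items():
        if p > 0 and p_state[s] > 0 and p_out[o] > 0:
            mi += p * math.log2(p / (p_state[s] * p_out[o]))
    return mi
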