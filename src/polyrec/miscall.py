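"""Alignment of accepted inserts to the error-free product reference and
misincorporation tallies.

Inserts are globally aligned to the theoretical error-free primer-extension
product (the reverse complement of the template extension region) under an
identity scoring scheme: match +1, mismatch 0, affine gaps with open -10 and
extend -2 (the first position of a gap costs the open penalty, each further
position the extend penalty), and end gaps scored like internal gaps, so
truncated products are penalised rather than silently trimmed.  Alignments
are kept only if the insert is at least 70 bases long and the score is
strictly greater than 60.

Tally conventions (stated once, used everywhere): extension positions are
1-based along the extension region in the order bases are added; the
incorporated dNTP is the read base; the template base is the template-strand
base, i.e. the complement of the product-reference base.  Columns containing
a gap, or an ambiguous read base, contribute neither to the error count n_p
nor to the total N_p at that position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .synthetic_data import BASES, TemplateSpec, revcomp

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "global_align",
    "accept_alignment",
    "MisincorporationTally",
    "tally",
    "tally_inserts",
    "RateTables",
    "rates",
    "transition_matrix",
    "RateEstimate",
    "replicate_stats",
    "NoiseFloor",
    "noise_floor",
    "error_matrix",
]

_CODE = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class AlignmentParams:
    """Scoring scheme and acceptance thresholds for insert alignment."""

    match: float = 1.0
    mismatch: float = 0.0
    gap_open: float = -10.0
    gap_extend: float = -2.0
    min_insert_len: int = 70
    min_score: float = 60.0  # exclusive


@dataclass
class AlignmentResult:
    """A global alignment as parallel 0-based index columns.

    ``ref_idx``/``qry_idx`` have one entry per alignment column; -1 marks a
    gap on that side.  ``query`` is kept for base lookups during tallying.
    """

    score: float
    ref_idx: np.ndarray
    qry_idx: np.ndarray
    query: str
    has_indel: bool


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def global_align(insert: str, product_ref: str,
                 params: AlignmentParams = AlignmentParams()) -> AlignmentResult:
    """Optimal global alignment of an insert against the product reference.

    For equal-length sequences with fewer than ``gap_open*2`` worth of
    mismatches, the gapless alignment is provably optimal (any gapped global
    alignment of equal-length sequences carries at least one gap on each side,
    costing more than the mismatches it can recover), so the dynamic program
    is skipped.  Otherwise the affine-gap dynamic program is delegated to
    Bio.Align.PairwiseAligner with the identical scoring scheme; ties are
    broken deterministically by taking its first reported optimal traceback.
    """
    if not insert or not product_ref:
        raise ValueError("sequences must be non-empty")
    n = len(product_ref)
    if len(insert) == n:
        a = np.frombuffer(insert.encode(), dtype=np.uint8)
        b = np.frombuffer(product_ref.encode(), dtype=np.uint8)
        mismatches = int((a != b).sum())
        # gapless score n - mm beats the <= n - 1 + 2*gap_open bound
        if params.match == 1.0 and params.mismatch == 0.0 and (
            mismatches < 2 * -params.gap_open
        ):
            idx = np.arange(n)
            return AlignmentResult(float(n - mismatches), idx, idx.copy(),
                                   insert, False)
    aligner = _make_aligner(params)
    aln = aligner.align(insert, product_ref)[0]
    indices = aln.indices  # 2 x columns, -1 at gaps
    qry_idx, ref_idx = indices[0], indices[1]
    has_indel = bool((qry_idx < 0).any() or (ref_idx < 0).any())
    return AlignmentResult(float(aln.score), ref_idx.astype(np.int64),
                           qry_idx.astype(np.int64), insert, has_indel)


def accept_alignment(result: AlignmentResult,
                     params: AlignmentParams = AlignmentParams()) -> bool:
    """Keep an alignment iff insert length >= 70 and score > 60 (strict)."""
    return (len(result.query) >= params.min_insert_len
            and result.score > params.min_score)


@dataclass
class MisincorporationTally:
    """Per-position, per-template-base and transition counts for one well.

    ``n_p``/``N_p`` are error and total event counts per extension position;
    ``transition_counts[t, i]`` counts template base ``BASES[t]`` opposite
    incorporated dNTP ``BASES[i]`` (correct incorporations sit in the
    Watson-Crick cells ``(b, complement(b))``).
    """

    template: TemplateSpec
    n_p: np.ndarray
    N_p: np.ndarray
    transition_counts: np.ndarray
    reads_used: int = 0
    reads_rejected_by_alignment: int = 0

    @classmethod
    def empty(cls, template: TemplateSpec) -> "MisincorporationTally":
        L = template.length
        return cls(template, np.zeros(L, dtype=np.int64),
                   np.zeros(L, dtype=np.int64),
                   np.zeros((4, 4), dtype=np.int64))

    def base_totals(self) -> np.ndarray:
        return self.transition_counts.sum(axis=1)

    def base_errors(self) -> np.ndarray:
        correct = self.transition_counts[np.arange(4), 3 - np.arange(4)]
        return self.base_totals() - correct

    def check_conservation(self) -> bool:
        return (int(self.N_p.sum()) == int(self.base_totals().sum())
                and np.all(self.n_p <= self.N_p))

    def add(self, other: "MisincorporationTally") -> "MisincorporationTally":
        return MisincorporationTally(
            self.template,
            self.n_p + other.n_p,
            self.N_p + other.N_p,
            self.transition_counts + other.transition_counts,
            self.reads_used + other.reads_used,
            self.reads_rejected_by_alignment + other.reads_rejected_by_alignment,
        )


def _template_base_codes(template: TemplateSpec) -> np.ndarray:
    """Template-strand base code at extension position p (0-based array)."""
    return np.array([_CODE[b] for b in template.bases_by_position], dtype=np.int64)


def tally(alignments: Iterable[AlignmentResult],
          template: TemplateSpec) -> MisincorporationTally:
    """Count misincorporations from accepted alignments.

    For each alignment column with a base on both sides, the total at the
    corresponding extension position and the (template base, incorporated
    dNTP) cell are incremented; mismatches additionally increment the error
    count.  Gap columns and ambiguous (N) read bases are excluded from both
    numerator and denominator.
    """
    out = MisincorporationTally.empty(template)
    ref = template.product_ref
    tbase = _template_base_codes(template)
    L = template.length
    for aln in alignments:
        out.reads_used += 1
        for ref_i, qry_i in zip(aln.ref_idx, aln.qry_idx):
            if ref_i < 0 or qry_i < 0:
                continue
            if ref_i >= L:
                raise ValueError("alignment references positions outside the template")
            q = aln.query[qry_i]
            if q not in _CODE:
                continue  # ambiguous base: excluded like an indel column
            out.N_p[ref_i] += 1
            qc = _CODE[q]
            out.transition_counts[tbase[ref_i], qc] += 1
            if q != ref[ref_i]:
                out.n_p[ref_i] += 1
    return out


def tally_inserts(
    inserts: Sequence[str],
    template: TemplateSpec,
    params: AlignmentParams = AlignmentParams(),
    return_error_matrix: bool = False,
):
    """Align, filter and tally a well's inserts in one pass.

    Full-length gapless inserts (the overwhelming majority) are counted with
    vectorised array arithmetic; anything else goes through the full
    alignment path.  With ``return_error_matrix=True`` also returns the
    binary reads-x-positions error matrix built from the indel-free
    full-length reads (see :func:`error_matrix`).
    """
    ref = template.product_ref
    refb = np.frombuffer(ref.encode(), dtype=np.uint8)
    L = template.length
    tbase = _template_base_codes(template)
    tally_out = MisincorporationTally.empty(template)

    full_len: list[str] = []
    slow: list[str] = []
    for ins in inserts:
        if len(ins) < params.min_insert_len:
            tally_out.reads_rejected_by_alignment += 1
        elif len(ins) == L and "N" not in ins:
            full_len.append(ins)
        else:
            slow.append(ins)

    rows = None
    if full_len:
        mat = np.frombuffer("".join(full_len).encode(), dtype=np.uint8)
        mat = mat.reshape(len(full_len), L)
        mism = mat != refb[None, :]
        mm_counts = mism.sum(axis=1)
        gapless_ok = mm_counts < 2 * -params.gap_open
        scores = L - mm_counts
        accepted = gapless_ok & (scores > params.min_score)
        # equal-length reads with pathological mismatch loads fall back to
        # the full dynamic program
        for i in np.nonzero(~gapless_ok)[0]:
            slow.append(full_len[i])
        amat = mat[accepted]
        amism = mism[accepted]
        tally_out.reads_used += int(accepted.sum())
        tally_out.n_p += amism.sum(axis=0)
        tally_out.N_p += np.full(L, amat.shape[0], dtype=np.int64)
        # transition counts via joint (template base, read base) histogram
        code_of = np.full(256, -1, dtype=np.int64)
        for b, c in _CODE.items():
            code_of[ord(b)] = c
        qcodes = code_of[amat]
        joint = tbase[None, :] * 4 + qcodes
        tally_out.transition_counts += np.bincount(
            joint.ravel(), minlength=16).reshape(4, 4)
        rejected_fast = int(gapless_ok.sum() - accepted.sum())
        tally_out.reads_rejected_by_alignment += rejected_fast
        if return_error_matrix:
            rows = amism  # every accepted fast-path read is indel-free

    slow_alns = []
    for ins in slow:
        aln = global_align(ins, ref, params)
        if accept_alignment(aln, params):
            slow_alns.append(aln)
        else:
            tally_out.reads_rejected_by_alignment += 1
    if slow_alns:
        slow_tally = tally(slow_alns, template)
        tally_out = tally_out.add(slow_tally)

    if return_error_matrix:
        n70 = min(70, L)
        if rows is None:
            rows = np.zeros((0, L), dtype=bool)
        # indel-free reads only: gapless full-length alignments from the fast
        # path plus any slow-path alignments without gaps
        extra = [
            (np.frombuffer(a.query.encode(), dtype=np.uint8) != refb)
            for a in slow_alns if not a.has_indel and len(a.query) == L
        ]
        if extra:
            rows = np.vstack([rows] + [e[None, :] for e in extra])
        return tally_out, rows[:, :n70].astype(np.uint8)
    return tally_out


def error_matrix(inserts: Sequence[str], template: TemplateSpec,
                 params: AlignmentParams = AlignmentParams(),
                 n_positions: int = 70) -> np.ndarray:
    """Binary (reads x positions) error-indicator matrix over the first
    ``n_positions`` extension positions, from accepted indel-free reads."""
    _, mat = tally_inserts(inserts, template, params, return_error_matrix=True)
    return mat[:, :n_positions]


# ---------------------------------------------------------------------------
# Rates, replicate statistics, noise floor
# ---------------------------------------------------------------------------


@dataclass
class RateTables:
    """Per-position and per-template-base misincorporation rates of a well."""

    position: pd.DataFrame  # position, template_base, errors, total, rate
    base: pd.DataFrame      # template_base, errors, total, rate
    mean_rate: float        # unweighted mean of the four per-base rates


def rates(tally_: MisincorporationTally) -> RateTables:
    """Misincorporation rates as ratios of error to total counts.

    Positions or bases with zero denominator get NaN rates and are excluded
    from the mean; the mean misincorporation rate is the unweighted average
    of the four per-template-base rates.
    """
    L = tally_.template.length
    tb = tally_.template.bases_by_position
    with np.errstate(invalid="ignore", divide="ignore"):
        pos_rate = np.where(tally_.N_p > 0, tally_.n_p / np.maximum(tally_.N_p, 1),
                            np.nan)
    position = pd.DataFrame({
        "position": np.arange(1, L + 1),
        "template_base": list(tb),
        "errors": tally_.n_p,
        "total": tally_.N_p,
        "rate": pos_rate,
    })
    be, bt = tally_.base_errors(), tally_.base_totals()
    base_rate = np.where(bt > 0, be / np.maximum(bt, 1), np.nan)
    base = pd.DataFrame({
        "template_base": list(BASES),
        "errors": be,
        "total": bt,
        "rate": base_rate,
    })
    mean_rate = float(np.nanmean(base_rate)) if np.isfinite(base_rate).any() else float("nan")
    return RateTables(position, base, mean_rate)


def transition_matrix(tally_: MisincorporationTally) -> pd.DataFrame:
    """Normalised wrong-dNTP distributions per template base.

    Rows are template bases, columns incorporated dNTPs; the correct
    (Watson-Crick) cell is set to NaN and each row of wrong-dNTP counts is
    normalised to sum to 1.  Rows with zero errors are omitted.
    """
    rows = {}
    for t, base in enumerate(BASES):
        counts = tally_.transition_counts[t].astype(float)
        counts[3 - t] = np.nan  # correct incorporation
        total = np.nansum(counts)
        if total > 0:
            rows[base] = counts / total
    return pd.DataFrame(rows, index=list(BASES)).T


@dataclass(frozen=True)
class RateEstimate:
    """Replicate-averaged rate with its standard error of duplicate means."""

    rate: float
    sem: float  # NaN flags a single-well estimate
    n_replicates: int


def replicate_stats(values: Sequence[float]) -> RateEstimate:
    """Mean and standard error (sd/sqrt(n)) over duplicate wells; a single
    well yields SEM = NaN as an explicit flag."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if vals.size == 0:
        return RateEstimate(float("nan"), float("nan"), 0)
    if vals.size == 1:
        return RateEstimate(float(vals[0]), float("nan"), 1)
    sem = float(vals.std(ddof=1) / np.sqrt(vals.size))
    return RateEstimate(float(vals.mean()), sem, int(vals.size))


@dataclass(frozen=True)
class NoiseFloor:
    """Apparent misincorporation floor measured with a high-fidelity control.

    ``mean_floor`` is the mean plus SEM of the control's mean (over template
    bases) misincorporation rate across wells; ``spatial_floor`` is the
    maximum over positions of the replicate-mean rate plus its SEM.
    """

    mean_floor: float
    spatial_floor: float


def noise_floor(control_tallies: Sequence[MisincorporationTally]) -> NoiseFloor:
    if not control_tallies:
        raise ValueError("need at least one control tally")
    mean_rates = []
    pos_rates = []
    for t in control_tallies:
        rt = rates(t)
        mean_rates.append(rt.mean_rate)
        pos_rates.append(rt.position["rate"].to_numpy())
    est = replicate_stats(mean_rates)
    sem = est.sem if np.isfinite(est.sem) else 0.0
    mean_floor = est.rate + sem
    pos = np.vstack(pos_rates)
    with np.errstate(invalid="ignore"):
        pos_mean = np.nanmean(pos, axis=0)
        n = np.isfinite(pos).sum(axis=0)
        if pos.shape[0] > 1:
            dev = pos - pos_mean[None, :]
            ss = np.nansum(dev * dev, axis=0)
            sd = np.sqrt(ss / np.maximum(n - 1, 1))
            pos_sem = np.where(n > 1, sd / np.sqrt(np.maximum(n, 1)), 0.0)
        else:
            pos_sem = np.zeros(pos.shape[1])
    spatial = np.nanmax(pos_mean + pos_sem) if np.isfinite(pos_mean).any() else float("nan")
    return NoiseFloor(float(mean_floor), float(spatial))
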