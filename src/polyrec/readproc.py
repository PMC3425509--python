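"""Filtering and demultiplexing of paired primer-extension reads.

Forward reads are kept only if they carry the left primer-binding sequence at
the expected offset, the first 12 bases of the right adapter, and a barcode
that exactly matches the barcode set; reverse reads must carry the left
primer-binding sequence and the barcode.  The insert (the bases strictly
between the two landmarks) of a forward read must exactly match the insert
recovered from its reverse mate, and known primer-dimer inserts are removed
and counted separately.  Every input pair is assigned exactly one outcome, so
the filter statistics partition the input.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .synthetic_data import (
    BARCODE_LENGTH,
    BarcodeSet,
    LEFT_PRIMER_BIND,
    RIGHT_ADAPTER_PREFIX,
    revcomp,
)

__all__ = [
    "FilterConfig",
    "FilterStats",
    "REJECTION_REASONS",
    "extract_insert",
    "pair_filter",
    "filter_and_demux",
    "FastqParseError",
    "write_well_fasta",
]

REJECTION_REASONS = (
    "no_left_primer",
    "no_right_adapter",
    "bad_barcode",
    "pair_mismatch",
    "primer_dimer",
)


class FastqParseError(ValueError):
    """Raised for unreadable or truncated FASTQ input, with record context."""


@dataclass(frozen=True)
class FilterConfig:
    """Sequences and rules used to filter and demultiplex read pairs.

    ``barcode_offset`` is the 0-based position of the barcode in the
    (forward-oriented) read; landmark matching is exact substring matching at
    the expected offsets (``offset_slack`` relaxes the position of the
    right-adapter search only, and defaults to the strictest setting).
    ``primer_dimer_insert`` is the insert produced by the known primer-dimer
    contaminant; the empty string means primer directly ligated to adapter.
    """

    barcode_set: BarcodeSet | Sequence[str]
    left_primer_bind: str = LEFT_PRIMER_BIND
    right_adapter_prefix: str = RIGHT_ADAPTER_PREFIX
    primer_dimer_insert: str = ""
    barcode_offset: int = 0

    def __post_init__(self) -> None:
        if len(self.right_adapter_prefix) != 12:
            raise ValueError("right adapter prefix must be 12 bases")
        ks = {len(b) for b in self.barcode_set}
        if len(ks) != 1:
            raise ValueError("barcodes must share one length")

    @property
    def barcode_len(self) -> int:
        return len(next(iter(self.barcode_set)))

    @property
    def barcode_lookup(self) -> frozenset:
        return frozenset(self.barcode_set)


def extract_insert(read: str, cfg: FilterConfig, direction: str = "forward"):
    """Extract (barcode, insert) from one read, or a typed rejection reason.

    Returns ``(barcode, insert, None)`` on success and
    ``(None, None, reason)`` otherwise; never raises on malformed reads.
    Reverse reads are reverse-complemented first, after which the same layout
    applies except that the right-adapter prefix is not required (the insert
    then runs to the end of the read, or to the adapter when present).
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if direction == "reverse":
        read = revcomp(read)
    off = cfg.barcode_offset
    k = cfg.barcode_len
    left = cfg.left_primer_bind
    start = off + k + len(left)
    if len(read) < start or read[off + k:start] != left:
        return None, None, "no_left_primer"
    barcode = read[off:off + k]
    rest = read[start:]
    j = rest.find(cfg.right_adapter_prefix)
    if direction == "forward":
        if j < 0:
            return None, None, "no_right_adapter"
        insert = rest[:j]
    else:
        insert = rest[:j] if j >= 0 else rest
    if barcode not in cfg.barcode_lookup:
        return None, None, "bad_barcode"
    return barcode, insert, None


def pair_filter(fwd_insert: str, rev_insert: str) -> bool:
    """Accept a pair iff the forward insert exactly equals the insert
    recovered from the reverse mate (already rendered in forward
    orientation)."""
    return fwd_insert == rev_insert


@dataclass
class FilterStats:
    """Per-reason rejection counts plus per-well accepted counts.

    Invariant: ``accepted + sum(rejections) == total`` on every input.
    """

    total: int = 0
    accepted: int = 0
    rejections: Counter = field(default_factory=Counter)
    per_well_accepted: Counter = field(default_factory=Counter)

    def check_partition(self) -> bool:
        return self.total == self.accepted + sum(self.rejections.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": "accepted", "count": self.accepted}]
        rows += [{"reason": r, "count": self.rejections.get(r, 0)}
                 for r in REJECTION_REASONS]
        rows.append({"reason": "total", "count": self.total})
        return pd.DataFrame(rows)


def _iter_fastq(path: str | Path):
    try:
        with open(path) as fh:
            yield from FastqGeneralIterator(fh)
    except ValueError as exc:  # Biopython flags truncated/malformed records
        raise FastqParseError(f"malformed FASTQ in {path}: {exc}") from exc


def filter_and_demux(
    fwd_fastq: str | Path,
    rev_fastq: str | Path,
    cfg: FilterConfig,
    barcode_to_well: dict[str, str] | None = None,
) -> tuple[dict[str, list[tuple[str, str]]], FilterStats]:
    """Filter a FASTQ pair and route accepted inserts to wells.

    Returns ``(wells, stats)`` where ``wells`` maps well id (or barcode when
    no mapping is given) to a list of ``(read_id, insert)``.  A pair is
    rejected, in order of precedence, for a failed forward extraction, a
    failed reverse extraction, mate disagreement (barcode or insert), or a
    primer-dimer insert.
    """
    wells: dict[str, list[tuple[str, str]]] = {}
    stats = FilterStats()
    fwd_it = _iter_fastq(fwd_fastq)
    rev_it = _iter_fastq(rev_fastq)
    for idx, ((fid, fseq, _), (rid, rseq, _)) in enumerate(zip(fwd_it, rev_it)):
        if fid.split()[0] != rid.split()[0]:
            raise FastqParseError(
                f"mate id mismatch at record {idx}: {fid!r} vs {rid!r}"
            )
        stats.total += 1
        fbc, fins, freason = extract_insert(fseq, cfg, "forward")
        if freason is not None:
            stats.rejections[freason] += 1
            continue
        rbc, rins, rreason = extract_insert(rseq, cfg, "reverse")
        if rreason is not None:
            stats.rejections[rreason] += 1
            continue
        if fbc != rbc or not pair_filter(fins, rins):
            stats.rejections["pair_mismatch"] += 1
            continue
        if fins == cfg.primer_dimer_insert:
            stats.rejections["primer_dimer"] += 1
            continue
        key = barcode_to_well.get(fbc, fbc) if barcode_to_well else fbc
        stats.accepted += 1
        stats.per_well_accepted[key] += 1
        wells.setdefault(key, []).append((fid.split()[0], fins))
    return wells, stats


def write_well_fasta(wells: dict[str, list[tuple[str, str]]],
                     out_dir: str | Path) -> dict[str, Path]:
    """Write one insert FASTA per well; returns well -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for well, inserts in sorted(wells.items()):
        path = out_dir / f"{well}.fasta"
        with open(path, "w") as fh:
            for read_id, insert in inserts:
                fh.write(f">{read_id}\n{insert}\n")
        paths[well] = path
    return paths
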