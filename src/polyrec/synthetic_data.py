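"""Seeded synthetic plates of barcoded error-prone primer-extension reads.

This module emulates, in silico, a multiplexed primer-extension assay used to
measure how divalent cation concentrations (Mn2+, Mg2+, Ca2+) modulate the
misincorporation rate of error-prone DNA polymerases.  Barcoded primers are
annealed to a known single-stranded template; an error-prone polymerase copies
a 76-base extension region; a partial sequencing adapter is ligated downstream;
and paired-end reads of the amplified products are emitted as FASTQ, together
with complete ground-truth tables, so that every downstream stage (filtering,
demultiplexing, alignment, misincorporation calling, transfer-function fits,
correlation statistics, information-theoretic summaries) can be tested against
known truth without any external data.

The generative model per molecule:

* the template copy carries rare substitution impurities (the synthesis
  "noise floor"), drawn per position;
* a unit-mean Gamma multiplier models molecule-to-molecule rate heterogeneity
  (overdispersion of per-read error counts);
* at each extension position the polymerase misincorporates with probability
  ``clip(multiplier * r_b + eps * prev_error, 0, 1)``, where ``r_b`` is the
  cation-dependent per-template-base rate and ``eps`` an optional lag-one
  coupling; the wrong dNTP is drawn from a cation-independent transition row;
* abortive termination and rare indels shorten or corrupt the product.

Polymerase presets (``dpo4_paper``, ``klenow_paper``, ``phusion_control``) are
constraint-calibrated so that the synthetic plates reproduce the headline
behaviour of Dpo4, Klenow exo- and a high-fidelity control: see
``data/presets.yaml`` and docs/methods.md for the calibration constraints.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "BASES",
    "revcomp",
    "TemplateSpec",
    "ORIGINAL_TEMPLATE",
    "SWAPPED_TEMPLATE",
    "get_template",
    "LEFT_ADAPTER",
    "LEFT_PRIMER_BIND",
    "RIGHT_ADAPTER",
    "RIGHT_ADAPTER_PREFIX",
    "BarcodeSet",
    "BarcodeInfeasibleError",
    "generate_barcodes",
    "CationCondition",
    "PolymerasePreset",
    "available_presets",
    "get_preset",
    "rate_oracle",
    "PlateDesign",
    "Well",
    "make_titration_plate",
    "write_plate_tsv",
    "read_plate_tsv",
    "simulate_extension",
    "simulate_well",
    "simulate_plate",
    "toy_structure_profile",
    "DEFAULT_NOISE_FLOOR",
    "DEFAULT_DIMER_FRACTION",
    "DEFAULT_MN_GRID_UM",
    "DEFAULT_MG_GRID_UM",
]

# ---------------------------------------------------------------------------
# DNA helpers and assay constants
# ---------------------------------------------------------------------------

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_ASCII = np.frombuffer(BASES.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (supports N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def _codes(seq: str) -> np.ndarray:
    """Encode ACGT as uint8 0..3 (complement of code c is 3 - c)."""
    return np.fromiter((_CODE[b] for b in seq), dtype=np.uint8, count=len(seq))


def _decode_row(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode()


# Oligos of the assay.  The barcoded extension primer is
# LEFT_ADAPTER + <5-mer barcode> + LEFT_PRIMER_BIND; the ligated downstream
# adapter contributes RIGHT_ADAPTER on the read strand.  A forward read starts
# right after the sequencing primer, i.e. with the barcode.
LEFT_ADAPTER = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT"
LEFT_PRIMER_BIND = "GATGGTCATAGCTGTTGTA"
RIGHT_ADAPTER = "AGATCGGAAGAGCGGTTCAGCAGGAATGCCGAG"
RIGHT_ADAPTER_PREFIX = RIGHT_ADAPTER[:12]

DEFAULT_NOISE_FLOOR = 1e-4
DEFAULT_DIMER_FRACTION = 0.02
BARCODE_LENGTH = 5

#: Default titration grids (micromolar).  The assay's published endpoints are
#: 75/800 uM Mn2+ and 1000/7000 uM Mg2+; interior points are spaced for a
#: stable least-squares slope.
DEFAULT_MN_GRID_UM = (10.0, 25.0, 75.0, 200.0, 400.0, 800.0)
DEFAULT_MG_GRID_UM = (1000.0, 2000.0, 4000.0, 7000.0)


# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TemplateSpec:
    """A single-stranded DNA template for the primer-extension assay.

    Parameters
    ----------
    name : str
        Short label (``"original"`` or ``"swapped"`` for the bundled ones).
    template_seq : str
        Template strand, 5'->3'.  The 3'-terminal base is a dideoxy-C and is
        never copied (it blocks extension along the upstream primer).
    primer_binding_len : int
        Number of 3'-terminal template bases (including the ddC) annealed by
        the primer 3' tail.
    extension_start, extension_end : int
        Half-open interval of 0-based template positions copied by the
        polymerase (the extension region).

    Notes
    -----
    Coordinate convention used throughout the package: extension positions
    are 1-based *in the order the polymerase adds bases*, i.e. position 1 is
    the template base adjacent to the primer (template index
    ``extension_end - 1``) and position L is the template 5' end.  A forward
    sequencing read contains the product strand in exactly this order, so
    alignment columns of a read against ``product_ref`` map directly onto
    extension positions.
    """

    name: str
    template_seq: str
    primer_binding_len: int = 19
    extension_start: int = 0
    extension_end: int = 76

    def __post_init__(self) -> None:
        ext = self.extension_seq
        if not ext or set(self.template_seq) - set(BASES):
            raise ValueError("template must be non-empty ACGT")
        # the primer 3' tail must anneal perfectly to the template 3' end
        # (the terminal template base is the non-extensible ddC)
        tail = self.template_seq[-self.primer_binding_len:]
        if revcomp(tail) != LEFT_PRIMER_BIND[-self.primer_binding_len:]:
            raise ValueError(
                f"primer tail does not anneal to the 3' end of template {self.name!r}"
            )

    @property
    def extension_seq(self) -> str:
        """Extension region of the template strand, 5'->3'."""
        return self.template_seq[self.extension_start:self.extension_end]

    @property
    def length(self) -> int:
        return self.extension_end - self.extension_start

    @property
    def product_ref(self) -> str:
        """Theoretical error-free extension product (reverse complement of
        the extension region); the alignment reference for all reads."""
        return revcomp(self.extension_seq)

    @property
    def bases_by_position(self) -> str:
        """Template-strand base at extension positions 1..L (extension order)."""
        return self.extension_seq[::-1]


ORIGINAL_TEMPLATE = TemplateSpec(
    name="original",
    template_seq=(
        "AAAATCATAACTAAGTCAGTCAGTACGTCAGTAGCTCAGTCGATGGATGCAATGAATGAATGAATG"
        "AAAATAAAAATACAACAGCTATGACCATC"
    ),
)

SWAPPED_TEMPLATE = TemplateSpec(
    name="swapped",
    template_seq=(
        "CGATGGATGCAATGAATGAATGAATGAAAATAAAAAAAAATCATAACTAAGTCAGTCAGTACGTCA"
        "GTAGCTCAGTTACAACAGCTATGACCATC"
    ),
)

_TEMPLATES = {t.name: t for t in (ORIGINAL_TEMPLATE, SWAPPED_TEMPLATE)}


def get_template(name: str) -> TemplateSpec:
    """Look up a bundled template by name (``original`` or ``swapped``)."""
    try:
        return _TEMPLATES[name]
    except KeyError:
        raise KeyError(f"unknown template {name!r}; choose from {sorted(_TEMPLATES)}")


# ---------------------------------------------------------------------------
# Barcodes
# ---------------------------------------------------------------------------


class BarcodeInfeasibleError(RuntimeError):
    pass


@dataclass(frozen=True)
class BarcodeSet:
    """A set of equal-length well barcodes with a guaranteed minimum pairwise
    Levenshtein distance."""

    barcodes: tuple[str, ...]
    min_pairwise_levenshtein: int

    def __post_init__(self) -> None:
        ks = {len(b) for b in self.barcodes}
        if len(ks) != 1:
            raise ValueError("barcodes must have equal length")
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be distinct")

    @property
    def k(self) -> int:
        return len(self.barcodes[0])

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    def __contains__(self, item: str) -> bool:
        return item in set(self.barcodes)


def _levenshtein(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def generate_barcodes(n: int, k: int = BARCODE_LENGTH, min_dist: int = 2,
                      seed: int = 0) -> BarcodeSet:
    """Greedily assemble ``n`` distinct ``k``-mers with pairwise Levenshtein
    distance >= ``min_dist``.

    Candidates are the full 4**k space (or a seeded random sample of it when
    that space is very large), visited in a seeded random order; a candidate
    is kept if it is at least ``min_dist`` edits from every kept barcode.

    Raises
    ------
    BarcodeInfeasibleError
        If the candidate pool is exhausted before ``n`` barcodes are found.
    """
    if n < 1 or k < 1 or min_dist < 1:
        raise ValueError("n, k and min_dist must all be >= 1")
    rng = np.random.default_rng(seed)
    space = 4 ** k
    if space <= 4 ** 8:
        order = rng.permutation(space)
        candidates = ("".join(BASES[(c >> (2 * i)) & 3] for i in range(k))
                      for c in order)
    else:  # sample without full enumeration; still deterministic given seed
        candidates = ("".join(rng.choice(list(BASES), size=k))
                      for _ in range(200 * n))
    kept: list[str] = []
    for cand in candidates:
        if all(_levenshtein(cand, b) >= min_dist for b in kept):
            kept.append(cand)
            if len(kept) == n:
                return BarcodeSet(tuple(kept), min_dist)
    raise BarcodeInfeasibleError(
        f"could not find {n} barcodes of length {k} with pairwise "
        f"Levenshtein distance >= {min_dist} (found {len(kept)})"
    )


# ---------------------------------------------------------------------------
# Cation conditions and polymerase presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CationCondition:
    """Divalent cation concentrations of one extension reaction (micromolar)."""

    mn_uM: float = 0.0
    mg_uM: float = 0.0
    ca_uM: float = 0.0

    def __post_init__(self) -> None:
        if min(self.mn_uM, self.mg_uM, self.ca_uM) < 0:
            raise ValueError("concentrations must be >= 0")

    def label(self) -> str:
        return f"mn{self.mn_uM:g}_mg{self.mg_uM:g}_ca{self.ca_uM:g}"


@dataclass(frozen=True)
class _RateParams:
    """Cation -> misincorporation-rate coefficients for one template base.

    The pre-clip rate is ``r0 + mn_amp * (mn_mM ** mn_gamma)
    + mg_amp * (mg_mM ** mg_gamma)``; concentrations enter in mM.
    """

    r0: float = 0.0
    mn_amp: float = 0.0
    mn_gamma: float = 1.0
    mg_amp: float = 0.0
    mg_gamma: float = 1.0


@dataclass(frozen=True)
class _CaModifier:
    """Piecewise log-linear fold multiplier keyed by Ca2+ concentration.

    ``knots`` is a sequence of (ca_uM, fold) pairs with strictly increasing
    ca_uM; the fold is interpolated linearly in log10(ca_uM) between knots
    and clamped to the terminal values outside them.  Which curve applies is
    selected by the background cation (Mn2+ takes precedence over Mg2+).
    """

    knots: tuple[tuple[float, float], ...] = ((1.0, 1.0),)

    def __call__(self, ca_uM: float) -> float:
        xs = np.log10([k[0] for k in self.knots])
        ys = [k[1] for k in self.knots]
        if ca_uM <= 0:
            return ys[0]
        return float(np.interp(math.log10(ca_uM), xs, ys))


@dataclass(frozen=True)
class PolymerasePreset:
    """Parametric misincorporation model of one polymerase.

    Attributes
    ----------
    rate_params : dict
        Per template base, the cation->rate coefficients (see `_RateParams`).
    transition_rows : dict
        Per template base, a probability distribution over the three wrong
        incoming dNTPs (cation independent; each row sums to 1).
    heterogeneity_shape : float
        Shape k of the unit-mean Gamma multiplier applied per molecule;
        ``inf`` means a homogeneous (Poisson) ensemble.
    lag1_boost : float
        Additive probability added to the error probability of the base
        immediately after a misincorporation.
    truncation_prob, indel_prob : float
        Per-position probabilities of abortive termination and of each indel
        flavour (insertion / deletion).
    ca_modifiers : dict
        Fold-multiplier curves keyed by background (``mn_background`` /
        ``mg_background``).
    """

    name: str
    rate_params: dict[str, _RateParams]
    transition_rows: dict[str, dict[str, float]]
    heterogeneity_shape: float = math.inf
    lag1_boost: float = 0.0
    truncation_prob: float = 0.0
    indel_prob: float = 0.0
    r_max: float = 0.5
    ca_modifiers: dict[str, _CaModifier] = field(default_factory=dict)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.heterogeneity_shape > 0:
            raise ValueError("heterogeneity_shape must be > 0")
        for b in BASES:
            row = self.transition_rows[b]
            wrong = set(BASES) - {revcomp(b)}
            if set(row) != wrong:
                raise ValueError(
                    f"transition row for template {b} must cover the wrong "
                    f"dNTPs {sorted(wrong)}"
                )
            if abs(sum(row.values()) - 1.0) > 1e-9:
                raise ValueError(f"transition row for template {b} must sum to 1")
            if min(row.values()) < 0:
                raise ValueError("transition probabilities must be >= 0")

    def ca_modifier(self, cond: CationCondition) -> float:
        if cond.mn_uM > 0:
            mod = self.ca_modifiers.get("mn_background")
        elif cond.mg_uM > 0:
            mod = self.ca_modifiers.get("mg_background")
        else:
            mod = None
        return mod(cond.ca_uM) if mod is not None else 1.0

    def rate(self, base: str, cond: CationCondition) -> float:
        p = self.rate_params[base]
        mn_mM = cond.mn_uM / 1000.0
        mg_mM = cond.mg_uM / 1000.0
        r = p.r0
        if p.mn_amp:
            r += p.mn_amp * mn_mM ** p.mn_gamma
        if p.mg_amp:
            r += p.mg_amp * mg_mM ** p.mg_gamma
        r *= self.ca_modifier(cond)
        return float(min(max(r, 0.0), self.r_max))

    def rate_vector(self, cond: CationCondition) -> np.ndarray:
        return np.array([self.rate(b, cond) for b in BASES])

    def wrong_base_tables(self) -> tuple[np.ndarray, np.ndarray]:
        """(4,3) arrays of wrong-base codes and their cumulative probabilities,
        row-indexed by template-base code."""
        codes = np.zeros((4, 3), dtype=np.uint8)
        cum = np.zeros((4, 3))
        for b in BASES:
            row = self.transition_rows[b]
            wrong = sorted(row)  # deterministic order
            codes[_CODE[b]] = [_CODE[w] for w in wrong]
            cum[_CODE[b]] = np.cumsum([row[w] for w in wrong])
        return codes, cum


def rate_oracle(preset: PolymerasePreset, base: str, cond: CationCondition) -> float:
    """Exact per-base misincorporation probability used by the simulator at
    ``cond``, before heterogeneity and lag-one coupling.

    This is the analytic ground truth that downstream estimators are tested
    against.
    """
    return preset.rate(base, cond)


def _load_preset_file() -> dict:
    text = resources.files("polyrec").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


_PRESET_CACHE: dict[str, PolymerasePreset] = {}


def available_presets() -> list[str]:
    return sorted(_load_preset_file()["presets"])


def get_preset(name: str) -> PolymerasePreset:
    """Load a bundled polymerase preset (``dpo4_paper``, ``klenow_paper`` or
    ``phusion_control``) from the versioned preset file."""
    if name in _PRESET_CACHE:
        return _PRESET_CACHE[name]
    data = _load_preset_file()["presets"]
    if name not in data:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(data)}")
    d = data[name]
    shape = d.get("heterogeneity_shape")
    preset = PolymerasePreset(
        name=name,
        rate_params={b: _RateParams(**d["rate_params"][b]) for b in BASES},
        transition_rows={b: dict(d["transition_rows"][b]) for b in BASES},
        heterogeneity_shape=math.inf if shape in (None, "inf") else float(shape),
        lag1_boost=float(d.get("lag1_boost", 0.0)),
        truncation_prob=float(d.get("truncation_prob", 0.0)),
        indel_prob=float(d.get("indel_prob", 0.0)),
        r_max=float(d.get("r_max", 0.5)),
        ca_modifiers={
            key: _CaModifier(tuple((float(x), float(y)) for x, y in knots))
            for key, knots in d.get("ca_modifiers", {}).items()
        },
        description=d.get("description", ""),
    )
    _PRESET_CACHE[name] = preset
    return preset


# ---------------------------------------------------------------------------
# Plate designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Well:
    well_id: str
    barcode: str
    condition: CationCondition
    replicate_group: str


@dataclass(frozen=True)
class PlateDesign:
    """Wells of one synthetic plate: barcode, cation condition and replicate
    group per well, plus the per-well read depth and the preset to simulate."""

    wells: tuple[Well, ...]
    reads_per_well: int
    preset_name: str

    def __post_init__(self) -> None:
        bcs = [w.barcode for w in self.wells]
        if len(set(bcs)) != len(bcs):
            raise ValueError("well barcodes must be unique")
        if self.reads_per_well < 1:
            raise ValueError("reads_per_well must be >= 1")

    def barcode_to_well(self) -> dict[str, str]:
        return {w.barcode: w.well_id for w in self.wells}

    def replicate_groups(self) -> dict[str, list[Well]]:
        groups: dict[str, list[Well]] = {}
        for w in self.wells:
            groups.setdefault(w.replicate_group, []).append(w)
        return groups


def make_titration_plate(
    varied: str,
    grid_uM: Sequence[float],
    preset_name: str,
    reads_per_well: int,
    *,
    duplicates: int = 2,
    background: CationCondition | None = None,
    barcodes: BarcodeSet | None = None,
    barcode_seed: int = 20120822,
) -> PlateDesign:
    """Build a duplicate-well titration plate varying one cation over a grid.

    Every concentration appears in ``duplicates`` wells with distinct
    barcodes; ``background`` fixes the other cations (default: none).
    """
    if varied not in ("mn", "mg", "ca"):
        raise ValueError("varied must be one of 'mn', 'mg', 'ca'")
    bg = background or CationCondition()
    if barcodes is None:
        barcodes = generate_barcodes(len(grid_uM) * duplicates, seed=barcode_seed)
    if len(barcodes) < len(grid_uM) * duplicates:
        raise ValueError("not enough barcodes for the requested plate")
    wells = []
    it = iter(barcodes)
    for conc in grid_uM:
        kw = {"mn_uM": bg.mn_uM, "mg_uM": bg.mg_uM, "ca_uM": bg.ca_uM}
        kw[f"{varied}_uM"] = float(conc)
        cond = CationCondition(**kw)
        for rep in range(duplicates):
            wells.append(
                Well(
                    well_id=f"{varied}{conc:g}_r{rep + 1}",
                    barcode=next(it),
                    condition=cond,
                    replicate_group=f"{varied}{conc:g}",
                )
            )
    return PlateDesign(tuple(wells), reads_per_well, preset_name)


def write_plate_tsv(plate: PlateDesign, path: str | Path) -> None:
    rows = [
        {
            "well_id": w.well_id,
            "barcode": w.barcode,
            "mn_uM": w.condition.mn_uM,
            "mg_uM": w.condition.mg_uM,
            "ca_uM": w.condition.ca_uM,
            "replicate_group": w.replicate_group,
        }
        for w in plate.wells
    ]
    df = pd.DataFrame(rows)
    df.insert(0, "preset", plate.preset_name)
    df.insert(1, "reads_per_well", plate.reads_per_well)
    df.to_csv(path, sep="\t", index=False)


def read_plate_tsv(path: str | Path) -> PlateDesign:
    df = pd.read_csv(path, sep="\t")
    wells = tuple(
        Well(
            well_id=str(r.well_id),
            barcode=str(r.barcode),
            condition=CationCondition(float(r.mn_uM), float(r.mg_uM), float(r.ca_uM)),
            replicate_group=str(r.replicate_group),
        )
        for r in df.itertuples()
    )
    return PlateDesign(wells, int(df.reads_per_well.iloc[0]), str(df.preset.iloc[0]))


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


@dataclass
class WellTruth:
    """Ground truth for one simulated well.

    ``poly_errors``/``noise_errors`` are boolean (reads x L) matrices over
    extension positions (column p is extension position p+1); ``lengths``
    holds product lengths after truncation; ``insertions``/``deletions`` mark
    indel positions; ``product_codes`` is the emitted product base code at
    each position (pre-truncation).
    """

    well_id: str
    poly_errors: np.ndarray
    noise_errors: np.ndarray
    lengths: np.ndarray
    insertions: np.ndarray
    deletions: np.ndarray
    product_codes: np.ndarray
    products: list[str]

    @property
    def n_reads(self) -> int:
        return len(self.lengths)

    def total_poly_errors(self) -> int:
        return int(self.visible_poly_errors().sum())

    def visible_poly_errors(self) -> np.ndarray:
        """Polymerase errors within the realized product length."""
        L = self.poly_errors.shape[1]
        return self.poly_errors & (np.arange(L)[None, :] < self.lengths[:, None])

    def per_position_poly_errors(self) -> np.ndarray:
        return self.visible_poly_errors().sum(axis=0)


def simulate_well(
    template: TemplateSpec,
    preset: PolymerasePreset,
    cond: CationCondition,
    n_reads: int,
    rng: np.random.Generator,
    *,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    well_id: str = "well",
) -> WellTruth:
    """Simulate ``n_reads`` primer-extension products for one well.

    Vectorised across molecules; the per-position loop carries the lag-one
    error coupling.  Returns the products (as strings, truncated to their
    realized lengths, with indels applied) plus full truth matrices.
    """
    L = template.length
    # template base codes in extension order (position 1 abuts the primer)
    tmpl = _codes(template.bases_by_position)

    # synthesis impurities: substitute template bases uniformly at random
    noise = rng.random((n_reads, L)) < noise_floor
    shift = rng.integers(1, 4, size=(n_reads, L), dtype=np.uint8)
    t_eff = np.where(noise, (tmpl[None, :] + shift) % 4, tmpl[None, :])

    rates = preset.rate_vector(cond)
    r = rates[t_eff]
    if math.isfinite(preset.heterogeneity_shape):
        k = preset.heterogeneity_shape
        mult = rng.gamma(shape=k, scale=1.0 / k, size=(n_reads, 1))
    else:
        mult = np.ones((n_reads, 1))
    base_p = np.clip(mult * r, 0.0, 1.0)

    u = rng.random((n_reads, L))
    err = np.zeros((n_reads, L), dtype=bool)
    eps = preset.lag1_boost
    prev = np.zeros(n_reads, dtype=bool)
    for p in range(L):
        prob = base_p[:, p]
        if eps:
            prob = np.minimum(prob + eps * prev, 1.0)
        e = u[:, p] < prob
        err[:, p] = e
        prev = e

    # incorporated bases: Watson-Crick complement, or a wrong dNTP from the
    # template base's transition row
    prod = (3 - t_eff).astype(np.uint8)
    n_err = int(err.sum())
    if n_err:
        wrong_codes, wrong_cum = preset.wrong_base_tables()
        tb = t_eff[err]
        v = rng.random(n_err)
        idx = (v[:, None] > wrong_cum[tb]).sum(axis=1)
        prod[err] = wrong_codes[tb, np.minimum(idx, 2)]

    # abortive termination: product length = first stop position
    if preset.truncation_prob > 0:
        stop = rng.random((n_reads, L)) < preset.truncation_prob
        any_stop = stop.any(axis=1)
        lengths = np.where(any_stop, stop.argmax(axis=1), L).astype(np.int64)
    else:
        lengths = np.full(n_reads, L, dtype=np.int64)

    if preset.indel_prob > 0:
        ins = rng.random((n_reads, L)) < preset.indel_prob
        dele = rng.random((n_reads, L)) < preset.indel_prob
        ins_bases = rng.integers(0, 4, size=(n_reads, L), dtype=np.uint8)
    else:
        ins = np.zeros((n_reads, L), dtype=bool)
        dele = np.zeros_like(ins)
        ins_bases = None

    ascii_rows = _ASCII[prod]
    has_indel = (ins | dele).any(axis=1)
    products: list[str] = []
    for i in range(n_reads):
        li = lengths[i]
        if not has_indel[i]:
            products.append(ascii_rows[i, :li].tobytes().decode())
            continue
        out = []
        for p in range(li):
            if dele[i, p]:
                continue
            out.append(BASES[prod[i, p]])
            if ins[i, p]:
                out.append(BASES[ins_bases[i, p]])
        products.append("".join(out))

    return WellTruth(
        well_id=well_id,
        poly_errors=err,
        noise_errors=noise,
        lengths=lengths,
        insertions=ins,
        deletions=dele,
        product_codes=prod,
        products=products,
    )


def simulate_extension(
    template: TemplateSpec,
    preset: PolymerasePreset,
    cond: CationCondition,
    rng: np.random.Generator,
    *,
    noise_floor: float = 0.0,
) -> tuple[str, WellTruth]:
    """Simulate a single primer-extension product (convenience wrapper around
    :func:`simulate_well` with ``n_reads=1``); returns (product, truth)."""
    truth = simulate_well(template, preset, cond, 1, rng,
                          noise_floor=noise_floor, well_id="single")
    return truth.products[0], truth


@dataclass
class PlateSimResult:
    fwd_fastq: Path
    rev_fastq: Path
    plate_tsv: Path
    truth_tsv: Path
    well_truths: dict[str, WellTruth]
    n_pairs: int


def _fastq_record(read_id: str, seq: str) -> str:
    return f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n"


def simulate_plate(
    plate: PlateDesign,
    preset: PolymerasePreset,
    template: TemplateSpec,
    seed: int,
    out_dir: str | Path,
    *,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    dimer_fraction: float = DEFAULT_DIMER_FRACTION,
) -> PlateSimResult:
    """Simulate a full plate and write paired FASTQ plus ground-truth TSVs.

    Forward reads are ``barcode + left-primer-binding sequence + product +
    first 12 bases of the right adapter``; reverse reads are their exact
    reverse complements (the paired-end mates fully overlap the short
    amplicon).  A ``dimer_fraction`` of extra primer-dimer pairs per well
    (zero-length insert) emulates the known contaminant.  Output is
    bit-reproducible given ``seed``: well ``i`` uses the RNG stream
    ``SeedSequence(seed, spawn_key=(i,))``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fwd_path = out_dir / "reads_R1.fastq"
    rev_path = out_dir / "reads_R2.fastq"
    truth_path = out_dir / "truth_reads.tsv"
    plate_path = out_dir / "plate.tsv"
    write_plate_tsv(plate, plate_path)

    n_dimers = int(round(dimer_fraction * plate.reads_per_well))
    well_truths: dict[str, WellTruth] = {}
    n_pairs = 0
    fwd = io.StringIO()
    rev = io.StringIO()
    truth_rows: list[str] = []
    truth_rows.append(
        "read_id\twell_id\tis_primer_dimer\tproduct_length\tpoly_errors\t"
        "noise_positions\tinsertions\tdeletions\n"
    )
    for i, well in enumerate(plate.wells):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))
        truth = simulate_well(
            template, preset, well.condition, plate.reads_per_well, rng,
            noise_floor=noise_floor, well_id=well.well_id,
        )
        well_truths[well.well_id] = truth
        vis = truth.visible_poly_errors()
        for j, prod in enumerate(truth.products):
            read_id = f"{well.well_id}:{j}"
            fseq = well.barcode + LEFT_PRIMER_BIND + prod + RIGHT_ADAPTER_PREFIX
            fwd.write(_fastq_record(read_id, fseq))
            rev.write(_fastq_record(read_id, revcomp(fseq)))
            li = truth.lengths[j]
            poly = ";".join(
                f"{p + 1}:{BASES[truth.product_codes[j, p]]}"
                for p in np.nonzero(vis[j])[0]
            )
            noise = ";".join(str(p + 1) for p in np.nonzero(truth.noise_errors[j, :li])[0])
            insr = ";".join(str(p + 1) for p in np.nonzero(truth.insertions[j, :li])[0])
            dels = ";".join(str(p + 1) for p in np.nonzero(truth.deletions[j, :li])[0])
            truth_rows.append(
                f"{read_id}\t{well.well_id}\t0\t{li}\t{poly}\t{noise}\t{insr}\t{dels}\n"
            )
            n_pairs += 1
        for j in range(n_dimers):
            read_id = f"{well.well_id}:dimer{j}"
            fseq = well.barcode + LEFT_PRIMER_BIND + RIGHT_ADAPTER_PREFIX
            fwd.write(_fastq_record(read_id, fseq))
            rev.write(_fastq_record(read_id, revcomp(fseq)))
            truth_rows.append(f"{read_id}\t{well.well_id}\t1\t0\t\t\t\t\n")
            n_pairs += 1

    fwd_path.write_text(fwd.getvalue())
    rev_path.write_text(rev.getvalue())
    truth_path.write_text("".join(truth_rows))
    return PlateSimResult(fwd_path, rev_path, plate_path, truth_path,
                          well_truths, n_pairs)


# ---------------------------------------------------------------------------
# Toy secondary-structure profiles
# ---------------------------------------------------------------------------


def toy_structure_profile(template: TemplateSpec | str, window: int = 5) -> np.ndarray:
    """Deterministic per-position pairedness score in [0, 1] from windowed
    self-complementarity.

    This is a synthetic stand-in for a thermodynamic ensemble pairing
    probability (it is emphatically *not* a NuPack computation): the score of
    position i is the best fraction of complementary base pairings achievable
    between the window centred on i and any non-overlapping, anti-parallel
    window elsewhere in the sequence.  It exists to give model fixtures a
    realistic structure covariate.

    For a :class:`TemplateSpec` the profile is computed over the extension
    region in extension order (length = extension-region length); for a raw
    string it covers the whole string.
    """
    if window < 3:
        raise ValueError("window must be >= 3")
    seq = template.bases_by_position if isinstance(template, TemplateSpec) else template
    codes = _codes(seq).astype(np.int16)
    L = len(codes)
    h = window // 2
    comp = 3 - codes
    scores = np.zeros(L)
    for i in range(L):
        best = 0.0
        for j in range(L):
            if abs(i - j) <= window:
                continue  # exclude self-overlap and hairpins tighter than the window
            hits = 0
            valid = 0
            for d in range(-h, h + 1):
                a, b = i + d, j - d
                if 0 <= a < L and 0 <= b < L:
                    valid += 1
                    if codes[a] == comp[b]:
                        hits += 1
            if valid:
                best = max(best, hits / valid)
        scores[i] = best
    return scores
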