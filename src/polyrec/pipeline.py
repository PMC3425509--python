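"""End-to-end orchestration: simulate -> filter -> quantify -> analyse.

The composite stages used by the command-line interface, the test-suite and
the acceptance script all live here, so that a titration experiment (a
duplicate-well plate varying one cation) can be simulated and analysed with
one call and a single seed, and the result interrogated for transfer-function
gains, per-base fold changes, transition matrices, correlation statistics and
information profiles.
"""

from __future__ import annotations

import hashlib
import json
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import infotheory, miscall, readproc, seqstats, transfer
from .miscall import (AlignmentParams, MisincorporationTally, RateEstimate,
                      RateTables, rates, replicate_stats, tally_inserts,
                      transition_matrix)
from .readproc import FilterConfig, FilterStats, filter_and_demux
from .synthetic_data import (DEFAULT_DIMER_FRACTION, DEFAULT_NOISE_FLOOR,
                             CationCondition, PlateDesign, TemplateSpec,
                             get_preset, get_template, make_titration_plate,
                             read_plate_tsv, simulate_plate)
from .transfer import TitrationSeries, TransferFit, fit_gain

__all__ = [
    "WellResult",
    "TitrationResult",
    "run_plate",
    "run_titration",
    "run_single_condition",
    "RunConfig",
    "run_all",
]


@dataclass
class WellResult:
    well_id: str
    condition: CationCondition
    replicate_group: str
    tally: MisincorporationTally
    tables: RateTables
    error_matrix: np.ndarray


@dataclass
class TitrationResult:
    """Per-well quantification of a simulated titration plate."""

    plate: PlateDesign
    template: TemplateSpec
    varied_cation: str
    wells: list[WellResult]
    filter_stats: FilterStats

    def _group_key(self, w: WellResult):
        return getattr(w.condition, f"{self.varied_cation}_uM")

    def conditions(self) -> list[CationCondition]:
        seen: dict[float, CationCondition] = {}
        for w in sorted(self.wells, key=self._group_key):
            seen.setdefault(self._group_key(w), w.condition)
        return list(seen.values())

    def mean_rate_series(self) -> TitrationSeries:
        """Replicate-averaged mean misincorporation rate per condition."""
        pts = []
        for cond in self.conditions():
            vals = [w.tables.mean_rate for w in self.wells if w.condition == cond]
            pts.append((cond, replicate_stats(vals)))
        return TitrationSeries(tuple(pts), self.varied_cation)

    def base_rate_series(self, base: str) -> TitrationSeries:
        """Replicate-averaged rate on one template base per condition."""
        i = "ACGT".index(base)
        pts = []
        for cond in self.conditions():
            vals = [float(w.tables.base["rate"].iloc[i])
                    for w in self.wells if w.condition == cond]
            pts.append((cond, replicate_stats(vals)))
        return TitrationSeries(tuple(pts), self.varied_cation)

    def pooled_tally(self, cond: CationCondition | None = None) -> MisincorporationTally:
        tallies = [w.tally for w in self.wells
                   if cond is None or w.condition == cond]
        out = tallies[0]
        for t in tallies[1:]:
            out = out.add(t)
        return out

    def pooled_position_rates(self, cond: CationCondition) -> np.ndarray:
        return rates(self.pooled_tally(cond)).position["rate"].to_numpy()

    def pooled_error_matrix(self, cond: CationCondition) -> np.ndarray:
        mats = [w.error_matrix for w in self.wells if w.condition == cond]
        return np.vstack(mats)

    def gain(self) -> TransferFit:
        return fit_gain(self.mean_rate_series())


def run_plate(
    plate: PlateDesign,
    template_name: str,
    seed: int,
    varied_cation: str,
    *,
    workdir: str | Path | None = None,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    dimer_fraction: float = DEFAULT_DIMER_FRACTION,
    align_params: AlignmentParams = AlignmentParams(),
) -> TitrationResult:
    """Simulate a plate, filter/demultiplex the reads, and quantify every
    well.  Uses a temporary directory unless ``workdir`` is given."""
    preset = get_preset(plate.preset_name)
    template = get_template(template_name)

    def _run(outdir: Path) -> TitrationResult:
        sim = simulate_plate(plate, preset, template, seed, outdir,
                             noise_floor=noise_floor,
                             dimer_fraction=dimer_fraction)
        cfg = FilterConfig(barcode_set=tuple(w.barcode for w in plate.wells))
        wells, stats = filter_and_demux(sim.fwd_fastq, sim.rev_fastq, cfg,
                                        plate.barcode_to_well())
        results = []
        for w in plate.wells:
            inserts = [ins for _, ins in wells.get(w.well_id, [])]
            tly, mat = tally_inserts(inserts, template, align_params,
                                     return_error_matrix=True)
            results.append(WellResult(w.well_id, w.condition,
                                      w.replicate_group, tly, rates(tly), mat))
        return TitrationResult(plate, template, varied_cation, results, stats)

    if workdir is None:
        with tempfile.TemporaryDirectory(prefix="polyrec_") as tmp:
            return _run(Path(tmp))
    return _run(Path(workdir))


def run_titration(
    preset_name: str,
    template_name: str,
    varied: str,
    grid_uM: Sequence[float],
    reads_per_well: int,
    seed: int,
    *,
    duplicates: int = 2,
    background: CationCondition | None = None,
    **kwargs,
) -> TitrationResult:
    """Convenience wrapper: build a duplicate-well titration plate for one
    preset and run it end to end."""
    plate = make_titration_plate(varied, grid_uM, preset_name, reads_per_well,
                                 duplicates=duplicates, background=background)
    return run_plate(plate, template_name, seed, varied, **kwargs)


def run_single_condition(
    preset_name: str,
    template_name: str,
    cond: CationCondition,
    n_reads: int,
    seed: int,
    **kwargs,
) -> WellResult:
    """Simulate and quantify a single well (used for the correlation and GLM
    analyses, which want one deep dataset at one condition)."""
    from .synthetic_data import Well, generate_barcodes

    barcode = generate_barcodes(1, seed=20120822).barcodes[0]
    plate = PlateDesign((Well("well1", barcode, cond, "g1"),), n_reads,
                        preset_name)
    res = run_plate(plate, template_name, seed, "mn", **kwargs)
    return res.wells[0]


# ---------------------------------------------------------------------------
# run-all with a config and a manifest
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of a full titration run.

    Either ``plate_tsv`` (a plate design file) or ``varied``+``grid_uM`` must
    be given.  Stage toggles turn the correlation/GLM statistics and the
    information profile on or off.
    """

    preset: str = "dpo4_paper"
    template: str = "original"
    seed: int = 0
    out_dir: str | Path = "polyrec_run"
    plate_tsv: str | Path | None = None
    varied: str = "mn"
    grid_uM: tuple[float, ...] = ()
    reads_per_well: int = 2000
    duplicates: int = 2
    noise_floor: float = DEFAULT_NOISE_FLOOR
    dimer_fraction: float = DEFAULT_DIMER_FRACTION
    do_stats: bool = True
    do_info: bool = True

    def validate(self) -> None:
        get_preset(self.preset)
        get_template(self.template)
        if self.plate_tsv is not None and not Path(self.plate_tsv).exists():
            raise FileNotFoundError(f"plate file not found: {self.plate_tsv}")
        if self.plate_tsv is None and not self.grid_uM:
            raise ValueError("need either plate_tsv or a concentration grid")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_all(config: RunConfig) -> dict:
    """Execute every stage, writing TSV artifacts and a manifest; returns a
    report dict with the headline numbers."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.plate_tsv is not None:
        plate = read_plate_tsv(config.plate_tsv)
    else:
        plate = make_titration_plate(config.varied, config.grid_uM,
                                     config.preset, config.reads_per_well,
                                     duplicates=config.duplicates)
    result = run_plate(plate, config.template, config.seed, config.varied,
                       workdir=out, noise_floor=config.noise_floor,
                       dimer_fraction=config.dimer_fraction)

    result.filter_stats.to_frame().to_csv(out / "filter_stats.tsv", sep="\t",
                                          index=False)
    rate_rows = []
    series = result.mean_rate_series()
    for cond, est in series.points:
        rate_rows.append({"condition": cond.label(), "template_base": "mean",
                          "rate": est.rate, "sem": est.sem,
                          "n_replicates": est.n_replicates})
    for base in "ACGT":
        for cond, est in result.base_rate_series(base).points:
            rate_rows.append({"condition": cond.label(), "template_base": base,
                              "rate": est.rate, "sem": est.sem,
                              "n_replicates": est.n_replicates})
    pd.DataFrame(rate_rows).to_csv(out / "rates.tsv", sep="\t", index=False)

    trans_frames = []
    for cond in result.conditions():
        tm = transition_matrix(result.pooled_tally(cond))
        tm.insert(0, "condition", cond.label())
        trans_frames.append(tm.reset_index(names="template_base"))
    pd.concat(trans_frames).to_csv(out / "transitions.tsv", sep="\t",
                                   index=False)

    fit = result.gain()
    pd.DataFrame([{
        "cation": config.varied,
        "gain_pct_per_mM": fit.gain_pct_per_mM,
        "gain_se": fit.gain_se,
        "fold_change": fit.fold_change,
    }]).to_csv(out / "transfer.tsv", sep="\t", index=False)
    report = {
        "gain_pct_per_mM": fit.gain_pct_per_mM,
        "gain_se": fit.gain_se,
        "fold_change": fit.fold_change,
    }

    conds = result.conditions()
    if config.do_stats:
        mat = result.pooled_error_matrix(conds[-1])
        lag = seqstats.lag_one_excess(mat, seed=config.seed)
        disp = seqstats.dispersion_test(mat)
        pd.DataFrame([{
            "condition": conds[-1].label(),
            "lag1_excess_pct": lag.excess_pct,
            "lag1_se_pct": lag.se_pct,
            "dispersion_index": disp.dispersion_index,
            "chi2_pvalue": disp.pvalue,
        }]).to_csv(out / "seqstats.tsv", sep="\t", index=False)
        report.update(lag1_excess_pct=lag.excess_pct,
                      dispersion_index=disp.dispersion_index,
                      chi2_pvalue=disp.pvalue)

    if config.do_info and len(conds) >= 2:
        hi = result.pooled_position_rates(conds[-1])
        lo = result.pooled_position_rates(conds[0])
        gains = infotheory.info_profile(hi, lo)
        pd.DataFrame({"position": np.arange(1, len(gains) + 1),
                      "gain_bits": gains}).to_csv(out / "info.tsv", sep="\t",
                                                  index=False)
        report["peak_info_gain_bits"] = float(np.nanmax(gains))

    manifest = {
        "seed": config.seed,
        "preset": config.preset,
        "template": config.template,
        "varied": config.varied,
        "reads_per_well": plate.reads_per_well,
        "files": {p.name: _sha256(p) for p in sorted(out.iterdir())
                  if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    report["manifest"] = manifest
    return report
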