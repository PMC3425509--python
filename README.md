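# polyrec

Cation-dependent DNA-polymerase fidelity landscapes from barcoded
deep-sequencing primer extensions — as a fully synthetic, seeded, testable
pipeline.

## The problem

An error-prone DNA polymerase copying a known template can act as a
nanoscale *recording device*: if an environmental signal (here, divalent
cation concentration) modulates the enzyme's misincorporation rate, the
density of wrong bases written into the copied strand encodes the signal,
and deep sequencing reads it back out.  Turning this idea into a usable
sensor requires the *transfer function* of each polymerase — the mapping
from cation concentration to misincorporation rate — resolved by template
base, base-to-base transition, position, and sequence context, plus the
statistical structure of the errors (are they independent? is the enzyme
ensemble homogeneous?) and the resulting information capacity in bits per
base.

`polyrec` implements the complete measurement pipeline for a multiplexed,
barcoded primer-extension assay with paired-end sequencing readout, together
with a calibrated synthetic-data generator, so every estimator can be tested
against analytic ground truth without touching real sequencing data.  Three
polymerase presets are bundled:

* **`dpo4_paper`** — a Y-family translesion polymerase emulation: a strongly
  superlinear Mn²⁺ response concentrated on template T (dGTP
  misincorporation, ≈50-fold between 75 and 800 µM Mn²⁺), a shallow Mg²⁺
  response, and Ca²⁺ fold-modulation in high-cation backgrounds;
* **`klenow_paper`** — a proofreading-deficient Klenow-fragment emulation:
  linear Mn²⁺ response (gain ≈0.6 %/mM), weak negative Mg²⁺ slope, dATP-
  dominated misincorporation except template T → dGTP, and lag-one error
  coupling;
* **`phusion_control`** — a high-fidelity control whose reads carry only the
  template-synthesis substitution noise floor.

## What the pipeline computes

1. **Simulation** (`synthetic_data`): 96-well-style plates of paired FASTQ
   reads — barcode + primer + extension product + adapter — with per-molecule
   Gamma rate heterogeneity, optional lag-one coupling, abortive
   terminations, rare indels, a synthesis noise floor and primer-dimer
   contaminants; bit-reproducible per seed, with ground-truth TSVs.
2. **Filtering/demultiplexing** (`readproc`): exact landmark and barcode
   matching (barcodes have pairwise Levenshtein distance ≥ 2), exact
   forward/reverse insert agreement, primer-dimer removal, and rejection
   statistics that partition the input.
3. **Misincorporation calling** (`miscall`): global alignment to the
   error-free product reference (match +1, mismatch 0, gap open −10, gap
   extend −2, end gaps scored; keep length ≥ 70 and score > 60), per-position
   n_p/N_p tallies, 4×4 template-base × incorporated-dNTP transition
   matrices, replicate statistics (SEM of duplicate wells) and noise floors.
4. **Transfer functions** (`transfer`): OLS gain in %/mM, fold changes with
   respect to the lowest concentration, Ca²⁺ endpoint responses, and the
   classical blue/white colony-assay error rate f = −ln(F)/(d·b).
5. **Error statistics** (`seqstats`): lag-one excess errors (observed
   adjacent-pair joint frequency minus the product of per-position rates,
   with bootstrap SE), a χ² Poisson-dispersion test of per-read error totals,
   and a binomial GLM of the error indicator on template base, position and
   local secondary structure, with cross-template prediction.
6. **Information** (`infotheory`): Shannon information gain per base about a
   binary cation state via the Bayesian posterior-entropy route (equal to
   the channel mutual information), per-position profiles, and recording
   capacity in bytes.

## Worked example

Simulate a duplicate-well Mn²⁺ titration of the Dpo4-like preset (6
concentrations × 2 wells × 2000 reads), run the full
filter → align → tally → fit chain, and read off the transfer function:

```python
import polyrec as pr
from polyrec.synthetic_data import DEFAULT_MN_GRID_UM

res = pr.run_titration("dpo4_paper", "original", "mn",
                       DEFAULT_MN_GRID_UM, 2000, seed=42)
fit = res.gain()
print(f"Mn gain: {fit.gain_pct_per_mM:.2f} +/- {fit.gain_se:.2f} %/mM")
for cond, est in res.mean_rate_series().points:
    print(f"  {cond.mn_uM:6.0f} uM Mn2+   mean rate {100*est.rate:6.3f}%")
```

prints

```
Mn gain: 2.30 +/- 0.25 %/mM
      10 uM Mn2+   mean rate  0.056%
      25 uM Mn2+   mean rate  0.075%
      75 uM Mn2+   mean rate  0.091%
     200 uM Mn2+   mean rate  0.237%
     400 uM Mn2+   mean rate  0.610%
     800 uM Mn2+   mean rate  1.898%
```

i.e. the pipeline recovers the ≈2 %/mM Mn²⁺ gain the preset was calibrated
to, a mean-rate fold change of ≈34 across the grid, and a template-T fold
change of several hundred (the T response dominates the mean).  The same
object exposes per-base titrations (`res.base_rate_series("T")`), pooled
transition matrices, per-position rate profiles and indel-free error
matrices for the statistical layer.

The equivalent shell workflow:

```bash
polyrec simulate --preset dpo4_paper --reads-per-well 2000 --seed 42 --out sim/
polyrec filter   --plate sim/plate.tsv --fwd sim/reads_R1.fastq --rev sim/reads_R2.fastq --out demux/
polyrec quantify --wells demux/ --out quant/
polyrec transfer --quant quant/ --plate sim/plate.tsv --out transfer.tsv
polyrec stats    --matrix quant/mn800_r1_matrix.tsv --out stats/
# or everything at once:
polyrec run-all  --preset dpo4_paper --varied mn --seed 42 --out run/
```

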