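# Methods

This note documents the generative model behind the synthetic assay, the
calibration of the bundled polymerase presets, the estimators, and the
numerical and design choices that were genuinely open.  Nothing here states
an empirical result that the test-suite or `scripts/acceptance.py` does not
itself compute.

## The assay being emulated

A barcoded primer (Illumina left adapter + 5-base well barcode + a 19-base
template-annealing tail) is annealed to a 95-nt single-stranded DNA template
whose 3'-terminal base is a dideoxy-C, so the template strand itself can
never be extended or amplified.  An error-prone polymerase extends the
primer across a 76-base extension region at a defined divalent-cation
condition; a partial right adapter is ligated downstream; high-fidelity PCR
completes the adapters; and 150-bp paired-end reads are taken.  Because the
112-bp amplicon is shorter than either read, the mates fully overlap, and a
forward read has the layout

```
[5-base barcode][GATGGTCATAGCTGTTGTA][extension product, <=76 nt][AGATCGGAAGAG...]
```

with the reverse read its exact reverse complement.  Two templates are
bundled ("original" and "swapped" — the same two 36/40-nt halves in swapped
order, identical base composition), both ending in the same
primer-annealing tail.

**Coordinate convention (used everywhere).** Extension positions are 1-based
in the order the polymerase adds bases: position 1 is the template base
adjacent to the primer, position 76 the template 5' end.  The alignment
reference `product_ref` is the reverse complement of the extension region,
so reference index i (0-based) is extension position i+1.  The template base
reported at a position is the template-strand base, i.e. the complement of
the reference base; the incorporated dNTP is the read base.

## Generative model

Per molecule:

1. **Synthesis noise floor.** Each template base is independently replaced
   by a uniformly random different base with probability `noise_floor`
   (default 1e-4), emulating substitution impurities in chemically
   synthesised oligonucleotides.  A correct copy of an impure template is a
   mismatch against the reference, so this sets the apparent error floor of
   a high-fidelity control.  PAGE-purified oligo pools motivate the 1e-4
   default; the value is a parameter of `simulate_plate`/`simulate_well`.
2. **Heterogeneity.** A molecule-wide multiplier m ~ Gamma(k, mean 1)
   scales all rates (k = `heterogeneity_shape`; k → ∞ recovers a
   homogeneous, Poisson ensemble; both error-prone presets use k = 2, which
   produces dispersion indices of per-read error totals well above 1 at
   the bundled rates).
3. **Misincorporation.** Walking positions 1..76, the error probability at
   position p is `clip(m * r_b(cond) + eps * [error at p-1], 0, 1)`, where
   r_b is the cation-dependent rate for template base b and eps
   (`lag1_boost`) an optional additive lag-one coupling.  A wrong
   incorporation draws from the preset's cation-independent transition row
   over the three non-Watson-Crick dNTPs — so cation concentration scales
   the rate but never changes the wrong-dNTP mix, which downstream
   estimators can verify.
4. **Abortive termination** with per-position probability 3e-3 (product
   length = first stop), and **indels** (insertion and deletion each at
   2e-4 per position).  Products abortive at the very first base have an
   empty insert and are indistinguishable from primer dimers downstream.
5. **Primer dimers.** Each well gains `round(dimer_fraction *
   reads_per_well)` contaminant pairs (default 2%) whose insert is empty.

Rates follow

```
r_b(cond) = clip((r0_b + mn_amp_b * mn_mM^mn_gamma_b
                       + mg_amp_b * mg_mM^mg_gamma_b) * ca_fold, 0, r_max)
```

with `ca_fold` a piecewise log-linear multiplier in Ca²⁺ concentration,
selected by the background cation (a Mn²⁺ background takes precedence over
Mg²⁺), flat at 1 outside its knots.  Qualities are constant placeholders
("I"): the pipeline never uses quality scores.  RNG: well i of a plate uses
the stream `SeedSequence(seed, spawn_key=(i,))`, so plates are reproducible
well-by-well and byte-identical per seed.

## Preset calibration

Presets are constraint-calibrated: coefficients were fixed, before the test
expectations were frozen, to reproduce a set of headline behaviours, and
live in `src/polyrec/data/presets.yaml`.

**dpo4_paper.**  Template T: r_T = a·c^γ (c = Mn²⁺ in mM) with
γ = ln(50)/ln(800/75) ≈ 1.653 and a ≈ 0.1012, pinned by r_T(75 µM) = 0.0014
and r_T(800 µM) = 0.070 — a 50-fold span.  Other bases are weakly
responsive (a = 9e-4, γ = 0.1).  The resulting OLS gain of the base-averaged
mean rate over the default Mn grid {10, 25, 75, 200, 400, 800} µM is
≈2.2 %/mM.  The Mg²⁺ response is a shallow saturating power law
(2.923e-3·c^0.1 per base) whose OLS gain over {1, 2, 4, 7} mM is exactly
0.01 %/mM at absolute rates ≈0.3%; a linear response with the same gain
would put the rates below any realistic noise floor and make the
Ca²⁺-response measurements in a Mg²⁺ background meaningless (see
Limitations).  Ca²⁺ fold multipliers: 1 → 2.9 between 100 nM and 1 mM Ca²⁺
in a Mn²⁺ background, and 1 → 0.58 between 100 µM and 1 mM in a Mg²⁺
background.  No lag-one coupling.

**klenow_paper.**  Linear Mn²⁺ response with amplitudes (A: 0.0112, C/G/T:
0.00373 per mM; baseline 9.3e-4) giving a marginal base-averaged gain of
0.6 %/mM — the amplitudes are deflated by ≈1/(1+eps) because lag-one
coupling inflates marginal rates.  Mg²⁺ slope −0.01 %/mM (rates stay
positive across the grid).  Transition rows are dATP-dominated except
template T, where dGTP carries 0.84 of the wrong-dNTP mass; after dilution
by the (uniform) noise-floor transitions the *estimated* dGTP preference
remains ≥4-fold.  `lag1_boost` = 0.0672 was calibrated numerically (three
seeds × 120k reads) so the measured lag-one excess at 800 µM Mn²⁺ is
0.047% per base; the naive guess eps = 0.047%/0.5% ≈ 0.094 overshoots
because the excess estimator averages the per-position marginal rate over
adjacent pairs (≈0.66% on this A-rich template, not the 0.5% base-averaged
mean) and because shared Gamma multipliers add a (1/k)·r_p·r_{p+1} term.

**phusion_control.**  All polymerase rates zero; reads show only the noise
floor, truncations and indels.

Default titration grids: Mn {10, 25, 75, 200, 400, 800} µM, Mg {1, 2, 4, 7}
mM (published endpoints 75/800 µM and 1/7 mM; interior points chosen for a
stable least-squares slope).  Default duplicates: 2 wells per condition
with distinct barcodes.

## Estimators and numerical choices

* **Barcodes** are built greedily over the 4^k space in seeded random order,
  keeping candidates at Levenshtein distance ≥ 2 (edlib) from all kept
  barcodes; infeasible requests raise.  Demultiplexing is *exact* barcode
  match — with pairwise distance ≥ 2 a 1-error-correcting decoder would be
  possible but is deliberately off.
* **Filtering** uses exact substring landmarks at their expected offsets
  (slack 0): forward reads need the primer-binding sequence, the 12-base
  right-adapter prefix and a set barcode; reverse reads the primer-binding
  sequence and barcode; mates must agree exactly on the insert.  Rejection
  reasons partition the input; reads shorter than barcode+landmark count as
  `no_left_primer`.
* **Alignment** is global with match +1, mismatch 0, affine gaps (open −10
  for the first gap position, −2 for each extension) and end gaps scored —
  truncated products are penalised and fail the score filter rather than
  being trimmed.  Acceptance: insert length ≥ 70 *and* score > 60 (strict);
  with this scheme inserts shorter than 74 cannot pass.  The dynamic program
  is Biopython's `PairwiseAligner`; a provably-optimal gapless shortcut
  handles full-length inserts with < 20 mismatches (any gapped global
  alignment of equal-length sequences scores ≤ L−21).  Ties are broken
  deterministically by taking the aligner's first optimal traceback; the
  test-suite checks score agreement with an independent exhaustive DP
  oracle.  Columns containing a gap or an ambiguous (N) read base count
  toward neither n_p nor N_p.
* **Rates** are n_p/N_p; the mean misincorporation rate is the unweighted
  average of the four per-template-base rates; zero denominators yield NaN
  and are excluded from means.  Replicate statistics: mean and sd/√n over
  duplicate wells (n = 1 flagged with NaN SEM).  Noise floors: mean + SEM of
  the control's base-averaged rate, and max over positions of
  (replicate-mean rate + SEM).
* **Transfer fits** are unweighted OLS of rate (%) on concentration (mM)
  (`scipy.stats.linregress`); whether to weight by SEM was open and
  unweighted was chosen for simplicity and robustness at 2 replicates.
  Fold change = rate(highest)/rate(lowest).  Ca²⁺ responses compare the
  first and last grid points; a zero reference rate is flagged NaN.
* **Error matrix**: accepted, indel-free, full-length reads over the first
  70 extension positions (shorter products are not re-mapped; the first 70
  reference positions are the declared window).
* **Lag-one excess**: mean over the 69 adjacent pairs of (joint error
  frequency − product of the two per-position rates), reported in %.  The
  position-specific product is the only reading of the squared-rate
  correction that actually removes template-induced structure, and is what
  is implemented.  The ±SE is a seeded bootstrap over reads (1000 resamples
  by default) using multinomial weights.
* **Dispersion**: χ² goodness of fit of per-read totals to Poisson(sample
  mean), adjacent bins pooled until every expected count is ≥ 5,
  dof = bins − 2; degenerate inputs (no errors, too few bins) are flagged
  with NaN p-values rather than tested.  Under a seeded homogeneous null
  (500 replicates) the measured type-I error at α = 0.05 is 0.05 ± 0.02.
* **GLM**: binomial family, logit link, IRLS to tolerance 1e-8
  (statsmodels).  Features per modelled base: bias; C/G/T indicators (A
  absorbed in the bias); position scaled by 1/70; structure scores at
  offsets −3..+3.  Modelled positions are 4..67, so the structure window is
  always complete.  Outcomes are per-read Bernoulli indicators; since the
  regressors are constant within a position the likelihood is aggregated to
  per-position binomial counts, which is exactly equivalent (identical
  estimates and standard errors) and far faster.  R² is the squared Pearson
  correlation between fitted and observed per-position rates; cross-template
  prediction applies one template's weights to the other's design.
  Non-convergence or separation raises a typed `GlmError`.
* **Structure profiles** are inputs (TSV: position, s).  The bundled
  fallback, `toy_structure_profile`, is a synthetic windowed
  self-complementarity score — *not* a thermodynamic ensemble computation —
  sufficient to exercise the GLM's structure features.
* **Information gain** follows the Bayesian route (posterior entropies after
  observing a correct/incorrect base, 0·log0 ≡ 0), which equals the channel
  mutual information; the test-suite checks agreement with a brute-force
  2×2 mutual-information oracle to 1e-12 bits.  Capacity uses decimal
  megabytes (bits × length / 8).
* **Colony assay**: f = −ln(F)/(d·b) with b = 349 bp (the detectable
  single-substitution target of the 1080-bp lacI gene); uncertainty by the
  delta method from Poisson counting of blue/white colonies.

## Problem sizes

The test-suite and the acceptance script run titrations at 6 (Mn) or 4 (Mg)
concentrations × 2 duplicate wells × 2000–5000 reads, and single deep wells
of 20000 reads for the correlation statistics — enough for the slope SEs and
bootstrap SEs to sit at a few percent of the calibrated values.  The whole
suite runs in well under a minute on one CPU; `scripts/acceptance.py` in
about ten seconds.

## Limitations

* The generator omits PCR amplification bias, quality-score error profiles,
  cluster-calling artifacts and context-dependent (nearest-neighbour)
  misincorporation; passing tests demonstrate estimator correctness on the
  stated generative model, not fidelity to any real polymerase.
* Structure covariates are synthetic; no claim of agreement with a
  thermodynamic secondary-structure model is made, and the GLM's structure
  weights on synthetic data are expected to be null.
* The noise floor, indel, truncation and dimer defaults are plausible-order
  choices, all configurable.  Note that because the floor does not scale
  with the Ca²⁺ modifier, floor-dominated regimes would systematically
  compress measured Ca²⁺ fold responses; the default floor (1e-4) keeps the
  bundled presets' rates at least an order of magnitude above it in every
  bundled condition.
* Molecular counting (UMI-style consensus) for high-fidelity polymerases is
  out of scope; the pipeline targets error-prone enzymes whose rates sit
  far above the floor.
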