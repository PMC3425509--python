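# Versioned polymerase presets for the synthetic primer-extension assay.
#
# Rate model per template base b (concentrations in mM):
#   r_b = clip((r0 + mn_amp * mn^mn_gamma + mg_amp * mg^mg_gamma) * ca_fold, 0, r_max)
# where ca_fold is a piecewise log-linear multiplier selected by the
# background cation (Mn2+ takes precedence over Mg2+).
#
# The presets are constraint-calibrated (see docs/methods.md):
#  * dpo4_paper  -- template-T Mn2+ response is superlinear with
#       r_T(75 uM) = 0.0014 and r_T(800 uM) = 0.070 (a 50-fold span), which
#       fixes mn_gamma = ln(50)/ln(800/75) and the amplitude; other bases are
#       weakly responsive; the Mg2+ response is shallow and saturating with a
#       base-averaged OLS gain of 0.01 %/mM over the 1-7 mM grid; Ca2+ fold
#       multipliers ramp 1 -> 2.9 (Mn background) and 1 -> 0.58 (Mg
#       background).
#  * klenow_paper -- linear Mn2+ response with base-averaged marginal gain
#       0.6 %/mM (dATP-dominated transitions except template T -> dGTP), a
#       weak negative Mg2+ slope of -0.01 %/mM, and lag-one coupling
#       calibrated so the measured excess is 0.047% per base at 800 uM Mn2+.
#  * phusion_control -- all polymerase rates zero; reads show only the
#       template-synthesis noise floor.
#
# transition_rows give the distribution of the *wrong* incoming dNTP
# conditional on the template base (keys are the incorporated bases; the
# Watson-Crick complement is excluded).  Rows are cation independent: cation
# concentration only scales the total misincorporation probability.

presets:
  dpo4_paper:
    description: >-
      Y-family translesion polymerase emulation: strong superlinear Mn2+
      response concentrated on template T (dGTP misincorporation), shallow
      saturating Mg2+ response, Ca2+ modulation only at high background.
    r_max: 0.5
    heterogeneity_shape: 2.0
    lag1_boost: 0.0
    truncation_prob: 0.003
    indel_prob: 0.0002
    rate_params:
      A: {r0: 0.0, mn_amp: 0.0009, mn_gamma: 0.1, mg_amp: 0.0029230, mg_gamma: 0.1}
      C: {r0: 0.0, mn_amp: 0.0009, mn_gamma: 0.1, mg_amp: 0.0029230, mg_gamma: 0.1}
      G: {r0: 0.0, mn_amp: 0.0009, mn_gamma: 0.1, mg_amp: 0.0029230, mg_gamma: 0.1}
      T: {r0: 0.0, mn_amp: 0.1012220, mn_gamma: 1.6526, mg_amp: 0.0029230, mg_gamma: 0.1}
    transition_rows:
      A: {A: 0.30, C: 0.25, G: 0.45}
      C: {A: 0.50, C: 0.20, T: 0.30}
      G: {A: 0.45, G: 0.20, T: 0.35}
      T: {C: 0.15, G: 0.75, T: 0.10}
    ca_modifiers:
      mn_background: [[0.1, 1.0], [1000.0, 2.9]]
      mg_background: [[100.0, 1.0], [1000.0, 0.58]]

  klenow_paper:
    description: >-
      Proofreading-deficient Klenow fragment emulation: moderate linear Mn2+
      response (dATP-dominated misincorporation, template T prefers dGTP),
      weak negative Mg2+ slope, lag-one error coupling, no Ca2+ response.
    r_max: 0.5
    heterogeneity_shape: 2.0
    lag1_boost: 0.0672
    truncation_prob: 0.003
    indel_prob: 0.0002
    rate_params:
      A: {r0: 0.000933, mn_amp: 0.011199, mn_gamma: 1.0, mg_amp: -0.0000933, mg_gamma: 1.0}
      C: {r0: 0.000933, mn_amp: 0.003733, mn_gamma: 1.0, mg_amp: -0.0000933, mg_gamma: 1.0}
      G: {r0: 0.000933, mn_amp: 0.003733, mn_gamma: 1.0, mg_amp: -0.0000933, mg_gamma: 1.0}
      T: {r0: 0.000933, mn_amp: 0.003733, mn_gamma: 1.0, mg_amp: -0.0000933, mg_gamma: 1.0}
    transition_rows:
      A: {A: 0.60, C: 0.20, G: 0.20}
      C: {A: 0.60, C: 0.20, T: 0.20}
      G: {A: 0.60, G: 0.20, T: 0.20}
      T: {C: 0.10, G: 0.84, T: 0.06}
    ca_modifiers: {}

  phusion_control:
    description: >-
      High-fidelity control: no polymerase misincorporation at all, so any
      apparent errors come from the synthetic-template noise floor.
    r_max: 0.5
    heterogeneity_shape: null
    lag1_boost: 0.0
    truncation_prob: 0.003
    indel_prob: 0.0002
    rate_params:
      A: {r0: 0.0}
      C: {r0: 0.0}
      G: {r0: 0.0}
      T: {r0: 0.0}
    transition_rows:
      A: {A: 0.3334, C: 0.3333, G: 0.3333}
      C: {A: 0.3334, C: 0.3333, T: 0.3333}
      G: {A: 0.3334, G: 0.3333, T: 0.3333}
      T: {C: 0.3334, G: 0.3333, T: 0.3333}
    ca_modifiers: {}
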