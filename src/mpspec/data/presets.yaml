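# Named particle and contaminant presets.
#
# Template presets pin the harmonic fingerprint directly (relative odd-harmonic
# amplitudes with A3 = 1 and per-harmonic phases in degrees, negative = lag).
# The template coordinates reproduce the published fingerprint clusters of the
# three tracer families: very small single-core particles (steep spectrum,
# near-zero lag), a dextran multi-particle agglomerate (intermediate), and
# large multicore systems (flat spectrum, large lag).
#
# Physical presets parameterize the Langevin/Debye forward model:
# lognormal core diameter law (median d_med, shape sigma_d), core saturation
# magnetization M_s and an effective Debye relaxation time tau.

vsop:
  mode: template
  template_amps: {3: 1.0, 5: 0.10, 7: 0.02, 9: 0.005}
  template_phases: {3: -2.0, 5: -2.0, 7: -2.0, 9: -2.0}

endorem:
  mode: template
  template_amps: {3: 1.0, 5: 0.20, 7: 0.055, 9: 0.018}
  template_phases: {3: -10.0, 5: -12.0, 7: -14.0, 9: -16.0}

mcp_resovist:
  mode: template
  template_amps: {3: 1.0, 5: 0.30, 7: 0.12, 9: 0.05}
  template_phases: {3: -30.0, 5: -33.0, 7: -36.0, 9: -39.0}

vsop_physical:
  mode: physical
  d_med: 5.0e-9      # m
  sigma_d: 0.25
  M_s: 3.0e5         # A/m
  tau: 1.0e-7        # s

endorem_physical:
  mode: physical
  d_med: 9.0e-9
  sigma_d: 0.30
  M_s: 3.2e5
  tau: 8.0e-7

multicore_physical:
  mode: physical
  d_med: 16.0e-9
  sigma_d: 0.30
  M_s: 3.5e5
  tau: 2.0e-6

contaminant_diet:
  mode: contaminant
  m_c: 1.0e-9        # A m^2, saturation moment (central value)
  B_c: 12.5e-3       # T, coercivity
  B_w: 3.0e-3        # T, switching smoothness
  jitter:
    m_c_decades: 0.5   # m_c drawn log-uniform over +/- half a decade
    B_c: 7.5e-3        # uniform half-width in T  -> B_c in [5, 20] mT
    B_w: 2.0e-3        # uniform half-width in T  -> B_w in [1, 5] mT
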