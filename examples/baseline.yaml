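# Reference operating point: 160 um chamber, one 100 um comb finger facing
# a planar counter-electrode, 1 mS/m KCl, 1 um latex tracer, 6 Vpp at 1 kHz.
chamber:
  height_um: 160
  electrode_width_um: 100
  gap_um: 200
medium:
  conductivity_mS_per_m: 1.0
  rel_permittivity: 78.5
  viscosity_mPa_s: 0.89
  temperature_K: 298.15
particle:
  radius_um: 0.5
  rel_permittivity: 2.55
  surface_conductance_nS: 1.0
drive:
  v_pp: 6.0
  frequency_Hz: 1000.0
dl:
  lambda: 0.25        # Stern / (Stern + diffuse) capacitance ratio
  lambda_exp: 0.02    # empirical slip correction factor
solver:
  duration_s: 60
  release_pitch_um: 15
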