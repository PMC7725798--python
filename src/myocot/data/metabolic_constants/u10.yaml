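# Muscle energetics model of Umberger (2010),
# "Stance and swing phase costs in human walking",
# J R Soc Interface 7(50):1329-1340.
# Revision of the 2003 model: the mechanical work rate term includes only
# positive (concentric) work, so eccentric contractions contribute through
# their (positive) lengthening heat alone.
model_id: U10
specific_tension_pa: 0.25e+6
muscle_density_kg_m3: 1059.7
include_negative_work: false      # eccentric work rate EXCLUDED: wdot = max(0, -F*v)/m
lengthening_heat_sign: positive
basal_rate_w_per_kg_body: 1.2
coefficients:
  act_maint_heat_fast_slope: 128.0
  act_maint_heat_intercept: 25.0
  act_maint_exponent: 0.6
  shortening_exponent: 2.0
  lengthening_exponent: 1.0
  shortening_coeff_slow_numerator: 100.0
  shortening_coeff_fast_numerator: 153.0
  vmax_slow_fraction: 0.4
  lengthening_coeff_factor: 4.0
  aerobic_scale: 1.5
  length_dep_offset: 0.4
  length_dep_slope: 0.6
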