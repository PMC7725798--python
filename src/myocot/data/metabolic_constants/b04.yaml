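# Muscle energetics model of Bhargava, Pandy & Anderson (2004),
# "A phenomenological model for estimating metabolic energy consumption
# in muscle contraction", J Biomech 37(1):81-88.
# Each coefficient is annotated with the construct it parameterizes in that
# publication.  Values are W/kg of muscle mass unless noted.
model_id: B04
specific_tension_pa: 0.25e+6      # sigma, max muscle stress (Pa); muscle mass = rho*(Fmax/sigma)*lopt
muscle_density_kg_m3: 1059.7      # rho, mammalian muscle density
include_negative_work: true       # eccentric (negative) work rate included in Wdot
lengthening_heat_sign: negative   # heat rate during lengthening is negative
basal_rate_w_per_kg_body: 1.2     # whole-body basal rate (toggleable; not part of B04 itself)
coefficients:
  activation_heat_slow: 40.0      # A_ST: slow-twitch activation heat rate coefficient
  activation_heat_fast: 133.0     # A_FT: fast-twitch activation heat rate coefficient
  maintenance_heat_slow: 74.0     # M_ST: slow-twitch maintenance heat rate coefficient
  maintenance_heat_fast: 111.0    # M_FT: fast-twitch maintenance heat rate coefficient
  decay_function: 1.0             # stimulation-decay factor phi (constant-1 variant)
  shortening_coeff_iso: 0.16      # alpha_S = 0.16*F_CE_iso + 0.18*F_CE during shortening
  shortening_coeff_force: 0.18
  lengthening_coeff: 0.157        # alpha_L = 0.157*F_CE during lengthening
# Fiber-length dependence of maintenance heat (piecewise linear in
# normalized fiber length): 0.5 below 0.5, identity to 1.0, falling 3-2*l
# to zero at 1.5, zero beyond.
fiber_length_dependence:
  breakpoints: [0.5, 1.0, 1.5]
  values_low: 0.5
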