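# Muscle energetics model of Umberger, Gerritsen & Martin (2003),
# "A model of human muscle energy expenditure",
# Comput Methods Biomech Biomed Engin 6(2):99-111.
# Heat and work rates are mass-specific (W/kg of muscle mass).
model_id: U03
specific_tension_pa: 0.25e+6
muscle_density_kg_m3: 1059.7
include_negative_work: true       # eccentric work rate included (subtracts from total)
lengthening_heat_sign: positive   # heat rate during lengthening is positive
basal_rate_w_per_kg_body: 1.2
coefficients:
  act_maint_heat_fast_slope: 128.0  # hdot_AM = 128*f_FT + 25 (W/kg), f_FT fast-twitch fraction
  act_maint_heat_intercept: 25.0
  act_maint_exponent: 0.6           # heat scales with A(t)^0.6
  shortening_exponent: 2.0          # shortening heat scales with A(t)^2.0
  lengthening_exponent: 1.0         # lengthening heat scales with A(t)^1.0
  shortening_coeff_slow_numerator: 100.0  # alpha_S(ST) = 100 / vmax_ST (4 x 25)
  shortening_coeff_fast_numerator: 153.0  # alpha_S(FT) = 153 / vmax_FT
  vmax_slow_fraction: 0.4           # vmax_ST = vmax_FT / 2.5
  lengthening_coeff_factor: 4.0     # alpha_L = 4 * alpha_S(ST)
  aerobic_scale: 1.5                # S, scaling for primarily aerobic activity
  length_dep_offset: 0.4            # above lopt: heat scaled by 0.4 + 0.6*F_iso(l)
  length_dep_slope: 0.6
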