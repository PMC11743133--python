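# Default effect structure for the synthetic-data generators.
# Trait baselines are flat across assay temperature so that regime
# multipliers express effects relative to the ancestor at any temperature;
# the headline structure (hot-regime footprint x1.8 at 35 degC, cold x1.076
# at 23 degC, C_m in the 3-4 range) is encoded here, not in code.
traits:
  baseline:
    omega: 60.0      # lifetime adult offspring per female
    mass_M: 6.0      # adult female mass at emergence, mg
    d1: 21.0         # mean egg-to-adult development time, days
    psi: 50.0        # eggs laid in first 16 h
    d2: 19.0         # development time of fastest individual, days
  regime_multipliers:
    hot:
      35: {omega: 1.45, mass_M: 1.18, d1: 0.95, psi: 1.50, d2: 0.95}   # phi1 ratio 1.80
      29: {omega: 1.20, mass_M: 1.10, d1: 0.98, psi: 1.22, d2: 0.98}
      23: {omega: 1.00, mass_M: 1.05, d1: 1.00, psi: 1.02, d2: 1.00}
    cold:
      23: {omega: 1.05, mass_M: 1.02, d1: 0.995, psi: 1.06, d2: 0.99}  # phi1 ratio 1.076
      29: {omega: 1.02, mass_M: 1.01, d1: 1.00, psi: 1.02, d2: 1.00}
      35: {omega: 0.95, mass_M: 1.00, d1: 1.00, psi: 0.95, d2: 1.00}
  origin_offsets: {Brazil: 1.0, California: 1.05, Yemen: 0.95}
  line_cv: 0.02      # lognormal line-level jitter (CV)
  se_cv: 0.05        # per-trait SE as a fraction of the mean
consumption:
  C_m: {23: 3.17, 29: 3.66, 35: 3.55}   # mg host per mg beetle, per temp
  mu_eggs: 60.0
  dish_cv: 0.6       # lognormal dish-to-dish fecundity variation
  survival_p: 0.5
  mass_mean: 6.0
  mass_cv: 0.06
  noise_cv: 0.05     # residual sd as a fraction of mean consumption
  drift: 8.0         # beetle-independent bean weight drift, mg
  drift_sd: 2.0
  dishes_per_assay: 3
  controls_per_temp: 5
expression:
  n_up_mating_down_heat: 21
  n_down_mating_up_heat: 113
  n_concordant_down: 3
  lfc_scale: 1.0
  mirror_jitter: 0.02
  base_mean: 200.0
  base_sigma: 1.0
  nb_dispersion: 10.0
  hot_shift: 1.0
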