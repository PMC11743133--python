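# Default run configuration. Temperatures in files and CLI are degrees
# Celsius; the model works in Kelvin internally.
version: 1
model:
  # Productivity kinetics (relative units; proportionality constants are
  # absorbed into a_B).
  a_B: 1.0
  Ea_B: 65000.0        # J/mol, ~0.67 eV
  # Failure/stability kinetics: two-state unfolding stand-in with scale
  # kappa_D divided by the maintenance allocation q*M.
  kappa_D: 100.0
  dH_m: 500000.0       # J/mol
  T_m: 315.0           # K (~41.9 degC unfolding midpoint)
  dCp: 0.0             # J/(mol K); 0 = no curvature in dG_u
  c: 0.1               # per-unit cost of juvenile acquisition
  b: 0.75              # allometric exponent
optimizer:
  M_bounds: [0.5, 40.0]
  grid_n: 41
  refine: true
  refine_tol: 1.0e-8
  n_restarts: 2
  seed: 0
bootstrap:
  n_boot: 2000
  seed: 0
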