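# thermofoot

Thermodynamic life-history optimization and agricultural-footprint
estimation for ectotherm pests.

The package has two halves:

1. **A thermodynamic life-history model.** Population growth rate r'(T) is
   the product of juvenile survival `(1-c)^M`, productivity
   `[M(1-p-q)]^b`, an Arrhenius reaction-rate factor with prefactor
   `a_B·p·M`, and a protein-stability factor
   `1/(1 + (kappa_D/(q·M))·K_u(T))` built on two-state unfolding
   thermodynamics (`dH_m`, `T_m`, optional `dCp`). A constrained grid +
   Nelder-Mead optimizer finds the strategy `(M, p, q)` maximizing r' at a
   given temperature; helpers build adapted thermal-performance curves,
   niche breadths, and the displacement between the growth-rate peak and
   the impact (`M·r'`) peak. All outputs are in relative units; the
   stability parameterization is a configurable stand-in for
   temperature-dependent failure kinetics.

2. **A footprint estimation pipeline.** Host-consumption assays yield
   per-temperature conversion constants `C_m` (through-origin regression
   slope of host mass lost on beetle mass produced), a per-egg constant
   `C_E` (pooled ratio), and a nested-OLS variance decomposition. Two
   footprint metrics — `phi1 = C_m·omega·mass/d1` and `phi2 = psi·C_E/d2`
   — are computed per line with parametric-bootstrap CIs, scaled relative
   to each line's own ancestor, and converted to per-generation rates.
   A gene-expression module scores samples along a
   reproduction-maintenance trade-off axis (overlap statistics,
   antagonistic-direction classification, lfc-weighted scores,
   first-eigenvector projection).

A synthetic-data module generates every input the pipeline consumes
(3 origins x 2 regimes x 2 replicate lines + 3 ancestors, assayed at
23/29/35 °C), with effect sizes configured in
`src/thermofoot/data/default_effects.yaml`.

## CLI

Temperatures on all interfaces are degrees Celsius.

```sh
thermofoot simulate --seed 5 --out-dir out/sim
thermofoot curves --temps 15:45:1 --strategy 17,0.55,0.03 --out out/curves.tsv
thermofoot optimize --temp 35 --out out/opt.json
thermofoot consumption --assays out/sim/consumption.tsv \
    --controls out/sim/controls.tsv --out out/cons.json
thermofoot footprint --traits out/sim/line_traits.tsv \
    --cm cm.tsv --boot 2000 --seed 1 --out out/footprint.json
thermofoot overlap --panel out/sim/gene_panel.tsv \
    --counts out/sim/counts.tsv --out out/overlap.json
thermofoot run --out-dir out/full      # full synthetic pipeline
```

Model and optimizer defaults live in
`src/thermofoot/data/default_config.yaml`; pass `--config` to override.
Unknown config keys are rejected.

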