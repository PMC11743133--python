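"""Synthetic data generators for the full analysis pipeline.

Emulates the experimental design — three geographic origins, two evolution
regimes (cold/hot) with two replicate lines each, plus one ancestor per
origin — assayed at 23/29/35 degC. Three generators produce the inputs the
downstream modules consume:

* :func:`generate_line_traits` — per-line trait means and SEs with a
  configurable regime x temperature multiplicative effect structure;
* :func:`generate_consumption` — dish-level assays with Poisson fecundity,
  Binomial survival, Normal masses and a linear mass-conversion structure
  plus noise, together with beetle-free control dishes;
* :func:`generate_expression` — an antagonistic/concordant gene panel and
  negative-binomial sample counts with a maintenance-pole mean shift for
  hot-assay samples.

:func:`generate_model_truth` bridges the thermodynamic model to the
footprint pipeline by mapping optimizer output to trait scales.

All generators are deterministic per seed and attach their full
parameterization as metadata (``DataFrame.attrs``). Default effect sizes
live in the shipped ``data/default_effects.yaml``, not in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .errors import InvalidInputError
from .optimize import OptimizerConfig, optimize_strategy
from .thermo import KineticParams, celsius_to_kelvin, growth_rate

TRAITS = ("omega", "mass_M", "d1", "psi", "d2")
REGIMES = ("ancestor", "cold", "hot")


@dataclass(frozen=True)
class DesignSpec:
    """The line design: origins x regimes x replicates at fixed assay temps."""

    origins: tuple[str, ...] = ("Brazil", "California", "Yemen")
    replicates_per_regime: int = 2
    regimes: tuple[str, ...] = REGIMES
    assay_temps: tuple[float, ...] = (23.0, 29.0, 35.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates_per_regime < 1:
            raise InvalidInputError("replicates_per_regime must be >= 1")
        if not set(self.regimes) <= set(REGIMES):
            raise InvalidInputError(f"regimes must be a subset of {REGIMES}")

    def lines(self) -> list[dict]:
        """All lines: replicate evolved lines plus one ancestor per origin."""
        out = []
        for origin in self.origins:
            for regime in self.regimes:
                if regime == "ancestor":
                    out.append({"line_id": f"{origin}_anc", "origin": origin, "regime": regime})
                else:
                    for rep in range(1, self.replicates_per_regime + 1):
                        out.append(
                            {
                                "line_id": f"{origin}_{regime}{rep}",
                                "origin": origin,
                                "regime": regime,
                            }
                        )
        return out


@dataclass(frozen=True)
class EffectSpec:
    """Generator effect structure (trait, consumption and expression blocks).

    Built from a nested mapping; see ``data/default_effects.yaml`` for the
    shipped defaults and the full key inventory.
    """

    traits: dict = field(default_factory=dict)
    consumption: dict = field(default_factory=dict)
    expression: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        base = self.traits.get("baseline", {})
        for t, v in base.items():
            if v <= 0:
                raise InvalidInputError(f"baseline mean for {t} must be positive")
        for key in ("line_cv", "se_cv"):
            if self.traits.get(key, 0.0) < 0:
                raise InvalidInputError(f"{key} must be >= 0")
        frac_keys = [k for k in self.expression if k.startswith("n_")]
        for k in frac_keys:
            if self.expression[k] < 0:
                raise InvalidInputError(f"{k} must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "EffectSpec":
        return cls(
            traits=d.get("traits", {}),
            consumption=d.get("consumption", {}),
            expression=d.get("expression", {}),
        )

    @classmethod
    def default(cls) -> "EffectSpec":
        text = resources.files("thermofoot.data").joinpath("default_effects.yaml").read_text()
        return cls.from_dict(yaml.safe_load(text))


def default_design(seed: int = 0) -> DesignSpec:
    return DesignSpec(seed=seed)


def _regime_multiplier(effects: EffectSpec, regime: str, temp: float, trait: str) -> float:
    reg = effects.traits.get("regime_multipliers", {}).get(regime, {})
    return float(reg.get(int(temp), {}).get(trait, 1.0))


def generate_line_traits(design: DesignSpec, effects: EffectSpec) -> pd.DataFrame:
    """Long-format trait table: one row per line x assay temp x trait.

    The structural mean of a trait is
    ``baseline * origin_offset * regime_multiplier(regime, temp)``; a
    lognormal line-level jitter with CV ``line_cv`` is applied, and the SE
    is ``se_cv * mean``. Deterministic per design seed.
    """
    rng = np.random.default_rng(design.seed)
    base = effects.traits["baseline"]
    offsets = effects.traits.get("origin_offsets", {})
    line_cv = float(effects.traits.get("line_cv", 0.0))
    se_cv = float(effects.traits.get("se_cv", 0.0))
    rows = []
    for line in design.lines():
        off = float(offsets.get(line["origin"], 1.0))
        # one jitter factor per line x trait, shared across assay temps
        jitter = {
            t: float(rng.lognormal(0.0, line_cv)) if line_cv > 0 else 1.0 for t in TRAITS
        }
        for temp in design.assay_temps:
            for trait in TRAITS:
                mean = (
                    base[trait]
                    * off
                    * _regime_multiplier(effects, line["regime"], temp, trait)
                    * jitter[trait]
                )
                rows.append(
                    {
                        **line,
                        "assay_temp_C": float(temp),
                        "trait": trait,
                        "mean": mean,
                        "se": se_cv * mean,
                    }
                )
    out = pd.DataFrame(rows)
    out.attrs["generator"] = {
        "seed": design.seed,
        "traits": effects.traits,
        "design": {"origins": design.origins, "replicates": design.replicates_per_regime},
    }
    return out


def simulate_consumption_dishes(
    n: int,
    temp: float,
    C_m: float,
    effects: EffectSpec,
    rng: np.random.Generator,
    line_id: str = "synthetic",
    regime: str = "ancestor",
    eggs_multiplier: float = 1.0,
) -> pd.DataFrame:
    """Dish-level consumption assays at one temperature.

    ``eggs ~ Poisson(mu * lognormal dish effect)``, ``survivors ~
    Binomial(eggs, survival_p)``, ``mean_adult_mass ~ Normal``, and
    ``host_loss_raw = C_m * survivors * mass + drift + Normal noise`` with
    noise sd equal to ``noise_cv`` times the mean expected consumption.
    """
    c = effects.consumption
    mu = float(c["mu_eggs"]) * eggs_multiplier
    dish_cv = float(c.get("dish_cv", 0.0))
    dish_effect = rng.lognormal(-0.5 * dish_cv**2, dish_cv, size=n) if dish_cv > 0 else 1.0
    eggs = rng.poisson(mu * dish_effect, size=n)
    survivors = rng.binomial(eggs, float(c["survival_p"]))
    mass = rng.normal(float(c["mass_mean"]), float(c["mass_cv"]) * float(c["mass_mean"]), size=n)
    mass = np.maximum(mass, 1e-3)
    expected = C_m * mu * float(c["survival_p"]) * float(c["mass_mean"])
    noise_sd = float(c["noise_cv"]) * expected
    drift = rng.normal(float(c["drift"]), float(c.get("drift_sd", 0.0)), size=n)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    host_loss = C_m * survivors * mass + drift + noise
    return pd.DataFrame(
        {
            "dish_id": [f"{line_id}_T{int(temp)}_d{i}" for i in range(n)],
            "line_id": line_id,
            "regime": regime,
            "assay_temp_C": float(temp),
            "eggs": eggs,
            "survivors": survivors,
            "mean_adult_mass": mass,
            "host_loss_raw": np.maximum(host_loss, 0.0),
        }
    )


def generate_consumption(
    design: DesignSpec, effects: EffectSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Consumption assays for every line x temp, plus beetle-free controls."""
    rng = np.random.default_rng(design.seed + 1)
    c = effects.consumption
    cm_map = {float(k): float(v) for k, v in c["C_m"].items()}
    n_dishes = int(c.get("dishes_per_assay", 3))
    n_controls = int(c.get("controls_per_temp", 5))
    frames = []
    for line in design.lines():
        for temp in design.assay_temps:
            mult = _regime_multiplier(effects, line["regime"], temp, "omega")
            frames.append(
                simulate_consumption_dishes(
                    n_dishes,
                    temp,
                    cm_map[float(temp)],
                    effects,
                    rng,
                    line_id=line["line_id"],
                    regime=line["regime"],
                    eggs_multiplier=mult,
                )
            )
    assays = pd.concat(frames, ignore_index=True)
    ctrl_rows = []
    for temp in design.assay_temps:
        drift = rng.normal(float(c["drift"]), float(c.get("drift_sd", 0.0)), size=n_controls)
        for d in drift:
            ctrl_rows.append({"assay_temp_C": float(temp), "host_loss": max(float(d), 0.0)})
    controls = pd.DataFrame(ctrl_rows)
    assays.attrs["generator"] = {"seed": design.seed + 1, "consumption": c}
    return assays, controls


def generate_expression(
    design: DesignSpec, effects: EffectSpec
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Gene panel, sample metadata and a genes x samples count matrix.

    The panel holds the configured numbers of antagonistic genes in each
    polarity (up-mating/down-heat and down-mating/up-heat) and concordant
    (both-down) genes; heat log-fold changes mirror the mating ones with a
    small multiplicative jitter, so panels are near-perfectly antagonistic.
    Sample counts are negative-binomial with per-gene lognormal baselines;
    samples assayed at 35 degC have means shifted along the heat-response
    direction (towards the maintenance pole).
    """
    rng = np.random.default_rng(design.seed + 2)
    e = effects.expression
    n_up, n_down = int(e["n_up_mating_down_heat"]), int(e["n_down_mating_up_heat"])
    n_conc = int(e.get("n_concordant_down", 0))
    scale = float(e.get("lfc_scale", 1.0))
    jit = float(e.get("mirror_jitter", 0.02))
    n_genes = n_up + n_down + n_conc
    gene_id = [f"g{i:04d}" for i in range(n_genes)]
    mag = scale * (0.2 + rng.lognormal(0.0, 0.5, size=n_genes))
    lfc_m = np.empty(n_genes)
    lfc_m[:n_up] = mag[:n_up]
    lfc_m[n_up : n_up + n_down] = -mag[n_up : n_up + n_down]
    lfc_m[n_up + n_down :] = -mag[n_up + n_down :]
    lfc_h = -lfc_m * (1.0 + jit * rng.standard_normal(n_genes))
    # concordant genes: both responses decrease expression
    lfc_h[n_up + n_down :] = -np.abs(lfc_h[n_up + n_down :])
    panel = pd.DataFrame(
        {
            "gene_id": gene_id,
            "lfc_mating": lfc_m,
            "lfc_heat": lfc_h,
            "sig_mating": True,
            "sig_heat": True,
        }
    )

    samples = []
    for line in design.lines():
        n_reps = 2 if line["regime"] == "ancestor" else 1
        for temp in design.assay_temps:
            for rep in range(1, n_reps + 1):
                samples.append(
                    {
                        "sample_id": f"{line['line_id']}_T{int(temp)}_r{rep}",
                        "line_id": line["line_id"],
                        "origin": line["origin"],
                        "regime": line["regime"],
                        "assay_temp_C": float(temp),
                    }
                )
    meta = pd.DataFrame(samples)

    base = rng.lognormal(np.log(float(e.get("base_mean", 200.0))), float(e.get("base_sigma", 1.0)), size=n_genes)
    shift = float(e.get("hot_shift", 1.0))
    heat_dir = np.sign(panel["lfc_heat"].to_numpy())
    disp = float(e.get("nb_dispersion", 10.0))
    cols = {}
    for _, s in meta.iterrows():
        mu = base * np.exp(heat_dir * shift if s["assay_temp_C"] == 35.0 else 0.0)
        p_nb = disp / (disp + mu)
        cols[s["sample_id"]] = rng.negative_binomial(disp, p_nb)
    counts = pd.DataFrame(cols, index=gene_id, dtype=float)
    counts.insert(0, "gene_id", gene_id)
    counts = counts.reset_index(drop=True)
    panel.attrs["generator"] = {"seed": design.seed + 2, "expression": e}
    return panel, meta, counts


def generate_model_truth(
    params: KineticParams,
    design: DesignSpec,
    cfg: OptimizerConfig | None = None,
    reference: dict | None = None,
    se_cv: float = 0.0,
) -> pd.DataFrame:
    """Trait table implied by the thermodynamic model.

    Each regime's strategy is optimized at its evolution temperature (cold
    23, ancestor 29, hot 35 degC) and frozen; trait means at each assay
    temperature are mapped from the growth-rate components so that
    phi1 is exactly proportional to M * r':

    * ``mass = mass_ref * M / M_ancestor``
    * ``omega = omega_ref * (survival * productivity * stability) / (same at ancestor, 29 degC)``
    * ``d1 = d1_ref * reaction_rate(ancestor, 29 degC) / reaction_rate``
    * ``psi``, ``d2`` scale with omega and d1 respectively.

    The mapping constants are recorded in ``DataFrame.attrs``. Rows from
    non-converged optimizations are flagged in the ``converged`` column.
    """
    ref = {"mass_M": 6.0, "omega": 60.0, "d1": 21.0, "psi_frac": 0.8, "d2_frac": 0.9}
    ref.update(reference or {})
    adapt_temp = {"cold": 23.0, "ancestor": 29.0, "hot": 35.0}
    opts = {
        regime: optimize_strategy(celsius_to_kelvin(t).item(), params, cfg)
        for regime, t in adapt_temp.items()
    }
    anc = opts["ancestor"]
    anc_out = growth_rate(celsius_to_kelvin(29.0).item(), anc.strategy, params)
    anc_sb = anc_out.survival * anc_out.productivity * anc_out.stability
    rows = []
    for line in design.lines():
        opt = opts[line["regime"]]
        for temp in design.assay_temps:
            out = growth_rate(celsius_to_kelvin(temp).item(), opt.strategy, params)
            sb = out.survival * out.productivity * out.stability
            mass = ref["mass_M"] * opt.strategy.M / anc.strategy.M
            omega = ref["omega"] * sb / anc_sb
            d1 = ref["d1"] * anc_out.reaction_rate / out.reaction_rate if out.reaction_rate > 0 else np.inf
            for trait, mean in (
                ("omega", omega),
                ("mass_M", mass),
                ("d1", d1),
                ("psi", ref["psi_frac"] * omega),
                ("d2", ref["d2_frac"] * d1),
            ):
                rows.append(
                    {
                        **line,
                        "assay_temp_C": float(temp),
                        "trait": trait,
                        "mean": float(mean),
                        "se": se_cv * float(mean) if np.isfinite(mean) else 0.0,
                        "converged": opt.converged,
                    }
                )
    out_df = pd.DataFrame(rows)
    out_df.attrs["generator"] = {
        "mapping": ref,
        "adapt_temp": adapt_temp,
        "ancestor_strategy": vars(anc.strategy),
    }
    return out_df
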