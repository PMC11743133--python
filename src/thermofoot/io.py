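"""Configuration, table I/O and the end-to-end pipeline.

Tables are plain CSV/TSV (delimiter chosen by extension) validated against
named schemas. The run configuration is YAML with ``model``, ``optimizer``
and ``bootstrap`` sections; unknown keys are rejected so typos fail loudly.
Every pipeline output JSON embeds the seed and a hash of the effective
configuration, making reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consumption as cons
from . import expression as expr
from . import footprint as fp
from . import simulate as sim
from .errors import ConfigurationError, SchemaError
from .optimize import OptimizerConfig
from .thermo import KineticParams

log = logging.getLogger(__name__)

_MODEL_KEYS = {"a_B", "Ea_B", "kappa_D", "dH_m", "T_m", "dCp", "c", "b"}
_OPT_KEYS = {"M_bounds", "grid_n", "refine", "refine_tol", "n_restarts", "seed"}
_BOOT_KEYS = {"n_boot", "seed"}
_TOP_KEYS = {"version", "model", "optimizer", "bootstrap", "paths"}

SCHEMAS: dict[str, list[str]] = {
    "line_traits": ["line_id", "origin", "regime", "assay_temp_C", "trait", "mean", "se"],
    "consumption": cons.ASSAY_COLUMNS,
    "controls": cons.CONTROL_COLUMNS,
    "gene_panel": expr.PANEL_COLUMNS,
    "counts": ["gene_id"],
    "cm_table": ["assay_temp_C", "C_m"],
}

_NUMERIC = {
    "line_traits": ["assay_temp_C", "mean", "se"],
    "consumption": ["assay_temp_C", "eggs", "survivors", "mean_adult_mass", "host_loss_raw"],
    "controls": ["assay_temp_C", "host_loss"],
    "gene_panel": ["lfc_mating", "lfc_heat"],
    "cm_table": ["assay_temp_C", "C_m"],
}


@dataclass(frozen=True)
class RunConfig:
    model: KineticParams
    optimizer: OptimizerConfig
    n_boot: int
    seed: int
    version: int
    raw: dict

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.raw, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _check_keys(section: dict, allowed: set[str], name: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigurationError(f"unknown key(s) in [{name}]: {sorted(unknown)}")


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML run configuration; ``None`` loads the shipped default."""
    if path is None:
        text = resources.files("thermofoot.data").joinpath("default_config.yaml").read_text()
    else:
        path = Path(path)
        if not path.exists():
            raise ConfigurationError(f"config file not found: {path}")
        text = path.read_text()
    raw = yaml.safe_load(text)
    _check_keys(raw, _TOP_KEYS, "top level")
    model_sec = raw.get("model", {})
    _check_keys(model_sec, _MODEL_KEYS, "model")
    missing = _MODEL_KEYS - set(model_sec) - {"dCp", "c", "b", "a_B"}
    if missing:
        raise ConfigurationError(f"missing model key(s): {sorted(missing)}")
    opt_sec = dict(raw.get("optimizer", {}))
    _check_keys(opt_sec, _OPT_KEYS, "optimizer")
    if "M_bounds" in opt_sec:
        opt_sec["M_bounds"] = tuple(float(x) for x in opt_sec["M_bounds"])
    boot_sec = raw.get("bootstrap", {})
    _check_keys(boot_sec, _BOOT_KEYS, "bootstrap")
    paths = raw.get("paths", {}) or {}
    for key, p in paths.items():
        if not Path(p).exists():
            raise ConfigurationError(f"configured path does not exist: {key}={p}")
    return RunConfig(
        model=KineticParams(**model_sec),
        optimizer=OptimizerConfig(**opt_sec),
        n_boot=int(boot_sec.get("n_boot", 2000)),
        seed=int(boot_sec.get("seed", 0)),
        version=int(raw.get("version", 1)),
        raw=raw,
    )


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV/TSV table against a named schema."""
    path = Path(path)
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'; known: {sorted(SCHEMAS)}")
    df = pd.read_csv(path, sep=_delimiter(path))
    missing = [c for c in SCHEMAS[schema] if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing}")
    for col in _NUMERIC.get(schema, []):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            raise SchemaError(
                f"{path.name}: non-numeric value in column '{col}' at row {int(bad.idxmax())}"
            )
        df[col] = coerced
    if schema == "counts":
        value_cols = [c for c in df.columns if c != "gene_id"]
        df[value_cols] = df[value_cols].apply(pd.to_numeric)
    log.info("read %s: %d rows, %d columns", path.name, len(df), df.shape[1])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_delimiter(path), index=False)
    return path


def traits_from_table(df: pd.DataFrame) -> list[fp.LineTraits]:
    """Pivot a long-format trait table into LineTraits records."""
    records = []
    for (line_id, origin, regime, temp), grp in df.groupby(
        ["line_id", "origin", "regime", "assay_temp_C"], sort=True
    ):
        by_trait = grp.set_index("trait")
        try:
            est = {
                t: fp.TraitEstimate(float(by_trait.loc[t, "mean"]), float(by_trait.loc[t, "se"]))
                for t in sim.TRAITS
            }
        except KeyError as exc:
            raise SchemaError(f"line {line_id} at {temp} degC missing trait {exc}") from exc
        records.append(
            fp.LineTraits(
                line_id=str(line_id),
                origin=str(origin),
                regime=str(regime),
                assay_temp=float(temp),
                omega=est["omega"],
                mass_M=est["mass_M"],
                d1=est["d1"],
                psi=est["psi"],
                d2=est["d2"],
            )
        )
    return records


def footprint_pipeline(
    traits_df: pd.DataFrame,
    cm_by_temp: dict[float, float],
    ce_by_temp: dict[float, float] | float,
    n_boot: int,
    seed: int,
) -> dict:
    """phi1/phi2 per line x temp, ancestor-relative changes and correlation."""
    records = traits_from_table(traits_df)
    ancestors = {
        (r.origin, r.assay_temp): r for r in records if r.regime == "ancestor"
    }
    results = []
    phi1s, phi2s = [], []
    for i, r in enumerate(records):
        cm = cm_by_temp[r.assay_temp]
        ce = ce_by_temp if isinstance(ce_by_temp, (int, float)) else ce_by_temp[r.assay_temp]
        boot1 = fp.parametric_bootstrap(r, cm, n_boot, seed + i)
        boot2 = fp.parametric_bootstrap_phi2(r, ce, n_boot, seed + i)
        entry = {
            "line_id": r.line_id,
            "origin": r.origin,
            "regime": r.regime,
            "assay_temp_C": r.assay_temp,
            "phi1": boot1.phi,
            "phi1_ci": [boot1.ci_low, boot1.ci_high],
            "phi2": boot2.phi,
            "phi2_ci": [boot2.ci_low, boot2.ci_high],
        }
        anc29 = ancestors.get((r.origin, 29.0))
        if anc29 is not None:
            rel = fp.relative_bootstrap(
                r, anc29, cm, cm_by_temp[29.0], n_boot, seed + 10_000 + i
            )
            entry["rel_footprint_pct"] = rel.phi
            entry["rel_footprint_ci"] = [rel.ci_low, rel.ci_high]
        # evolution effect: line versus its own ancestor at the same assay
        # temperature (the conversion constant cancels)
        anc_same = ancestors.get((r.origin, r.assay_temp))
        if anc_same is not None and r.regime != "ancestor":
            delta = fp.relative_bootstrap(r, anc_same, cm, cm, n_boot, seed + 20_000 + i)
            entry["delta_vs_ancestor_pct"] = delta.phi
            entry["delta_vs_ancestor_ci"] = [delta.ci_low, delta.ci_high]
        results.append(entry)
        phi1s.append(boot1.phi)
        phi2s.append(boot2.phi)
    r_corr, t_stat, dof = fp.footprint_correlation(phi1s, phi2s)
    return {
        "per_line": results,
        "correlation": {"r": r_corr, "t": t_stat, "df": dof},
        "n_boot": n_boot,
        "seed": seed,
    }


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    effects: sim.EffectSpec | None = None,
    design: sim.DesignSpec | None = None,
) -> dict:
    """simulate -> consumption -> footprint -> expression, with JSON summary.

    Stage failures abort with the failing stage named in the log. Returns
    the summary dict (also written to ``summary.json`` under ``out_dir``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    effects = effects or sim.EffectSpec.default()
    design = design or sim.DesignSpec(seed=config.seed)
    summary: dict = {"seed": config.seed, "config_hash": config.config_hash, "version": config.version}
    stage = "simulate"
    try:
        traits_df = sim.generate_line_traits(design, effects)
        assays, controls = sim.generate_consumption(design, effects)
        panel, meta, counts = sim.generate_expression(design, effects)
        write_table(traits_df, out_dir / "line_traits.tsv")
        write_table(assays, out_dir / "consumption.tsv")
        write_table(controls, out_dir / "controls.tsv")
        write_table(panel, out_dir / "gene_panel.tsv")
        write_table(counts, out_dir / "counts.tsv")

        stage = "consumption"
        corrected = cons.control_correct(assays, controls)
        cm = cons.estimate_Cm_by_temperature(corrected)
        ce = cons.estimate_CE_by_temperature(corrected)
        r2 = cons.lifehistory_variance_explained(corrected)
        summary["consumption"] = {
            "C_m": {str(t): {"slope": e.slope, "se": e.se, "n": e.n} for t, e in cm.items()},
            "C_E": {str(t): v for t, v in ce.items()},
            "r2_sequence": list(r2),
        }

        stage = "footprint"
        cm_slopes = {t: e.slope for t, e in cm.items()}
        summary["footprint"] = footprint_pipeline(
            traits_df, cm_slopes, ce, config.n_boot, config.seed
        )

        stage = "expression"
        n_genes = len(panel)
        scores = expr.tradeoff_scores(panel, counts)
        proj = expr.tradeoff_axis_projection(scores)
        directions = expr.classify_directions(panel)
        scored = scores.merge(meta, on="sample_id")
        scored["projection"] = proj.projection
        write_table(scored, out_dir / "tradeoff_scores.tsv")
        summary["expression"] = {
            "n_genes": n_genes,
            "antagonistic": directions.antagonistic,
            "concordant": directions.concordant,
            "p_binomial": directions.p_binomial,
            "score_correlation": proj.score_correlation,
            "mean_projection_by_temp": {
                str(t): float(np.mean(proj.projection[scored["assay_temp_C"] == t]))
                for t in sorted(scored["assay_temp_C"].unique())
            },
        }
    except Exception:
        log.error("pipeline stage '%s' failed", stage)
        raise
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
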