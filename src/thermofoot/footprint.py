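"""Agricultural footprint metrics, bootstrap uncertainty and selection stats.

Two independent per-line footprints (host mass destroyed per day):

* ``phi1 = C_m * omega * mass / d1`` from lifetime offspring production,
  adult mass at emergence and mean egg-to-adult development time;
* ``phi2 = psi * C_E / d2`` from early fecundity, per-egg host consumption
  and the development time of the fastest individual.

Uncertainty is propagated by a parametric bootstrap drawing each trait
independently from Normal(mean, se), truncated at a small positive floor
for strictly positive traits; intervals are 2.5/97.5 percentiles. Point
estimates are plug-in values from the trait means, so the printed phi is
noise-free.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError

log = logging.getLogger(__name__)

_FLOOR_FRACTION = 1e-6  # truncation floor for strictly positive traits


@dataclass(frozen=True)
class TraitEstimate:
    mean: float
    se: float

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InvalidInputError("se must be >= 0")
        if not math.isfinite(self.mean):
            raise InvalidInputError("mean must be finite")


@dataclass(frozen=True)
class LineTraits:
    """Per-line trait summaries at one assay temperature."""

    line_id: str
    origin: str
    regime: str
    assay_temp: float
    omega: TraitEstimate
    mass_M: TraitEstimate
    d1: TraitEstimate
    psi: TraitEstimate
    d2: TraitEstimate

    def __post_init__(self) -> None:
        if self.d1.mean <= 0 or self.d2.mean <= 0:
            raise InvalidInputError("development times must be > 0")
        if self.mass_M.mean <= 0:
            raise InvalidInputError("body mass must be > 0")
        if self.omega.mean < 0 or self.psi.mean < 0:
            raise InvalidInputError("offspring/egg counts must be >= 0")


@dataclass(frozen=True)
class FootprintResult:
    phi: float
    ci_low: float
    ci_high: float
    n_boot: int
    seed: int


def phi1(C_m: float, omega: float, mass_M: float, d1: float) -> float:
    """Footprint from lifetime reproduction: ``C_m * omega * mass / d1``."""
    if d1 <= 0:
        raise InvalidInputError("d1 must be > 0")
    return C_m * omega * mass_M / d1


def phi2(psi: float, C_E: float, d2: float) -> float:
    """Footprint from early fecundity: ``psi * C_E / d2``."""
    if d2 <= 0:
        raise InvalidInputError("d2 must be > 0")
    return psi * C_E / d2


def relative_footprint(line_phi: float, ancestor_phi_29C: float) -> float:
    """Percent change of a line's footprint versus its ancestor at 29 degC."""
    if not ancestor_phi_29C > 0:
        raise InvalidInputError("ancestor reference footprint must be > 0")
    return 100.0 * (line_phi / ancestor_phi_29C - 1.0)


def _draw_traits(traits: LineTraits, rng: np.random.Generator, n: int) -> dict:
    """Independent truncated-normal draws per trait; floors are logged."""
    draws = {}
    floors = 0
    for name, positive in (
        ("omega", False),
        ("mass_M", True),
        ("d1", True),
        ("psi", False),
        ("d2", True),
    ):
        est: TraitEstimate = getattr(traits, name)
        x = rng.normal(est.mean, est.se, size=n)
        if positive:
            floor = _FLOOR_FRACTION * abs(est.mean)
            nlow = int((x < floor).sum())
            if nlow:
                floors += nlow
                x = np.maximum(x, floor)
        else:
            x = np.maximum(x, 0.0)
        draws[name] = x
    if floors:
        log.info("bootstrap truncation floor applied to %d draws", floors)
    return draws


def parametric_bootstrap(
    traits: LineTraits, C_m: float, n_boot: int, seed: int
) -> FootprintResult:
    """phi1 with percentile bootstrap CI from per-trait Normal(mean, se)."""
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    d = _draw_traits(traits, rng, n_boot)
    phis = C_m * d["omega"] * d["mass_M"] / d["d1"]
    point = phi1(C_m, traits.omega.mean, traits.mass_M.mean, traits.d1.mean)
    lo, hi = np.percentile(phis, [2.5, 97.5])
    return FootprintResult(point, float(lo), float(hi), n_boot, seed)


def parametric_bootstrap_phi2(
    traits: LineTraits, C_E: float, n_boot: int, seed: int
) -> FootprintResult:
    """phi2 analogue of :func:`parametric_bootstrap`."""
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    d = _draw_traits(traits, rng, n_boot)
    phis = d["psi"] * C_E / d["d2"]
    point = phi2(traits.psi.mean, C_E, traits.d2.mean)
    lo, hi = np.percentile(phis, [2.5, 97.5])
    return FootprintResult(point, float(lo), float(hi), n_boot, seed)


def relative_bootstrap(
    line: LineTraits,
    ancestor_29C: LineTraits,
    C_m_line: float,
    C_m_29C: float,
    n_boot: int,
    seed: int,
) -> FootprintResult:
    """Percent footprint change of a line versus its own ancestor at 29 degC.

    Both the line's and the ancestor's traits are redrawn in each bootstrap
    replicate; the reported point estimate is the plug-in ratio of means.
    """
    if n_boot < 1:
        raise InvalidInputError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    dl = _draw_traits(line, rng, n_boot)
    da = _draw_traits(ancestor_29C, rng, n_boot)
    num = C_m_line * dl["omega"] * dl["mass_M"] / dl["d1"]
    den = C_m_29C * da["omega"] * da["mass_M"] / da["d1"]
    den = np.where(den <= 0, np.nan, den)
    rel = 100.0 * (num / den - 1.0)
    point = relative_footprint(
        phi1(C_m_line, line.omega.mean, line.mass_M.mean, line.d1.mean),
        phi1(C_m_29C, ancestor_29C.omega.mean, ancestor_29C.mass_M.mean, ancestor_29C.d1.mean),
    )
    lo, hi = np.nanpercentile(rel, [2.5, 97.5])
    return FootprintResult(point, float(lo), float(hi), n_boot, seed)


def per_generation_rate(delta_pct: float, n_generations: int) -> float:
    """Percent change per generation under a constant (linear) pace.

    Reported rounded to one decimal.
    """
    if n_generations < 1:
        raise InvalidInputError("n_generations must be >= 1")
    return round(delta_pct / n_generations, 1)


def footprint_correlation(phi1_by_line, phi2_by_line) -> tuple[float, float, int]:
    """Pearson correlation of the two footprint metrics across lines.

    Returns ``(r, t, df)`` with ``t = r * sqrt((n - 2) / (1 - r**2))`` and
    ``df = n - 2``.
    """
    x = np.asarray(phi1_by_line, dtype=float)
    y = np.asarray(phi2_by_line, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidInputError("need equal-length sequences with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y).statistic)
    df = x.size - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
    return r, t, df


def selection_differential(fitness, trait) -> float:
    """Directional selection differential on a standardized trait.

    Sample covariance (n-1 denominator) between relative fitness
    ``w / mean(w)`` and the z-scored trait.
    """
    w = np.asarray(fitness, dtype=float)
    z = np.asarray(trait, dtype=float)
    if w.size != z.size or w.size < 3:
        raise InvalidInputError("need equal-length sequences with n >= 3")
    if w.mean() <= 0:
        raise UndefinedStatisticError("mean fitness must be > 0")
    sd = z.std(ddof=1)
    if sd == 0:
        raise UndefinedStatisticError("trait variance is zero")
    rel_w = w / w.mean()
    zs = (z - z.mean()) / sd
    return float(np.cov(rel_w, zs, ddof=1)[0, 1])
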