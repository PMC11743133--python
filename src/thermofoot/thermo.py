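"""Thermodynamic life-history model.

Population growth rate is the product of four temperature- and
strategy-dependent factors:

* juvenile survival ``(1 - c)**M`` — the cost of acquiring reserves ``M``,
* productivity ``[M (1 - p - q)]**b`` — reserves left for growth and
  reproduction after allocation,
* an Arrhenius reaction-rate factor with prefactor proportional to ``p M``,
* a protein-stability factor ``1 / (1 + A_D K_u(T))`` with
  ``A_D = kappa_D / (q M)``, where ``K_u`` is the two-state unfolding
  equilibrium constant.

The failure kinetics are realized through two-state unfolding
thermodynamics (``dH_m``, ``T_m``, optional ``dCp`` curvature); this stands
in for a temperature-dependent activation energy of molecular failure.
All proportionality constants are absorbed into ``a_B`` and ``kappa_D``,
so outputs are in relative units. Temperatures are Kelvin internally;
user-facing interfaces use degrees Celsius (see :func:`celsius_to_kelvin`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

R_GAS = 8.314
"""Universal gas constant, J/(mol K)."""

KELVIN_OFFSET = 273.15


def celsius_to_kelvin(temp_c):
    """Convert Celsius (scalar or array) to Kelvin."""
    return np.asarray(temp_c, dtype=float) + KELVIN_OFFSET


@dataclass(frozen=True)
class KineticParams:
    """Constants of the thermodynamic model.

    Parameters
    ----------
    a_B : float
        Productivity rate scale per unit ``p * M`` (dimensionless baseline).
    Ea_B : float
        Productivity activation energy, J/mol (> 0).
    kappa_D : float
        Failure scale before division by the maintenance allocation ``q * M``.
    dH_m : float
        Enthalpy of unfolding at the midpoint, J/mol (> 0).
    T_m : float
        Unfolding midpoint temperature, K (> 273.15).
    dCp : float, optional
        Heat-capacity change of unfolding, J/(mol K). Default 0.
    c : float, optional
        Per-unit cost of juvenile resource acquisition, probability in [0, 1).
    b : float, optional
        Allometric exponent, in (0, 1]. Default 0.75.
    """

    a_B: float
    Ea_B: float
    kappa_D: float
    dH_m: float
    T_m: float
    dCp: float = 0.0
    c: float = 0.1
    b: float = 0.75

    def __post_init__(self) -> None:
        checks = [
            (self.a_B >= 0, "a_B must be >= 0"),
            (self.Ea_B > 0, "Ea_B must be > 0"),
            (self.kappa_D > 0, "kappa_D must be > 0"),
            (self.dH_m > 0, "dH_m must be > 0"),
            (self.T_m > KELVIN_OFFSET, "T_m must exceed 273.15 K"),
            (0 <= self.c < 1, "c must lie in [0, 1)"),
            (0 < self.b <= 1, "b must lie in (0, 1]"),
        ]
        for ok, msg in checks:
            if not ok:
                raise InvalidInputError(msg)
        for name in ("a_B", "Ea_B", "kappa_D", "dH_m", "T_m", "dCp", "c", "b"):
            if not math.isfinite(getattr(self, name)):
                raise InvalidInputError(f"{name} must be finite")


@dataclass(frozen=True)
class Strategy:
    """A life-history strategy: acquired reserves and their allocation.

    ``M`` is the acquired energy reserve (> 0), ``p`` the fraction allocated
    to catalytic capacity, ``q`` the fraction allocated to maintenance;
    ``p + q <= 1`` and the residual ``M (1 - p - q)`` funds reproduction.
    """

    M: float
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (self.M > 0 and math.isfinite(self.M)):
            raise InvalidInputError("M must be positive and finite")
        if self.p < 0 or self.q < 0:
            raise InvalidInputError("allocation fractions must be >= 0")
        if self.p + self.q > 1 + 1e-12:
            raise InvalidInputError("p + q must not exceed 1")


@dataclass(frozen=True)
class ModelOutput:
    """Growth rate at one temperature, with its multiplicative components."""

    T: float
    r_prime: float
    impact: float
    survival: float
    productivity: float
    reaction_rate: float
    stability: float

    @property
    def components(self) -> dict[str, float]:
        return {
            "survival": self.survival,
            "productivity": self.productivity,
            "reaction_rate": self.reaction_rate,
            "stability": self.stability,
        }


def arrhenius_rate(A, Ea, T):
    """Arrhenius rate ``A * exp(-Ea / (R T))``.

    Accepts scalars or arrays; ``T`` must be positive (Kelvin).
    """
    A = np.asarray(A, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("temperature must be positive (Kelvin)")
    if np.any(A < 0):
        raise InvalidInputError("rate scale A must be >= 0")
    out = A * np.exp(-np.asarray(Ea, dtype=float) / (R_GAS * T))
    return out.item() if out.ndim == 0 else out


def unfold_constant(T, params: KineticParams):
    """Two-state unfolding equilibrium constant ``K_u(T)``.

    ``K_u = exp(-dG_u / (R T))`` with
    ``dG_u(T) = dH_m (1 - T/T_m) - dCp [(T_m - T) + T ln(T/T_m)]``.
    Equals 1 exactly at ``T = T_m``.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise InvalidInputError("temperature must be positive (Kelvin)")
    dG = params.dH_m * (1.0 - T / params.T_m) - params.dCp * (
        (params.T_m - T) + T * np.log(T / params.T_m)
    )
    out = np.exp(-dG / (R_GAS * T))
    return out.item() if out.ndim == 0 else out


def stability_factor(T, strategy: Strategy, params: KineticParams):
    """Proportion of properly folded (working) protein, in [0, 1].

    ``1 / (1 + (kappa_D / (q M)) K_u(T))``; the ``q -> 0`` limit is 0 and is
    returned rather than raised so optimizers can probe the boundary.
    """
    qM = strategy.q * strategy.M
    if qM == 0:
        k = unfold_constant(T, params)
        zero = np.zeros_like(np.asarray(k, dtype=float))
        return zero.item() if zero.ndim == 0 else zero
    k = unfold_constant(T, params)
    out = 1.0 / (1.0 + (params.kappa_D / qM) * np.asarray(k, dtype=float))
    return out.item() if np.ndim(out) == 0 else out


def juvenile_survival(M, c):
    """Survival to maturity ``(1 - c)**M`` under acquisition cost ``c``."""
    if not 0 <= c < 1:
        raise InvalidInputError("c must lie in [0, 1)")
    M = np.asarray(M, dtype=float)
    if np.any(M < 0):
        raise InvalidInputError("M must be >= 0")
    out = (1.0 - c) ** M
    return out.item() if out.ndim == 0 else out


def productivity(strategy: Strategy, b: float):
    """Productivity ``[M (1 - p - q)]**b`` of the residual reserves."""
    residual = max(strategy.M * (1.0 - strategy.p - strategy.q), 0.0)
    return residual**b


def growth_rate(T, strategy: Strategy, params: KineticParams) -> ModelOutput:
    """Population growth rate r' at temperature ``T`` (Kelvin).

    r' is the product of juvenile survival, productivity, the Arrhenius
    reaction-rate factor (prefactor ``a_B p M``) and the protein-stability
    factor. Zero whenever ``p = 0``, ``q = 0`` or ``p + q = 1``.
    """
    surv = juvenile_survival(strategy.M, params.c)
    prod = productivity(strategy, params.b)
    rate = arrhenius_rate(params.a_B * strategy.p * strategy.M, params.Ea_B, T)
    stab = stability_factor(T, strategy, params)
    r = surv * prod * rate * stab
    return ModelOutput(
        T=float(T),
        r_prime=float(r),
        impact=float(strategy.M * r),
        survival=float(surv),
        productivity=float(prod),
        reaction_rate=float(rate),
        stability=float(stab),
    )


def agricultural_impact(T, strategy: Strategy, params: KineticParams) -> float:
    """Impact ``M * r'(T)`` — growth rate weighted by per-capita consumption."""
    return growth_rate(T, strategy, params).impact


def relative_response(values, reference):
    """Element-wise division by a positive reference value."""
    if not reference > 0:
        raise InvalidInputError("reference must be > 0")
    return np.asarray(values, dtype=float) / float(reference)


def r_prime_grid(T, M, p, q, params: KineticParams):
    """Vectorized r' over broadcastable arrays of (M, p, q) at scalar ``T``.

    Infeasible points (p + q > 1, p < 0, q < 0, M <= 0) evaluate to 0.
    Used by grid searches; agrees with :func:`growth_rate` pointwise.
    """
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    feas = (p >= 0) & (q >= 0) & (p + q <= 1.0) & (M > 0)
    Mf = np.where(feas, M, 1.0)
    pf = np.where(feas, p, 0.0)
    qf = np.where(feas, q, 0.0)
    surv = (1.0 - params.c) ** Mf
    prod = np.maximum(Mf * (1.0 - pf - qf), 0.0) ** params.b
    rate = params.a_B * pf * Mf * np.exp(-params.Ea_B / (R_GAS * float(T)))
    ku = unfold_constant(float(T), params)
    qM = qf * Mf
    with np.errstate(divide="ignore"):
        stab = np.where(qM > 0, 1.0 / (1.0 + params.kappa_D * ku / np.where(qM > 0, qM, 1.0)), 0.0)
    return np.where(feas, surv * prod * rate * stab, 0.0)
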