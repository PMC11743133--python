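"""Optimal acquisition/allocation strategies and thermal performance curves.

The optimum of r' over {M in bounds, p >= 0, q >= 0, p + q <= 1} is found by
a coarse simplex-constrained grid scan followed by derivative-free local
refinement (Nelder-Mead) started from the best grid point plus seeded
jittered restarts. Ties on the grid are broken lexicographically by
(M, p, q) for reproducibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .errors import InvalidInputError
from .thermo import KineticParams, ModelOutput, Strategy, growth_rate, r_prime_grid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizerConfig:
    """Grid and refinement settings for :func:`optimize_strategy`."""

    M_bounds: tuple[float, float] = (0.5, 40.0)
    grid_n: int = 41
    refine: bool = True
    refine_tol: float = 1e-8
    n_restarts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.M_bounds
        if not (lo > 0 and hi > lo):
            raise InvalidInputError("M_bounds must satisfy 0 < low < high")
        if self.grid_n < 5:
            raise InvalidInputError("grid_n must be >= 5")


@dataclass(frozen=True)
class OptimalStrategy:
    strategy: Strategy
    r_prime: float
    T: float
    converged: bool
    evaluations: int


@dataclass(frozen=True)
class PerformanceCurve:
    """r' and impact of one fixed strategy across a temperature grid."""

    T: np.ndarray
    r_prime: np.ndarray
    impact: np.ndarray
    strategy: Strategy
    T_adapt: float
    converged: bool


def _objective(x, T, params, lo, hi, counter):
    counter[0] += 1
    M, p, q = x
    if not (lo <= M <= hi and p >= 0 and q >= 0 and p + q <= 1):
        return np.inf
    if p == 0 or q == 0:
        return 0.0
    return -growth_rate(T, Strategy(M, p, q), params).r_prime


def optimize_strategy(
    T: float, params: KineticParams, cfg: OptimizerConfig | None = None
) -> OptimalStrategy:
    """Maximize r' over (M, p, q) at temperature ``T`` (Kelvin)."""
    cfg = cfg or OptimizerConfig()
    lo, hi = cfg.M_bounds
    n = cfg.grid_n
    Ms = np.linspace(lo, hi, n)
    fr = np.linspace(0.0, 1.0, n)
    Mg, pg, qg = np.meshgrid(Ms, fr, fr, indexing="ij")
    vals = r_prime_grid(T, Mg, pg, qg, params)
    evaluations = vals.size

    best = float(vals.max())
    if best <= 0.0:
        log.warning("objective is zero over the entire grid at T=%.2f K", T)
        return OptimalStrategy(
            strategy=Strategy(lo, fr[1], fr[1]),
            r_prime=0.0,
            T=float(T),
            converged=False,
            evaluations=evaluations,
        )

    # lexicographic (M, p, q) tie-break among near-maximal grid points
    tie = np.argwhere(vals >= best * (1.0 - 1e-12))
    order = np.lexsort((tie[:, 2], tie[:, 1], tie[:, 0]))
    i, j, k = tie[order[0]]
    x0 = np.array([Ms[i], fr[j], fr[k]])
    best_x, best_val = x0, float(vals[i, j, k])

    if cfg.refine:
        rng = np.random.default_rng(cfg.seed)
        counter = [0]
        starts = [x0]
        step = np.array([(hi - lo) / (n - 1), 1.0 / (n - 1), 1.0 / (n - 1)])
        for _ in range(cfg.n_restarts):
            jitter = rng.uniform(-0.5, 0.5, size=3) * step
            starts.append(np.clip(x0 + jitter, [lo, 0, 0], [hi, 1, 1]))
        for s in starts:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = minimize(
                    _objective,
                    s,
                    args=(T, params, lo, hi, counter),
                    method="Nelder-Mead",
                    options={
                        "xatol": cfg.refine_tol * max(1.0, hi),
                        "fatol": cfg.refine_tol * best,
                        "maxiter": 2000,
                    },
                )
            if np.isfinite(res.fun) and -res.fun > best_val:
                best_val = -float(res.fun)
                best_x = np.asarray(res.x)
        evaluations += counter[0]

    M, p, q = best_x
    p, q = max(p, 0.0), max(q, 0.0)
    if p + q > 1:  # numerical fringe from the simplex boundary
        scale = (p + q) / 1.0
        p, q = p / scale, q / scale
    strat = Strategy(float(M), float(p), float(q))
    return OptimalStrategy(
        strategy=strat,
        r_prime=best_val,
        T=float(T),
        converged=True,
        evaluations=evaluations,
    )


def adapted_performance_curve(
    T_adapt: float,
    params: KineticParams,
    T_grid,
    cfg: OptimizerConfig | None = None,
) -> PerformanceCurve:
    """Optimize once at ``T_adapt``, then evaluate that fixed strategy on a grid.

    Models an adapted population with no plasticity: the strategy is frozen
    at its evolution temperature.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    if T_grid.size == 0 or np.any(np.diff(T_grid) <= 0):
        raise InvalidInputError("T_grid must be non-empty and increasing")
    opt = optimize_strategy(T_adapt, params, cfg)
    r = np.array([growth_rate(t, opt.strategy, params).r_prime for t in T_grid])
    return PerformanceCurve(
        T=T_grid,
        r_prime=r,
        impact=opt.strategy.M * r,
        strategy=opt.strategy,
        T_adapt=float(T_adapt),
        converged=opt.converged,
    )


def niche_breadth(T, values, level: float = 0.5) -> float:
    """Temperature span where the curve is >= ``level`` times its maximum.

    Crossings between grid points are located by linear interpolation; the
    spans of all super-threshold segments are summed. Returns 0 for an
    identically zero curve (with a warning log).
    """
    T = np.asarray(T, dtype=float)
    v = np.asarray(values, dtype=float)
    if T.size < 3 or T.size != v.size:
        raise InvalidInputError("need >= 3 aligned (T, value) points")
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    vmax = v.max()
    if vmax <= 0:
        log.warning("flat-zero curve: niche breadth is 0")
        return 0.0
    thr = level * vmax
    above = v >= thr
    width = 0.0
    start = None
    for idx in range(T.size):
        if above[idx] and start is None:
            if idx == 0:
                start = T[0]
            else:  # interpolate the upward crossing
                t0, t1, v0, v1 = T[idx - 1], T[idx], v[idx - 1], v[idx]
                start = t0 + (thr - v0) / (v1 - v0) * (t1 - t0)
        elif not above[idx] and start is not None:
            t0, t1, v0, v1 = T[idx - 1], T[idx], v[idx - 1], v[idx]
            end = t0 + (thr - v0) / (v1 - v0) * (t1 - t0)
            width += end - start
            start = None
    if start is not None:
        width += T[-1] - start
    return float(width)


@dataclass(frozen=True)
class PeakDisplacement:
    T_at_max_r: float
    T_at_max_impact: float
    r_prime: np.ndarray
    impact: np.ndarray
    T: np.ndarray
    boundary_warning: bool


def impact_peak_displacement(
    params: KineticParams, T_grid, cfg: OptimizerConfig | None = None
) -> PeakDisplacement:
    """Peak temperatures of r' and of impact for locally optimal strategies.

    At each grid temperature the strategy is re-optimized; the impact peak
    sits at or above the growth-rate peak because hotter optima carry
    larger reserves M.
    """
    T_grid = np.asarray(T_grid, dtype=float)
    opts = [optimize_strategy(t, params, cfg) for t in T_grid]
    r = np.array([o.r_prime for o in opts])
    imp = np.array([o.strategy.M * o.r_prime for o in opts])
    i_r, i_imp = int(np.argmax(r)), int(np.argmax(imp))
    boundary = i_r in (0, T_grid.size - 1) or i_imp in (0, T_grid.size - 1)
    if boundary:
        log.warning("a peak lies on the temperature-grid boundary")
    return PeakDisplacement(
        T_at_max_r=float(T_grid[i_r]),
        T_at_max_impact=float(T_grid[i_imp]),
        r_prime=r,
        impact=imp,
        T=T_grid,
        boundary_warning=boundary,
    )
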