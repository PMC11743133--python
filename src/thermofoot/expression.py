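"""Post-differential-expression analytics of the reproduction/maintenance
trade-off.

Given two differentially expressed gene sets (response to mating and to
heat shock) drawn from a common gene universe, this module computes the
overlap expected under independence with chi-square and hypergeometric
tests, classifies overlapping genes as concordant or antagonistic by the
signs of their two log-fold changes, scores samples by summed
lfc x normalized count, and projects the 2-D (reproduction, heat-stress)
score cloud onto its leading eigenvector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedStatisticError

log = logging.getLogger(__name__)

PANEL_COLUMNS = ["gene_id", "lfc_mating", "lfc_heat", "sig_mating", "sig_heat"]


@dataclass(frozen=True)
class OverlapResult:
    n_A: int
    n_B: int
    N: int
    observed: int
    expected: float
    chi2: float
    p_chi2: float
    p_hypergeom: float


@dataclass(frozen=True)
class DirectionCounts:
    antagonistic: int
    concordant: int
    quadrants: dict[str, int]
    p_binomial: float
    n_excluded: int


@dataclass(frozen=True)
class ProjectionResult:
    projection: np.ndarray
    axis: np.ndarray
    score_correlation: float


def overlap_stats(
    n_A: int, n_B: int, N: int, observed: int, yates: bool = False
) -> OverlapResult:
    """Overlap of two gene sets versus the independence expectation.

    ``expected = n_A * n_B / N`` (the hypergeometric mean). The chi-square
    statistic comes from the implied 2x2 contingency table (df = 1, no
    continuity correction unless ``yates=True``); ``p_hypergeom`` is the
    upper-tail probability of observing >= ``observed`` shared genes.
    """
    if not (0 <= n_A <= N and 0 <= n_B <= N):
        raise InvalidInputError("set sizes must lie in [0, N]")
    if not 0 <= observed <= min(n_A, n_B):
        raise InvalidInputError("observed overlap exceeds a set size")
    if observed < n_A + n_B - N:
        raise InvalidInputError("observed overlap below feasible minimum")
    table = np.array(
        [
            [observed, n_A - observed],
            [n_B - observed, N - n_A - n_B + observed],
        ],
        dtype=float,
    )
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    exp_table = rows * cols / N
    dev = np.abs(table - exp_table)
    if yates:
        dev = np.maximum(dev - 0.5, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        cells = np.where(exp_table > 0, dev**2 / exp_table, 0.0)
    chi2 = float(cells.sum())
    return OverlapResult(
        n_A=n_A,
        n_B=n_B,
        N=N,
        observed=observed,
        expected=n_A * n_B / N,
        chi2=chi2,
        p_chi2=float(stats.chi2.sf(chi2, df=1)),
        p_hypergeom=float(stats.hypergeom.sf(observed - 1, N, n_A, n_B)),
    )


def classify_directions(panel: pd.DataFrame) -> DirectionCounts:
    """Concordant/antagonistic classification of overlap genes.

    A gene is antagonistic when its mating and heat-shock log-fold changes
    have opposite signs. Genes with a zero lfc in either response are
    excluded (count logged). The binomial p-value is the exact upper-tail
    probability of >= max(antagonistic, concordant) successes in n trials
    at probability 0.5.
    """
    lfc_m = panel["lfc_mating"].to_numpy(dtype=float)
    lfc_h = panel["lfc_heat"].to_numpy(dtype=float)
    if not (np.isfinite(lfc_m).all() and np.isfinite(lfc_h).all()):
        raise InvalidInputError("log-fold changes must be finite")
    ties = (lfc_m == 0) | (lfc_h == 0)
    if ties.any():
        log.info("excluded %d genes with a zero log-fold change", int(ties.sum()))
    m, h = lfc_m[~ties], lfc_h[~ties]
    quadrants = {
        "up_mating_down_heat": int(((m > 0) & (h < 0)).sum()),
        "down_mating_up_heat": int(((m < 0) & (h > 0)).sum()),
        "both_up": int(((m > 0) & (h > 0)).sum()),
        "both_down": int(((m < 0) & (h < 0)).sum()),
    }
    antagonistic = quadrants["up_mating_down_heat"] + quadrants["down_mating_up_heat"]
    concordant = quadrants["both_up"] + quadrants["both_down"]
    n = antagonistic + concordant
    k = max(antagonistic, concordant)
    p = float(stats.binom.sf(k - 1, n, 0.5)) if n > 0 else 1.0
    return DirectionCounts(
        antagonistic=antagonistic,
        concordant=concordant,
        quadrants=quadrants,
        p_binomial=p,
        n_excluded=int(ties.sum()),
    )


def tradeoff_scores(panel: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample reproduction and heat-stress scores.

    ``score_R = sum_g lfc_mating(g) * count(g, sample)`` and likewise
    ``score_HS`` with the heat-shock log-fold changes. ``counts`` is a
    genes x samples matrix indexed by gene_id (first column), aligned to
    the panel's gene order.
    """
    counts = counts.set_index("gene_id") if "gene_id" in counts.columns else counts
    missing = set(panel["gene_id"]) - set(counts.index)
    if missing:
        raise InvalidInputError(
            f"counts matrix missing {len(missing)} panel genes (e.g. {sorted(missing)[:3]})"
        )
    mat = counts.loc[panel["gene_id"]].to_numpy(dtype=float)
    if (mat < 0).any():
        raise InvalidInputError("normalized counts must be >= 0")
    lfc_m = panel["lfc_mating"].to_numpy(dtype=float)
    lfc_h = panel["lfc_heat"].to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "sample_id": counts.columns,
            "score_R": lfc_m @ mat,
            "score_HS": lfc_h @ mat,
        }
    )


def tradeoff_axis_projection(scores: pd.DataFrame) -> ProjectionResult:
    """Project samples onto the leading eigenvector of the score cloud.

    The 2-D (score_R, score_HS) cloud is centered, the leading eigenvector
    of its covariance extracted, and samples projected onto it. The sign
    convention puts the maintenance pole (positive loading on score_HS) in
    the positive direction. Also returns the Pearson correlation of the
    two scores.
    """
    X = scores[["score_R", "score_HS"]].to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise InvalidInputError("need >= 3 samples")
    if np.allclose(X.var(axis=0), 0):
        raise UndefinedStatisticError("zero-variance score cloud: axis undefined")
    Xc = X - X.mean(axis=0)
    cov = np.cov(Xc, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, int(np.argmax(evals))]
    if axis[1] < 0:  # maintenance-pole sign convention
        axis = -axis
    corr = float(stats.pearsonr(X[:, 0], X[:, 1]).statistic)
    return ProjectionResult(projection=Xc @ axis, axis=axis, score_correlation=corr)
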