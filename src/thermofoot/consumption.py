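"""Host-consumption conversion constants and variance decomposition.

Dish-level assays record fecundity (hatched eggs), survival to pupation,
mean adult mass and host mass lost. The per-temperature conversion
constant ``C_m`` (host mass consumed per unit beetle mass produced) is the
slope of a regression of corrected host loss on beetle mass produced,
through the origin by default (a dish producing no beetle mass consumes
essentially nothing); a with-intercept variant is available behind a flag.
``C_E`` (host mass per laid egg) is a pooled ratio estimator. A nested OLS
sequence quantifies how much consumption variance the life-history traits
explain.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ConfigurationError, InvalidInputError, UndefinedStatisticError

log = logging.getLogger(__name__)

ASSAY_COLUMNS = [
    "dish_id",
    "line_id",
    "regime",
    "assay_temp_C",
    "eggs",
    "survivors",
    "mean_adult_mass",
    "host_loss_raw",
]
CONTROL_COLUMNS = ["assay_temp_C", "host_loss"]


@dataclass(frozen=True)
class CmEstimate:
    slope: float
    se: float
    n: int
    through_origin: bool


def control_correct(assays: pd.DataFrame, controls: pd.DataFrame) -> pd.DataFrame:
    """Subtract the temperature-matched mean control host loss from each dish.

    Negative corrected values are floored at zero; the number of floored
    dishes is logged. A missing control temperature raises
    :class:`ConfigurationError`.
    """
    out = assays.copy()
    ctrl_means = controls.groupby("assay_temp_C")["host_loss"].mean()
    missing = set(out["assay_temp_C"].unique()) - set(ctrl_means.index)
    if missing:
        raise ConfigurationError(f"no control assays for temperature(s): {sorted(missing)}")
    corr = out["host_loss_raw"] - out["assay_temp_C"].map(ctrl_means)
    n_neg = int((corr < 0).sum())
    if n_neg:
        log.info("floored %d negative corrected host-loss values at 0", n_neg)
    out["host_loss_corrected"] = corr.clip(lower=0.0)
    return out


def beetle_mass_produced(assays: pd.DataFrame) -> pd.Series:
    """Cumulative beetle mass per dish: survivors x mean adult mass."""
    return assays["survivors"] * assays["mean_adult_mass"]


def estimate_Cm(assays: pd.DataFrame, through_origin: bool = True) -> CmEstimate:
    """Conversion constant C_m for dishes at a single assay temperature.

    Least-squares slope of corrected host loss on beetle mass produced.
    Through-origin by default; ``through_origin=False`` adds an intercept
    and returns the slope on beetle mass.
    """
    x = beetle_mass_produced(assays).to_numpy(dtype=float)
    y = assays["host_loss_corrected"].to_numpy(dtype=float)
    if (x > 0).sum() < 3:
        raise InvalidInputError("need >= 3 dishes with positive beetle mass")
    if np.all(x == 0):
        raise UndefinedStatisticError("all-zero predictor: slope undefined")
    X = x[:, None] if through_origin else sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    slope_idx = 0 if through_origin else 1
    return CmEstimate(
        slope=float(fit.params[slope_idx]),
        se=float(fit.bse[slope_idx]),
        n=int(x.size),
        through_origin=through_origin,
    )


def estimate_Cm_by_temperature(
    assays: pd.DataFrame, through_origin: bool = True
) -> dict[float, CmEstimate]:
    """C_m estimated separately at each assay temperature."""
    return {
        float(t): estimate_Cm(grp, through_origin)
        for t, grp in assays.groupby("assay_temp_C")
    }


def estimate_CE(assays: pd.DataFrame) -> float:
    """Pooled host mass consumed per laid egg: sum(loss) / sum(eggs)."""
    eggs = float(assays["eggs"].sum())
    if eggs <= 0:
        raise UndefinedStatisticError("zero total eggs: C_E undefined")
    return float(assays["host_loss_corrected"].sum()) / eggs


def estimate_CE_by_temperature(assays: pd.DataFrame) -> dict[float, float]:
    return {float(t): estimate_CE(grp) for t, grp in assays.groupby("assay_temp_C")}


def lifehistory_variance_explained(assays: pd.DataFrame) -> np.ndarray:
    """R^2 of nested OLS models of corrected host loss.

    Predictor sets: (1) eggs; (2) eggs + survivors; (3) eggs + survivors +
    mean adult mass (main effects only). The sequence is non-decreasing.
    """
    if len(assays) < 10:
        raise InvalidInputError("need >= 10 dishes")
    y = assays["host_loss_corrected"].to_numpy(dtype=float)
    preds = [
        ["eggs"],
        ["eggs", "survivors"],
        ["eggs", "survivors", "mean_adult_mass"],
    ]
    r2 = []
    for cols in preds:
        X = sm.add_constant(assays[cols].to_numpy(dtype=float))
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise UndefinedStatisticError("rank-deficient design matrix")
        r2.append(float(sm.OLS(y, X).fit().rsquared))
    out = np.array(r2)
    # monotone by construction of nested OLS; tolerate fp jitter
    assert np.all(np.diff(out) >= -1e-12)
    return out
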