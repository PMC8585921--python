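"""Predator-diet calibration: predicting abundance indices from seabird diets.

Common murre provision their chicks with whichever forage fish dominates the
surrounding ecosystem, so the mean proportion of a prey group in chick diet
tracks that prey's relative abundance.  Fitting an ordinary least-squares
regression of the trawl-based log abundance index on the diet proportion
over well-sampled years turns an uninterrupted colony-based diet series into
an independent predictor of the index — with prediction intervals — for
years when the trawl survey is curtailed.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .delta_glm import IndexSeries

__all__ = [
    "CalibrationModel",
    "IndexPrediction",
    "IntervalEstimate",
    "AgreementReport",
    "fit_calibration",
    "predict_index",
    "assess_agreement",
    "permutation_p_value",
    "trawl_interval",
]

MIN_PAIRED_YEARS = 10


@dataclass
class IndexPrediction:
    """Point prediction of a log abundance index with a 95% interval."""

    prey_group: str
    proportion: float
    point: float
    lo95: float
    hi95: float
    interval_kind: str  # "prediction" or "confidence"
    extrapolated: bool
    scale: str = "log_index"


@dataclass
class IntervalEstimate:
    """A point estimate with a 95% interval on a declared scale."""

    point: float
    lo95: float
    hi95: float
    scale: str = "log_index"


@dataclass
class AgreementReport:
    """Agreement between a diet-based prediction and a trawl-based estimate."""

    discrepancy: float          # prediction point minus trawl point
    intervals_overlap: bool
    pred_in_trawl_interval: bool
    trawl_in_pred_interval: bool

    @property
    def agree(self) -> bool:
        """Mutual interval containment of the two point estimates."""
        return self.pred_in_trawl_interval and self.trawl_in_pred_interval


@dataclass
class CalibrationModel:
    """OLS fit of log abundance index on diet proportion for one prey group."""

    prey_group: str
    slope: float
    intercept: float
    residual_se: float
    r_squared: float
    p_value: float
    training_years: tuple[int, ...]
    result: object
    train_proportions: np.ndarray
    train_log_index: np.ndarray

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.residual_se) or np.var(self.train_proportions) == 0


def fit_calibration(
    diet: pd.DataFrame,
    index: IndexSeries,
    prey_group: str,
    years: Iterable[int] | None = None,
) -> CalibrationModel:
    """Regress the log abundance index on the chick-diet proportion.

    Pairs years present in both series (optionally restricted to ``years``,
    e.g. a later start when early index years are not comparable).  Requires
    at least 10 paired years and non-constant proportions.
    """
    d = diet[diet["prey_group"] == prey_group][["year", "mean_proportion"]]
    idx = index.table[["log_index"]].reset_index()
    pairs = d.merge(idx, on="year", how="inner")
    if years is not None:
        pairs = pairs[pairs["year"].isin(set(years))]
    pairs = pairs.dropna(subset=["mean_proportion", "log_index"]).sort_values("year")
    if len(pairs) < MIN_PAIRED_YEARS:
        raise ValueError(
            f"{prey_group}: need >= {MIN_PAIRED_YEARS} paired years, got {len(pairs)}")
    if np.isclose(pairs["mean_proportion"].var(ddof=0), 0.0):
        raise ValueError(f"{prey_group}: zero variance in diet proportions")

    res = smf.ols("log_index ~ mean_proportion", data=pairs).fit()
    return CalibrationModel(
        prey_group=prey_group,
        slope=float(res.params["mean_proportion"]),
        intercept=float(res.params["Intercept"]),
        residual_se=float(np.sqrt(res.mse_resid)),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues["mean_proportion"]),
        training_years=tuple(int(y) for y in pairs["year"]),
        result=res,
        train_proportions=pairs["mean_proportion"].to_numpy(),
        train_log_index=pairs["log_index"].to_numpy(),
    )


def predict_index(
    model: CalibrationModel,
    proportion: float,
    interval: str = "prediction",
    alpha: float = 0.05,
) -> IndexPrediction:
    """Predict the log index from a new diet proportion with a 95% band.

    ``interval="prediction"`` accounts for both coefficient and residual
    uncertainty (the right band for predicting a new year's index);
    ``interval="confidence"`` is the narrower band on the fitted line.
    Flags extrapolation when the proportion lies outside the training range.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must lie in [0, 1]")
    if model.degenerate:
        raise ValueError(f"{model.prey_group}: degenerate calibration model")
    if interval not in ("prediction", "confidence"):
        raise ValueError(f"unknown interval kind {interval!r}")
    pred = model.result.get_prediction(pd.DataFrame({"mean_proportion": [proportion]}))
    sf = pred.summary_frame(alpha=alpha)
    lo_col, hi_col = (("obs_ci_lower", "obs_ci_upper") if interval == "prediction"
                      else ("mean_ci_lower", "mean_ci_upper"))
    return IndexPrediction(
        prey_group=model.prey_group,
        proportion=float(proportion),
        point=float(sf["mean"].iloc[0]),
        lo95=float(sf[lo_col].iloc[0]),
        hi95=float(sf[hi_col].iloc[0]),
        interval_kind=interval,
        extrapolated=bool(proportion < model.train_proportions.min()
                          or proportion > model.train_proportions.max()),
    )


def permutation_p_value(
    proportions: np.ndarray,
    log_index: np.ndarray,
    n_permutations: int = 500,
    seed: int = 0,
) -> float:
    """Permutation p-value for the diet-index association.

    Two-sided test of the absolute Pearson correlation under random
    reassignment of index years to diet years (distribution-free check of
    the OLS slope test).
    """
    x = np.asarray(proportions, float)
    y = np.asarray(log_index, float)
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / x.std(ddof=0)
    yc = (y - y.mean()) / y.std(ddof=0)
    obs = abs(np.mean(xc * yc))
    perms = np.stack([rng.permutation(yc) for _ in range(n_permutations)])
    null = np.abs(perms @ xc / len(xc))
    return float((1 + np.sum(null >= obs)) / (1 + n_permutations))


def trawl_interval(index: IndexSeries, year: int) -> IntervalEstimate:
    """The trawl-based estimate for one year on the log(x+1) scale."""
    row = index.table.loc[year]
    return IntervalEstimate(
        point=float(row["log_index"]),
        lo95=float(np.log1p(row["lo95"])),
        hi95=float(np.log1p(row["hi95"])),
        scale="log_index",
    )


def assess_agreement(
    prediction: IndexPrediction | IntervalEstimate,
    trawl: IntervalEstimate,
) -> AgreementReport:
    """Compare a diet-based prediction with a trawl-based interval estimate.

    Both must be on the same (log) scale.  Reports the signed discrepancy,
    whether the intervals overlap, and whether each point estimate lies
    inside the other's interval (mutual containment = agreement).
    """
    if getattr(prediction, "scale", "log_index") != trawl.scale:
        raise ValueError(
            f"scale mismatch: {prediction.scale!r} vs {trawl.scale!r}")
    return AgreementReport(
        discrepancy=float(prediction.point - trawl.point),
        intervals_overlap=bool(prediction.lo95 <= trawl.hi95
                               and trawl.lo95 <= prediction.hi95),
        pred_in_trawl_interval=bool(trawl.lo95 <= prediction.point <= trawl.hi95),
        trawl_in_pred_interval=bool(prediction.lo95 <= trawl.point <= prediction.hi95),
    )
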