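"""Survey effort-reduction machinery: focal-year subsetting, relative bias,
SE-versus-n scaling, and random-exclusion validation experiments.

The central question: if a survey year is sampled with a fraction of the
usual effort (and at a spatially biased subset of stations), how wrong and
how uncertain do the annual abundance indices become?  Bias is quantified by
recomputing each focal year's index from the reduced station subset and
comparing to the all-haul estimate as (x_sub - x_all)/x_all.  Precision is
extrapolated with the standard scaling relationship SE = SD/sqrt(n) and
validated by randomly excluding hauls and recomputing the SE.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import delta_glm
from .delta_glm import IndexSeries

__all__ = [
    "PrecisionCurve",
    "subset_focal_year",
    "run_bias_simulation",
    "summarize_bias",
    "se_extrapolation",
    "se_percent_change",
    "random_exclusion_experiment",
    "DEFAULT_N_GRID",
]

logger = logging.getLogger(__name__)

#: Default haul-count grid spanning the effort levels of interest.
DEFAULT_N_GRID = (10, 15, 20, 30, 40, 62, 90, 120)


def subset_focal_year(
    hauls: pd.DataFrame,
    focal_year: int,
    station_subset: Sequence[str],
) -> pd.DataFrame:
    """Reduce one year to (at most) the last haul at each subset station.

    All other years are untouched.  "Last" is resolved by (julian_day,
    haul_id) lexicographic order.  Subset stations not visited in the focal
    year contribute nothing.  Deterministic and idempotent.
    """
    if focal_year not in set(hauls["year"]):
        raise ValueError(f"focal year {focal_year} not present in haul table")
    focal = hauls[hauls["year"] == focal_year]
    keep = focal[focal["station_id"].isin(set(station_subset))]
    if keep.empty:
        raise ValueError(
            f"no focal-year haul at any subset station in {focal_year}")
    last = (keep.sort_values(["julian_day", "haul_id"])
                .groupby("station_id", sort=False).tail(1))
    out = pd.concat([hauls[hauls["year"] != focal_year], last])
    return out.sort_values(["year", "haul_id"]).reset_index(drop=True)


def _model_index(hauls, stations, taxon, candidate_covariates, seasonal):
    fit = delta_glm.fit_delta_glm(
        hauls, stations, taxon,
        candidate_covariates=candidate_covariates, seasonal=seasonal)
    return delta_glm.compute_index(fit)


def run_bias_simulation(
    hauls: pd.DataFrame,
    stations: pd.DataFrame,
    taxa: Sequence[str],
    focal_years: Sequence[int] | None = None,
    estimators: Sequence[str] = ("naive", "model_based"),
    station_subset: Sequence[str] | None = None,
    candidate_covariates: Sequence[tuple[str, ...]] | None = None,
    seasonal: Mapping[str, bool] | None = None,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Relative bias of reduced-effort indices across past focal years.

    For each focal year x taxon x estimator, the focal year's hauls are
    reduced to the last haul at each subset station (default: the flagged
    reduced-year stations) and the index is recomputed — the model-based
    refit keeps complete data for all other years — giving
    relative_bias = (x_sub - x_all)/x_all.  The naive estimator's point
    estimate is its mean-log(CPUE+1) index; the model-based estimator uses
    the arithmetic-scale MLE index (``log_scale=True`` switches both to the
    log(x+1) scale).  Cells with x_all = 0 are flagged (relative bias
    undefined); per-cell fit errors are logged and skipped.
    """
    seasonal = dict(seasonal or {})
    if station_subset is None:
        station_subset = stations.loc[stations["reduced_year_flag"], "station_id"].tolist()
    if focal_years is None:
        focal_years = sorted(hauls["year"].unique().tolist())

    def _point(series: IndexSeries, year: int, estimator: str) -> float:
        row = series.table.loc[year]
        if estimator == "naive" or log_scale:
            return float(row["log_index"])
        return float(row["point_index"])

    full_series: dict[tuple[str, str], IndexSeries] = {}
    for taxon in taxa:
        full_series[("naive", taxon)] = delta_glm.naive_index(hauls, taxon)
        if "model_based" in estimators:
            full_series[("model_based", taxon)] = _model_index(
                hauls, stations, taxon, candidate_covariates, seasonal.get(taxon, False))

    rows = []
    for focal in focal_years:
        try:
            sub = subset_focal_year(hauls, focal, station_subset)
        except ValueError as exc:
            logger.warning("focal year %s skipped: %s", focal, exc)
            continue
        for taxon in taxa:
            for estimator in estimators:
                try:
                    if estimator == "naive":
                        series = delta_glm.naive_index(sub[sub["year"] == focal], taxon)
                    elif estimator == "model_based":
                        series = _model_index(sub, stations, taxon,
                                              candidate_covariates,
                                              seasonal.get(taxon, False))
                    else:
                        raise ValueError(f"unknown estimator {estimator!r}")
                    x_sub = _point(series, focal, estimator)
                    x_all = _point(full_series[(estimator, taxon)], focal, estimator)
                except Exception as exc:  # keep going over remaining cells
                    logger.warning("bias cell (%s, %s, %s) failed: %s",
                                   focal, taxon, estimator, exc)
                    continue
                if x_all == 0:
                    logger.warning("x_all = 0 for (%s, %s, %s); bias undefined",
                                   focal, taxon, estimator)
                    rel = np.nan
                else:
                    rel = (x_sub - x_all) / x_all
                rows.append(
                    {"taxon": taxon, "year": focal, "estimator": estimator,
                     "x_sub": x_sub, "x_all": x_all, "relative_bias": rel}
                )
    return pd.DataFrame(rows)


def summarize_bias(results: pd.DataFrame) -> pd.DataFrame:
    """Boxplot-style summary per taxon x estimator: median, quartiles,
    1.5xIQR whiskers, and the count of dropped (undefined) cells."""
    out = []
    for (taxon, estimator), g in results.groupby(["taxon", "estimator"]):
        vals = g["relative_bias"].dropna().to_numpy()
        n_dropped = int(g["relative_bias"].isna().sum())
        if len(vals) == 0:
            continue
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        iqr = q3 - q1
        lo = vals[vals >= q1 - 1.5 * iqr].min()
        hi = vals[vals <= q3 + 1.5 * iqr].max()
        out.append(
            {"taxon": taxon, "estimator": estimator, "n": len(vals),
             "n_dropped": n_dropped, "median": med, "q1": q1, "q3": q3,
             "whisker_lo": lo, "whisker_hi": hi}
        )
    return pd.DataFrame(out)


@dataclass
class PrecisionCurve:
    """SE-versus-sample-size curve for one taxon-year under SE = SD/sqrt(n)."""

    taxon: str
    year: int
    n_obs: int
    se_obs: float
    sd_implied: float
    n_grid: tuple[int, ...]
    mean_log_index: float

    def predicted_se(self, n) -> np.ndarray | float:
        n = np.asarray(n, dtype=float)
        if np.any(n <= 0):
            raise ValueError("sample size must be > 0")
        return self.sd_implied / np.sqrt(n)

    @property
    def table(self) -> pd.DataFrame:
        n = np.asarray(self.n_grid, dtype=float)
        return pd.DataFrame(
            {
                "n": self.n_grid,
                "predicted_se": self.predicted_se(n),
                "pct_change_vs_obs": 100.0 * (np.sqrt(self.n_obs / n) - 1.0),
            }
        )


def se_extrapolation(
    index: IndexSeries,
    year: int,
    n_grid: Sequence[int] = DEFAULT_N_GRID,
) -> PrecisionCurve:
    """Extrapolate a year's observed SE to other sample sizes via SD/sqrt(n)."""
    row = index.table.loc[year]
    se_obs = float(row["se_log"])
    n_obs = int(row["n_hauls"])
    if not np.isfinite(se_obs) or n_obs <= 0:
        raise ValueError(f"se_log/n_hauls unavailable for year {year}")
    return PrecisionCurve(
        taxon=index.taxon, year=year, n_obs=n_obs, se_obs=se_obs,
        sd_implied=se_obs * np.sqrt(n_obs), n_grid=tuple(int(n) for n in n_grid),
        mean_log_index=float(row["log_index"]),
    )


def se_percent_change(n_from: float, n_to: float) -> float:
    """Percent change in SE when effort moves from ``n_from`` to ``n_to`` hauls
    under SE = SD/sqrt(n); positive means a larger error."""
    if n_from <= 0 or n_to <= 0:
        raise ValueError("sample sizes must be > 0")
    return 100.0 * (np.sqrt(n_from / n_to) - 1.0)


def _draw_subset(focal: pd.DataFrame, n: int, mode: str,
                 rng: np.random.Generator) -> pd.DataFrame:
    if mode == "purely_random":
        idx = rng.choice(focal.index.to_numpy(), size=n, replace=False)
        return focal.loc[idx]
    if mode == "consecutive_nights":
        nights = focal["night_id"].unique()
        rng.shuffle(nights)
        chosen: list[pd.DataFrame] = []
        total = 0
        for night in nights:
            g = focal[focal["night_id"] == night].sort_values("haul_id")
            take = min(len(g), n - total)
            chosen.append(g.head(take))
            total += take
            if total >= n:
                break
        if total < n:
            raise ValueError(f"not enough nights to assemble {n} hauls")
        return pd.concat(chosen)
    raise ValueError(f"unknown exclusion mode {mode!r}")


def random_exclusion_experiment(
    hauls: pd.DataFrame,
    stations: pd.DataFrame,
    focal_year: int,
    taxon: str,
    n_list: Sequence[int],
    mode: str = "purely_random",
    reps: int = 30,
    seed: int = 0,
    covariates: tuple[str, ...] = (),
    n_draws: int = 400,
) -> pd.DataFrame:
    """Recompute the focal year's SE after random exclusion down to n hauls.

    Per (n, rep): keep n focal-year hauls — chosen purely at random, or as
    consecutive hauls from randomly selected nights — refit the delta-GLM
    (fixed ``covariates``), and record the focal year's se_log from the
    normal-approximation posterior.  Returns one row per (mode, n, rep) plus
    the SD/sqrt(n) prediction anchored at the full-effort SE.
    """
    if reps < 20:
        raise ValueError("reps must be >= 20")
    focal = hauls[hauls["year"] == focal_year]
    n_full = len(focal)
    if any(n > n_full for n in n_list):
        raise ValueError(f"n_list values must be <= {n_full} hauls in {focal_year}")
    rng = np.random.default_rng(seed)
    others = hauls[hauls["year"] != focal_year]

    def _se(table: pd.DataFrame, sub_seed: int) -> float:
        fit = delta_glm.fit_delta_glm(table, stations, taxon,
                                      candidate_covariates=[covariates])
        series = delta_glm.estimate_uncertainty(
            fit, method="posterior", n_draws=n_draws, seed=sub_seed)
        return float(series.table.loc[focal_year, "se_log"])

    se_full = _se(hauls, int(rng.integers(2 ** 31)))
    rows = []
    for n in n_list:
        for rep in range(reps):
            if n == n_full:
                sub = focal
            else:
                sub = _draw_subset(focal, int(n), mode, rng)
            se = _se(pd.concat([others, sub], ignore_index=True),
                     int(rng.integers(2 ** 31)))
            rows.append(
                {"mode": mode, "n": int(n), "rep": rep, "se_log": se,
                 "predicted_se": se_full * np.sqrt(n_full / n)}
            )
    return pd.DataFrame(rows)
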