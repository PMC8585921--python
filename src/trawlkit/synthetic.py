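"""Synthetic survey scenario generators with known ground truth.

Emulates the statistical structure of an annual mid-water trawl survey over a
stratified core-area station grid: ~62 hauls per year across shelf/slope/deep
strata, zero-inflated lognormal catches with taxon-specific nearshore or
offshore depth associations, a degraded final year sampled only at a
15-station inshore-biased subset, chick-diet proportions linearly linked to
the log abundance index, and smooth environmental response surfaces for two
krill-like species (one neritic, one offshore).  Every generator is
deterministic for a fixed seed, and every generative parameter is recoverable
by the downstream estimators, so bias and coverage are testable end to end.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .delta_glm import IndexSeries

__all__ = [
    "TaxonParams",
    "KrillSpeciesResponse",
    "EnvGrid",
    "make_design",
    "simulate_hauls",
    "simulate_diet",
    "simulate_calibration_pairs",
    "simulate_env_and_krill",
    "default_taxa",
    "true_index",
    "DEFAULT_STRATA",
]

STRATA = ("shelf", "slope", "deep")
#: Depth-stratum score multiplying ``depth_association``; positive = nearshore.
DEPTH_SCORE = {"shelf": 1.0, "slope": 0.0, "deep": -1.0}
DEFAULT_STRATA = {"shelf": 0.5, "slope": 0.3, "deep": 0.2}
REGIONS = ("north", "central", "south")
SEASON_WINDOW = (121, 180)        # May-June analogue
REDUCED_SEASON_WINDOW = (160, 177)  # late, pandemic-year analogue
SEASON_CENTER = 150
N_REDUCED_STATIONS = 15

_DEPTH_RANGE = {"shelf": (30.0, 180.0), "slope": (200.0, 1400.0), "deep": (1500.0, 3000.0)}
_DIST_RANGE = {"shelf": (3.0, 25.0), "slope": (20.0, 70.0), "deep": (60.0, 140.0)}


@dataclass
class TaxonParams:
    """Generative parameters of one taxon's hurdle catch process.

    ``year_effects`` holds the true log abundance lambda_y of the positive
    catch; ``occurrence_intercept`` is on the logit scale; ``depth_association``
    shifts both the occurrence logit and the positive log mean by +1x on the
    shelf and -1x in deep water (positive = nearshore affinity);
    ``seasonal_slope`` is a per-day log-abundance trend (rockfish-like taxa).
    ``patchiness_cv`` adds a station-by-year lognormal swarm factor with that
    coefficient of variation on top of the haul-level ``sigma_log``.
    """

    taxon: str
    year_effects: dict[int, float]
    occurrence_intercept: float = 1.4
    depth_association: float = 0.0
    region_effects: dict[str, float] = field(default_factory=dict)
    sigma_log: float = 0.7
    patchiness_cv: float = 0.0
    seasonal_slope: float = 0.0

    def validate(self) -> None:
        if self.sigma_log <= 0:
            raise ValueError(f"{self.taxon}: sigma_log must be > 0")
        if self.patchiness_cv < 0:
            raise ValueError(f"{self.taxon}: patchiness_cv must be >= 0")
        vals = np.asarray(list(self.year_effects.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{self.taxon}: year_effects must be finite")


def make_design(
    n_stations: int = 35,
    strata_spec: Mapping[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Lay out a core-area station grid with an inshore-biased reduced subset.

    Stations are allocated to shelf/slope/deep strata by the given
    proportions (largest-remainder rounding), given stratum-typical bottom
    depths and shore distances, and spread round-robin over three alongshore
    regions.  The 15 shallowest stations are flagged as the reduced-year
    subset, so flagged stations are inshore-biased by construction.
    """
    if n_stations < N_REDUCED_STATIONS:
        raise ValueError(
            f"n_stations must be >= {N_REDUCED_STATIONS} to host a reduced-year scenario")
    strata = dict(strata_spec if strata_spec is not None else DEFAULT_STRATA)
    total = sum(strata.values())
    if not np.isclose(total, 1.0):
        raise ValueError(f"strata proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)

    raw = {s: n_stations * p for s, p in strata.items()}
    counts = {s: int(np.floor(v)) for s, v in raw.items()}
    for s in sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True):
        if sum(counts.values()) == n_stations:
            break
        counts[s] += 1

    rows = []
    i = 0
    for stratum in STRATA:
        for _ in range(counts.get(stratum, 0)):
            dlo, dhi = _DEPTH_RANGE[stratum]
            klo, khi = _DIST_RANGE[stratum]
            rows.append(
                {
                    "station_id": f"S{i + 1:03d}",
                    "region": REGIONS[i % len(REGIONS)],
                    "depth_stratum": stratum,
                    "bottom_depth_m": float(rng.uniform(dlo, dhi)),
                    "distance_to_shore_km": float(rng.uniform(klo, khi)),
                }
            )
            i += 1
    design = pd.DataFrame(rows)
    flagged = design["bottom_depth_m"].nsmallest(N_REDUCED_STATIONS).index
    design["reduced_year_flag"] = False
    design.loc[flagged, "reduced_year_flag"] = True
    return design


def _taxon_station_effects(taxon: TaxonParams, design: pd.DataFrame) -> np.ndarray:
    score = design["depth_stratum"].map(DEPTH_SCORE).to_numpy()
    reg = design["region"].map(lambda r: taxon.region_effects.get(r, 0.0)).to_numpy()
    return taxon.depth_association * score + reg


def simulate_hauls(
    design: pd.DataFrame,
    taxa: Sequence[TaxonParams],
    years: Sequence[int],
    hauls_per_year: int = 62,
    reduced_years: Iterable[int] = (),
    seed: int = 0,
    integer_counts: bool = True,
    hauls_per_night: int = 3,
) -> pd.DataFrame:
    """Simulate haul-level catches from the hurdle generative model.

    Normal years get ``hauls_per_year`` hauls spread round-robin over the
    station grid within the May-June season window; reduced years get exactly
    one haul at each flagged station, later in the season.  Hauls are grouped
    ~``hauls_per_night`` per night (a night shares one Julian day).  Per taxon
    and haul, catch = Bernoulli(occurrence) x LogNormal(lambda_y + covariate
    effects, sigma_log), rounded to integer counts unless
    ``integer_counts=False`` (rounding keeps the hurdle interpretation: a
    rounded-to-zero haul is a zero).
    """
    if hauls_per_year < 1:
        raise ValueError("hauls_per_year must be >= 1")
    years = list(years)
    reduced_years = set(reduced_years)
    if not reduced_years <= set(years):
        raise ValueError("reduced_years must be a subset of years")
    for t in taxa:
        t.validate()
        missing = [y for y in years if y not in t.year_effects]
        if missing:
            raise ValueError(f"{t.taxon}: year_effects missing for years {missing}")
    if reduced_years and not design["reduced_year_flag"].any():
        raise ValueError("design has no reduced-year stations flagged")

    rng = np.random.default_rng(seed)
    flagged = design[design["reduced_year_flag"]]
    effects = {t.taxon: dict(zip(design["station_id"], _taxon_station_effects(t, design)))
               for t in taxa}
    logits = {t.taxon: dict(zip(design["station_id"],
                                t.occurrence_intercept + _taxon_station_effects(t, design)))
              for t in taxa}

    frames = []
    for year in years:
        if year in reduced_years:
            station_seq = flagged["station_id"].tolist()
            window = REDUCED_SEASON_WINDOW
        else:
            ids = design["station_id"].to_numpy()
            reps = int(np.ceil(hauls_per_year / len(ids)))
            seq = np.concatenate([rng.permutation(ids) for _ in range(reps)])
            station_seq = seq[:hauls_per_year].tolist()
            window = SEASON_WINDOW
        n = len(station_seq)
        n_nights = int(np.ceil(n / hauls_per_night))
        night_days = np.sort(rng.integers(window[0], window[1] + 1, size=n_nights))
        night_idx = np.repeat(np.arange(n_nights), hauls_per_night)[:n]
        frame = pd.DataFrame(
            {
                "haul_id": [f"{year}-{k + 1:03d}" for k in range(n)],
                "year": year,
                "julian_day": night_days[night_idx],
                "night_id": [f"{year}-N{j + 1:02d}" for j in night_idx],
                "station_id": station_seq,
            }
        )
        for t in taxa:
            eff = frame["station_id"].map(effects[t.taxon]).to_numpy()
            logit = frame["station_id"].map(logits[t.taxon]).to_numpy()
            occurred = rng.random(n) < expit(logit)
            mu = (t.year_effects[year] + eff
                  + t.seasonal_slope * (frame["julian_day"].to_numpy() - SEASON_CENTER))
            if t.patchiness_cv > 0:
                sd_sw = float(np.sqrt(np.log(1.0 + t.patchiness_cv ** 2)))
                swarm = {s: rng.normal(-0.5 * sd_sw ** 2, sd_sw)
                         for s in pd.unique(frame["station_id"])}
                mu = mu + frame["station_id"].map(swarm).to_numpy()
            catch = np.where(occurred, np.exp(rng.normal(mu, t.sigma_log)), 0.0)
            if integer_counts:
                catch = np.round(catch)
            frame[f"cpue_{t.taxon}"] = catch
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def true_index(taxon: TaxonParams, design: pd.DataFrame, years: Sequence[int]) -> IndexSeries:
    """Generative analogue of the standardized index: p-bar_y x m-bar_y.

    Averages occurrence probability and exp(positive log mean) over the
    station grid (the effort distribution of a balanced year), matching the
    estimand of the effort-standardized delta-GLM index.
    """
    eff = _taxon_station_effects(taxon, design)
    p_bar = float(np.mean(expit(taxon.occurrence_intercept + eff)))
    x = {y: p_bar * float(np.mean(np.exp(taxon.year_effects[y] + eff))) for y in years}
    log_index = np.log1p(pd.Series(x).sort_index())
    return IndexSeries.from_log_index(taxon.taxon, log_index.index, log_index.to_numpy())


def default_taxa(years: Sequence[int], seed: int = 0,
                 mean_log: float = 3.0, year_sd: float = 0.7) -> list[TaxonParams]:
    """Four-taxon default scenario spanning the habitat-association spectrum.

    A nearshore anchovy-like taxon, an offshore hake-like taxon, a neutral
    sanddab-like taxon, and a seasonal rockfish-like taxon (mild nearshore
    affinity, declining availability late in the season).  True log-abundance
    year effects are iid N(mean_log, year_sd) per taxon.
    """
    rng = np.random.default_rng(seed)
    specs = [
        ("anchovy_like", 1.2, 0.0, 1.4),
        ("hake_like", -1.2, 0.0, 1.4),
        ("sanddab_like", 0.0, 0.0, 1.4),
        ("rockfish_like", 0.6, -0.02, 1.2),
    ]
    taxa = []
    for name, assoc, slope, occ in specs:
        lam = {int(y): float(v) for y, v in
               zip(years, rng.normal(mean_log, year_sd, size=len(list(years))))}
        taxa.append(TaxonParams(
            taxon=name, year_effects=lam, occurrence_intercept=occ,
            depth_association=assoc, sigma_log=0.7, seasonal_slope=slope))
    return taxa


def simulate_diet(
    index: IndexSeries,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
    prey_group: str = "prey",
    n_obs: int = 300,
) -> pd.DataFrame:
    """Chick-diet proportions linearly linked to the log abundance index.

    proportion_y = clamp_[0,1](intercept + slope * log_index_y + N(0, noise_sd)).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if len(index.table) == 0:
        raise ValueError("index series is empty")
    rng = np.random.default_rng(seed)
    log_index = index.table["log_index"].to_numpy()
    prop = intercept + slope * log_index + rng.normal(0.0, noise_sd, size=len(log_index))
    return pd.DataFrame(
        {
            "year": index.table.index.to_numpy(),
            "prey_group": prey_group,
            "mean_proportion": np.clip(prop, 0.0, 1.0),
            "n_obs": n_obs,
        }
    )


def simulate_calibration_pairs(
    n_years: int,
    slope: float,
    intercept: float,
    noise_sd: float,
    seed: int = 0,
    prey_group: str = "prey",
    start_year: int = 1990,
    prop_range: tuple[float, float] = (0.05, 0.95),
) -> tuple[pd.DataFrame, IndexSeries]:
    """Paired diet/index years with truth in the calibration direction.

    Proportions are uniform on ``prop_range`` and
    log_index = intercept + slope * proportion + N(0, noise_sd), i.e. the
    direction the calibration regression fits, so slope recovery and interval
    coverage have a defined generative truth.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(start_year, start_year + n_years)
    prop = rng.uniform(*prop_range, size=n_years)
    log_index = intercept + slope * prop + rng.normal(0.0, noise_sd, size=n_years)
    diet = pd.DataFrame(
        {"year": years, "prey_group": prey_group, "mean_proportion": prop, "n_obs": 300})
    index = IndexSeries.from_log_index(prey_group, years, log_index)
    return diet, index


# ---------------------------------------------------------------------------
# Environmental grid and krill-like species


@dataclass
class EnvGrid:
    """Gridded environmental covariates: static cell geometry + dynamic fields.

    ``cells``: one row per cell (cell_id, latitude, longitude, depth_m,
    distance_to_shore_km).  ``dynamic``: long format (cell_id, year,
    covariate, value).
    """

    cells: pd.DataFrame
    dynamic: pd.DataFrame

    @property
    def static_covariates(self) -> list[str]:
        return ["depth_m", "distance_to_shore_km"]

    @property
    def dynamic_covariates(self) -> list[str]:
        return sorted(self.dynamic["covariate"].unique().tolist())

    @property
    def years(self) -> list[int]:
        return sorted(self.dynamic["year"].unique().tolist())

    def frame(self, years: Iterable[int] | None = None) -> pd.DataFrame:
        """Wide covariate frame, one row per cell x year."""
        wide = self.dynamic.pivot_table(
            index=["cell_id", "year"], columns="covariate", values="value").reset_index()
        wide.columns.name = None
        if years is not None:
            years = set(years)
            missing = years - set(self.years)
            if missing:
                raise KeyError(f"dynamic covariates missing for years {sorted(missing)}")
            wide = wide[wide["year"].isin(years)]
        return wide.merge(self.cells, on="cell_id", how="left")


@dataclass
class KrillSpeciesResponse:
    """Smooth response surface of a krill-like species on the ln(CPUE+1) scale.

    A Gaussian dome over distance to shore (``peak_km``, ``width_km``,
    ``amplitude``) plus linear responses to the winter-preconditioning and
    spring ocean-state covariates; truth is floored at 0.
    """

    species: str
    peak_km: float
    width_km: float
    amplitude: float
    base: float = 0.2
    winter_coef: float = 0.0
    spring_coef: float = 0.0

    def truth_ln(self, dist_km: np.ndarray, winter: np.ndarray, spring: np.ndarray) -> np.ndarray:
        dome = self.amplitude * np.exp(-0.5 * ((dist_km - self.peak_km) / self.width_km) ** 2)
        return np.maximum(
            0.0, self.base + dome + self.winter_coef * winter + self.spring_coef * spring)


def default_krill_species() -> list[KrillSpeciesResponse]:
    """A neritic species peaking inshore and an offshore outer-slope species."""
    return [
        KrillSpeciesResponse("tspin_like", peak_km=15.0, width_km=18.0,
                             amplitude=2.5, base=0.1, winter_coef=0.6, spring_coef=0.15),
        KrillSpeciesResponse("epac_like", peak_km=75.0, width_km=30.0,
                             amplitude=3.0, base=0.2, winter_coef=0.5, spring_coef=0.25),
    ]


def _make_grid(grid_spec: Mapping | None, rng: np.random.Generator) -> pd.DataFrame:
    spec = dict(grid_spec or {})
    n_across = int(spec.get("n_across", 16))
    n_alongshore = int(spec.get("n_alongshore", 8))
    max_dist = float(spec.get("max_dist_km", 170.0))
    dists = np.linspace(5.0, max_dist, n_across)
    rows = []
    k = 0
    for j in range(n_alongshore):
        lat = 36.0 + 0.25 * j
        for i, d in enumerate(dists):
            depth = 25.0 + 3000.0 * (d / max_dist) ** 1.4
            rows.append(
                {
                    "cell_id": f"C{k + 1:03d}",
                    "latitude": lat,
                    "longitude": -122.0 - d / 90.0,
                    "depth_m": depth,
                    "distance_to_shore_km": float(d),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_env_and_krill(
    grid_spec: Mapping | None = None,
    species_responses: Sequence[KrillSpeciesResponse] | None = None,
    years: Sequence[int] = tuple(range(2002, 2021)),
    station_subset: pd.DataFrame | None = None,
    seed: int = 0,
    patchiness_sd: float = 0.6,
    covariate_year_values: Mapping[str, Mapping[int, float]] | None = None,
) -> tuple[EnvGrid, pd.DataFrame, pd.DataFrame]:
    """Environmental fields, true krill abundance, and station-level samples.

    Two dynamic covariates (``winter_precond``, ``spring_state``) vary by year
    (iid N(0,1), overridable per year via ``covariate_year_values``) with a
    mild static alongshore gradient.  Truth per cell-year is each species'
    response surface evaluated on the covariates; interannual variability
    enters through the dynamic covariates, so a covariate-driven model can
    track it.  Station samples are the truth at each station's cell on the
    CPUE scale times multiplicative mean-1 lognormal patchiness noise.

    Returns ``(env, truth, samples)``: truth long-format (cell_id, year,
    species, ln_truth); samples one row per station x year with cell_id and
    ``cpue_<species>`` columns.
    """
    years = [int(y) for y in years]
    if len(years) < 10:
        raise ValueError("need >= 10 years for a training/holdout split")
    species = list(species_responses if species_responses is not None
                   else default_krill_species())
    rng = np.random.default_rng(seed)
    cells = _make_grid(grid_spec, rng)
    lat_grad = (cells["latitude"] - cells["latitude"].mean()) / max(
        cells["latitude"].std(ddof=0), 1e-12)

    overrides = covariate_year_values or {}
    dyn_rows = []
    year_vals: dict[str, dict[int, float]] = {}
    for cov in ("winter_precond", "spring_state"):
        vals = {y: float(rng.normal()) for y in years}
        vals.update({int(y): float(v) for y, v in overrides.get(cov, {}).items()})
        year_vals[cov] = vals
        for y in years:
            dyn_rows.append(pd.DataFrame(
                {
                    "cell_id": cells["cell_id"],
                    "year": y,
                    "covariate": cov,
                    "value": vals[y] + 0.15 * lat_grad,
                }
            ))
    env = EnvGrid(cells=cells, dynamic=pd.concat(dyn_rows, ignore_index=True))

    wide = env.frame(years)
    truth_frames = []
    for sp in species:
        t = wide[["cell_id", "year"]].copy()
        t["species"] = sp.species
        t["ln_truth"] = sp.truth_ln(
            wide["distance_to_shore_km"].to_numpy(),
            wide["winter_precond"].to_numpy(),
            wide["spring_state"].to_numpy(),
        )
        truth_frames.append(t)
    truth = pd.concat(truth_frames, ignore_index=True)

    # Map stations onto grid cells (nearest cross-shore distance, middle row).
    if station_subset is None:
        mid_lat = sorted(cells["latitude"].unique())[len(cells["latitude"].unique()) // 2]
        band = cells[cells["latitude"] == mid_lat]
        chosen = band[band["distance_to_shore_km"] <= 110.0]
        stations = pd.DataFrame(
            {
                "station_id": [f"K{i + 1:03d}" for i in range(len(chosen))],
                "cell_id": chosen["cell_id"].to_numpy(),
                "distance_to_shore_km": chosen["distance_to_shore_km"].to_numpy(),
            }
        )
    else:
        max_d = cells["distance_to_shore_km"].max()
        if (station_subset["distance_to_shore_km"] > max_d).any():
            raise ValueError("station outside grid extent")
        mid_lat = sorted(cells["latitude"].unique())[len(cells["latitude"].unique()) // 2]
        band = cells[cells["latitude"] == mid_lat].reset_index(drop=True)
        idx = np.abs(band["distance_to_shore_km"].to_numpy()[None, :]
                     - station_subset["distance_to_shore_km"].to_numpy()[:, None]).argmin(axis=1)
        stations = pd.DataFrame(
            {
                "station_id": station_subset["station_id"].to_numpy(),
                "cell_id": band["cell_id"].to_numpy()[idx],
                "distance_to_shore_km": station_subset["distance_to_shore_km"].to_numpy(),
            }
        )

    truth_by = truth.set_index(["species", "cell_id", "year"])["ln_truth"]
    sample_rows = []
    for y in years:
        row = {
            "haul_id": [f"K{y}-{i + 1:03d}" for i in range(len(stations))],
            "year": y,
            "station_id": stations["station_id"].to_numpy(),
            "cell_id": stations["cell_id"].to_numpy(),
        }
        frame = pd.DataFrame(row)
        for sp in species:
            ln_t = truth_by.loc[sp.species].loc[
                list(zip(stations["cell_id"], [y] * len(stations)))].to_numpy()
            cpue_t = np.expm1(ln_t)
            if patchiness_sd > 0:
                noise = np.exp(rng.normal(-0.5 * patchiness_sd ** 2, patchiness_sd,
                                          size=len(stations)))
            else:
                noise = np.ones(len(stations))
            frame[f"cpue_{sp.species}"] = cpue_t * noise
        sample_rows.append(frame)
    samples = pd.concat(sample_rows, ignore_index=True)
    return env, truth, samples
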