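"""CSV readers/writers, scenario configuration, and validation.

All tabular I/O is plain CSV (UTF-8, header row).  The gridded environment
uses long format (cell_id, year, covariate, value) plus a static cell table.
A scenario configuration file (YAML) fully determines a simulation: its
SHA-256 hash is stamped on run logs for provenance.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .delta_glm import IndexSeries
from .synthetic import EnvGrid, TaxonParams

__all__ = [
    "ScenarioConfig",
    "read_haul_table",
    "write_haul_table",
    "read_station_table",
    "write_station_table",
    "read_diet_series",
    "write_diet_series",
    "read_env_grid",
    "write_env_grid",
    "read_index_series",
    "write_index_series",
    "build_scenario",
]

HAUL_REQUIRED = ("haul_id", "year", "julian_day", "night_id", "station_id")
STATION_REQUIRED = ("station_id", "region", "depth_stratum", "bottom_depth_m",
                    "distance_to_shore_km", "reduced_year_flag")
DIET_REQUIRED = ("year", "prey_group", "mean_proportion", "n_obs")
INDEX_COLUMNS = ("taxon", "year", "point_index", "log_index", "se_log",
                 "lo95", "hi95", "z_score", "n_hauls", "flag")


class SchemaError(ValueError):
    """A table is missing required columns or violates validation rules."""


def _require(df: pd.DataFrame, cols, what: str, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: {what} missing required columns {missing}")


def read_haul_table(path) -> pd.DataFrame:
    """Read and validate a haul table; unknown columns are preserved.

    Raises :class:`SchemaError` naming offending rows (1-based data rows)
    for negative CPUE values.
    """
    df = pd.read_csv(path)
    _require(df, HAUL_REQUIRED, "haul table", path)
    cpue_cols = [c for c in df.columns if c.startswith("cpue_")]
    for c in cpue_cols:
        bad = df.index[df[c] < 0]
        if len(bad):
            rows = (bad + 1).tolist()[:10]
            raise SchemaError(f"{path}: negative CPUE in column {c} at rows {rows}")
    return df


def write_haul_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_station_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, STATION_REQUIRED, "station table", path)
    if df["station_id"].duplicated().any():
        dupes = df.loc[df["station_id"].duplicated(), "station_id"].tolist()
        raise SchemaError(f"{path}: duplicate station ids {dupes}")
    df["reduced_year_flag"] = df["reduced_year_flag"].astype(bool)
    return df


def write_station_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_diet_series(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, DIET_REQUIRED, "diet series", path)
    bad = df.index[(df["mean_proportion"] < 0) | (df["mean_proportion"] > 1)]
    if len(bad):
        raise SchemaError(
            f"{path}: diet proportions outside [0, 1] at rows {(bad + 1).tolist()}")
    return df


def write_diet_series(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_env_grid(env: EnvGrid, cells_path, dynamic_path) -> None:
    env.cells.to_csv(cells_path, index=False)
    env.dynamic.to_csv(dynamic_path, index=False)


def read_env_grid(cells_path, dynamic_path) -> EnvGrid:
    cells = pd.read_csv(cells_path)
    _require(cells, ("cell_id", "latitude", "longitude", "depth_m",
                     "distance_to_shore_km"), "env cell table", cells_path)
    dynamic = pd.read_csv(dynamic_path)
    _require(dynamic, ("cell_id", "year", "covariate", "value"),
             "env dynamic table", dynamic_path)
    return EnvGrid(cells=cells, dynamic=dynamic)


def write_index_series(series: IndexSeries, path) -> None:
    tab = series.table.reset_index()
    tab.insert(0, "taxon", series.taxon)
    tab.to_csv(path, index=False)


def read_index_series(path) -> IndexSeries:
    df = pd.read_csv(path)
    _require(df, ("taxon", "year", "point_index", "log_index"), "index series", path)
    taxon = df["taxon"].iloc[0]
    tab = df.drop(columns="taxon").set_index("year")
    if "flag" in tab.columns:
        tab["flag"] = tab["flag"].fillna("")
    return IndexSeries(taxon=taxon, table=tab)


# ---------------------------------------------------------------------------
# Scenario configuration


@dataclass
class ScenarioConfig:
    """Full specification of a synthetic survey scenario.

    Round-trips losslessly through YAML; the config hash fingerprints the
    scenario for provenance stamps on output files.
    """

    seed: int = 0
    design: dict = field(default_factory=lambda: {
        "n_stations": 35, "strata": dict(synthetic.DEFAULT_STRATA)})
    years: dict = field(default_factory=lambda: {"start": 1990, "end": 2020})
    hauls_per_year: int = 62
    reduced_years: list = field(default_factory=lambda: [2020])
    taxa: dict = field(default_factory=dict)
    diet: list = field(default_factory=list)
    index: dict = field(default_factory=lambda: {
        "uncertainty": "bootstrap", "n_draws": 500})
    effort: dict = field(default_factory=lambda: {
        "n_grid": list((10, 15, 20, 30, 40, 62, 90, 120)), "reps": 30})
    sdm: dict = field(default_factory=lambda: {
        "baseline_start": 2002, "baseline_end": 2018, "mask_km": 150.0})

    @classmethod
    def default(cls) -> "ScenarioConfig":
        cfg = cls()
        cfg.taxa = {
            "anchovy_like": {"depth_association": 1.2, "occurrence_intercept": 1.4,
                             "sigma_log": 0.7, "seasonal_slope": 0.0},
            "hake_like": {"depth_association": -1.2, "occurrence_intercept": 1.4,
                          "sigma_log": 0.7, "seasonal_slope": 0.0},
            "sanddab_like": {"depth_association": 0.0, "occurrence_intercept": 1.4,
                             "sigma_log": 0.7, "seasonal_slope": 0.0},
            "rockfish_like": {"depth_association": 0.6, "occurrence_intercept": 1.2,
                              "sigma_log": 0.7, "seasonal_slope": -0.02},
        }
        cfg.diet = [{"prey_group": "rockfish_like", "slope": 0.12,
                     "intercept": -0.25, "noise_sd": 0.06}]
        return cfg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "design": self.design, "years": self.years,
            "hauls_per_year": self.hauls_per_year,
            "reduced_years": list(self.reduced_years), "taxa": self.taxa,
            "diet": self.diet, "index": self.index, "effort": self.effort,
            "sdm": self.sdm,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        cfg = cls()
        for key, val in d.items():
            if not hasattr(cfg, key):
                raise SchemaError(f"unknown scenario config key {key!r}")
            setattr(cfg, key, val)
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @property
    def year_list(self) -> list[int]:
        return list(range(int(self.years["start"]), int(self.years["end"]) + 1))


def build_scenario(cfg: ScenarioConfig):
    """Materialize a scenario: (stations, taxa, hauls, diet tables).

    Year effects are drawn from the scenario seed (iid normal with per-taxon
    ``mean_log``/``year_sd``, defaults 3.0/0.7); diet series are generated
    from each configured prey taxon's true index.
    """
    rng = np.random.default_rng(cfg.seed)
    design = synthetic.make_design(
        n_stations=int(cfg.design.get("n_stations", 35)),
        strata_spec=cfg.design.get("strata"),
        seed=int(rng.integers(2 ** 31)),
    )
    years = cfg.year_list
    taxa = []
    for name, spec in cfg.taxa.items():
        mean_log = float(spec.get("mean_log", 3.0))
        year_sd = float(spec.get("year_sd", 0.7))
        lam = {int(y): float(v) for y, v in
               zip(years, rng.normal(mean_log, year_sd, size=len(years)))}
        taxa.append(TaxonParams(
            taxon=name,
            year_effects=lam,
            occurrence_intercept=float(spec.get("occurrence_intercept", 1.4)),
            depth_association=float(spec.get("depth_association", 0.0)),
            region_effects=dict(spec.get("region_effects", {})),
            sigma_log=float(spec.get("sigma_log", 0.7)),
            patchiness_cv=float(spec.get("patchiness_cv", 0.0)),
            seasonal_slope=float(spec.get("seasonal_slope", 0.0)),
        ))
    hauls = synthetic.simulate_hauls(
        design, taxa, years,
        hauls_per_year=int(cfg.hauls_per_year),
        reduced_years=[int(y) for y in cfg.reduced_years],
        seed=int(rng.integers(2 ** 31)),
    )
    diets = {}
    taxa_by_name = {t.taxon: t for t in taxa}
    for spec in cfg.diet:
        prey = spec["prey_group"]
        truth = synthetic.true_index(taxa_by_name[prey], design, years)
        diets[prey] = synthetic.simulate_diet(
            truth, slope=float(spec["slope"]), intercept=float(spec["intercept"]),
            noise_sd=float(spec["noise_sd"]), seed=int(rng.integers(2 ** 31)),
            prey_group=prey,
        )
    return design, taxa, hauls, diets
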