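"""Shared fixtures: a small worked example with closed-form answers and the
default 31-year survey scenario (62 hauls/year, final year reduced to the
15-station inshore subset)."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from trawlkit import synthetic

YEARS = list(range(1990, 2021))


@pytest.fixture(scope="session")
def worked_example():
    """2 years x 4 hauls with catches {0,0,3,9} and {0,2,2,0}.

    Year-only closed form: p-hat = (0.5, 0.5); mu-hat = (mean(log3, log9),
    log 2); index = (0.5*sqrt(27), 1.0).
    """
    hauls = pd.DataFrame(
        {
            "haul_id": [f"h{i}" for i in range(8)],
            "year": [2001] * 4 + [2002] * 4,
            "julian_day": [130, 135, 140, 145] * 2,
            "night_id": ["n1", "n1", "n2", "n2"] * 2,
            "station_id": ["S001", "S002", "S003", "S004"] * 2,
            "cpue_t": [0, 0, 3, 9, 0, 2, 2, 0],
        }
    )
    stations = pd.DataFrame(
        {
            "station_id": [f"S00{i}" for i in range(1, 5)],
            "region": ["north"] * 4,
            "depth_stratum": ["shelf"] * 4,
            "bottom_depth_m": [50.0] * 4,
            "distance_to_shore_km": [10.0] * 4,
            "reduced_year_flag": [True] * 4,
        }
    )
    return hauls, stations


@pytest.fixture(scope="session")
def core_design():
    return synthetic.make_design(n_stations=35, seed=1)


@pytest.fixture(scope="session")
def default_scenario(core_design):
    """(design, taxa, hauls): the default 31-year scenario with a reduced
    final year."""
    taxa = synthetic.default_taxa(YEARS, seed=2)
    hauls = synthetic.simulate_hauls(
        core_design, taxa, YEARS, hauls_per_year=62, reduced_years=[2020], seed=3)
    return core_design, taxa, hauls
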