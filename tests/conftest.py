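import warnings

import numpy as np
import pandas as pd
import pytest

from phytosize.simulate import ScenarioConfig, generate_dataset

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small two-station, four-year synthetic realization for unit tests."""
    cfg = ScenarioConfig(
        n_stations=2, months=48, n_diatom=8, n_dinoflagellate=5, n_other=3,
        stations_per_wcz=1, seed=7,
    )
    return generate_dataset(cfg)


@pytest.fixture
def simple_obs():
    """Hand-written observation table with two stations and two months."""
    rows = []
    for st, wcz in (("A", "Z1"), ("B", "Z2")):
        for date in ("2000-01", "2000-02"):
            rows += [
                dict(station_id=st, wcz=wcz, date=pd.Period(date, "M"),
                     species_id="small1", group="diatom", abundance=90.0, cell_biovolume=10.0),
                dict(station_id=st, wcz=wcz, date=pd.Period(date, "M"),
                     species_id="mid1", group="dinoflagellate", abundance=9.0, cell_biovolume=1e3),
                dict(station_id=st, wcz=wcz, date=pd.Period(date, "M"),
                     species_id="big1", group="other", abundance=1.0, cell_biovolume=1e5),
                dict(station_id=st, wcz=wcz, date=pd.Period(date, "M"),
                     species_id="big2", group="diatom", abundance=2.0, cell_biovolume=2e4),
            ]
    return pd.DataFrame(rows)
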