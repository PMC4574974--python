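import numpy as np
import pandas as pd
import pytest

from lynxkill import killseries, synthio


@pytest.fixture(scope="session")
def sim_config():
    """One full-year study, all four statuses, carcasses always found."""
    return synthio.SimConfig(
        seed=11,
        monitoring_days=365,
        miss_rate=0.0,
        n_lynx={"adult_male": 3, "single_adult_female": 2,
                "subadult_female": 2, "family_group": 2},
    )


@pytest.fixture(scope="session")
def landscape(sim_config):
    return synthio.make_landscape(sim_config)


@pytest.fixture(scope="session")
def kills(sim_config, landscape):
    return synthio.simulate_killseries(sim_config, landscape)


@pytest.fixture(scope="session")
def intervals(kills):
    return killseries.censor_intervals(killseries.build_intervals(kills))


def make_kills_frame(records):
    """Small kills table from (lynx_id, status, species, kill, left, found)."""
    rows = []
    for lynx_id, status, species, kill, left, found in records:
        rows.append({
            "lynx_id": lynx_id, "status": status, "species": species,
            "kill_date": pd.Timestamp(kill), "left_date": pd.Timestamp(left),
            "x_m": 0.0, "y_m": 0.0, "found": found,
        })
    columns = ["lynx_id", "status", "species", "kill_date", "left_date",
               "x_m", "y_m", "found"]
    return pd.DataFrame(rows, columns=columns)
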