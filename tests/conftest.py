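import numpy as np
import pandas as pd
import pytest

from ovibias import SimulationConfig, generate_monitoring, generate_pairs, generate_survey


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig()

@pytest.fixture(scope="session")
def null_config() -> SimulationConfig:
    return SimulationConfig.null()


@pytest.fixture(scope="session")
def survey_df(default_config):
    return generate_survey(default_config)


@pytest.fixture(scope="session")
def plants_df(default_config):
    return generate_monitoring(default_config)


@pytest.fixture(scope="session")
def pairs_df(default_config):
    return generate_pairs(default_config)


def make_flowers(n: int, n_herm: int, n_eggs: int, obs_herm_eggs: int, population: str = "P1") -> pd.DataFrame:
    """A single-population flower table with a prescribed egg placement."""
    assert 0 <= n_herm <= n and 0 <= n_eggs <= n
    assert max(0, n_eggs - (n - n_herm)) <= obs_herm_eggs <= min(n_eggs, n_herm)
    sex = np.array(["H"] * n_herm + ["F"] * (n - n_herm), dtype=object)
    egg = np.zeros(n, dtype=np.int64)
    egg[:obs_herm_eggs] = 1                      # eggs on hermaphrodites
    egg[n_herm : n_herm + (n_eggs - obs_herm_eggs)] = 1  # rest on females
    return pd.DataFrame({"population": population, "sex": sex, "egg": egg})


def make_pairs(diffs: np.ndarray, base: float = 10.0) -> pd.DataFrame:
    """A minimal pairs table whose seed differences (egg - control) are ``diffs``."""
    n = len(diffs)
    rows = []
    for i, d in enumerate(diffs):
        for egg, seeds in ((1, base + d), (0, base)):
            rows.append(
                {
                    "pair_id": f"PR{i + 1}",
                    "plant_id": f"PL{i + 1}",
                    "population": "MSH",
                    "sex": "H",
                    "egg": egg,
                    "floral_face_width": 20.0,
                    "flower_length": 22.0,
                    "calyx_width": 8.0,
                    "calyx_length": 13.0,
                    "tube_opening": 3.0,
                    "seeds": int(round(seeds)),
                    "fruit_mass": 80.0,
                }
            )
    return pd.DataFrame(rows)
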