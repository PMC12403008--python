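import numpy as np
import pandas as pd
import pytest

from spatid import Pedigree, SimulationConfig, simulate_population


@pytest.fixture(scope="session")
def small_dataset():
    """One modest simulated deme shared by read-only tests."""
    cfg = SimulationConfig(
        n_founders=80, n_loci=300, years=10, mating_radius_m=200.0,
        arena_size_m=1200.0, seed=11,
    )
    return simulate_population(cfg)


@pytest.fixture()
def fullsib_pedigree():
    """Founders A, B; full siblings C, D; E their offspring."""
    return Pedigree(
        pd.DataFrame(
            {
                "id": ["A", "B", "C", "D", "E"],
                "dam": ["", "", "A", "A", "C"],
                "sire": ["", "", "B", "B", "D"],
                "sex": ["F", "M", "F", "M", "F"],
            }
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
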