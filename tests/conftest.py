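import numpy as np
import pandas as pd
import pytest

from hspherit import Pedigree, SimulationConfig, simulate_dataset


def random_pedigree(rng: np.random.Generator, n_animals: int) -> Pedigree:
    """Random multi-generation pedigree, inbred matings allowed.

    Founders plus successive animals whose parents are drawn from earlier
    animals (or unknown with small probability), so loops of relatedness and
    inbreeding occur — a stress case for relationship-matrix code.
    """
    n_founders = max(4, n_animals // 5)
    records = [(f"A{i}", "", "") for i in range(n_founders)]
    for i in range(n_founders, n_animals):
        if rng.random() < 0.1:
            s = ""
        else:
            s = f"A{rng.integers(0, i)}"
        if rng.random() < 0.1:
            d = ""
        else:
            d = f"A{rng.integers(0, i)}"
        records.append((f"A{i}", s, d))
    return Pedigree.from_records(records)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced design (10 sires x 3 dams, 4-6 offspring) for fast fits."""
    return SimulationConfig(
        n_sires=10,
        offspring_range=(4, 6),
        fractions=("intracellular",),
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config, seed=7)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """Full study-sized dataset (60 families, both years, one fraction)."""
    cfg = SimulationConfig(fractions=("intracellular",))
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def trio_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "animal": ["S1", "D1", "O1"],
            "sire": ["0", "0", "S1"],
            "dam": ["0", "0", "D1"],
        }
    )
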