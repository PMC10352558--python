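import numpy as np
import pandas as pd
import pytest

from acetyltempo import QuantTable
from acetyltempo.synthetic_data import SimulationDesign, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One seeded synthetic dataset shared across tests (~800 sites)."""
    design = SimulationDesign(n_proteins=400, seed=11)
    return simulate_dataset(design)


@pytest.fixture
def tiny_table():
    """3 sites x 9 samples with hand-set intensities."""
    rng = np.random.default_rng(3)
    samples = [f"{c}_r{r}" for c in ("UnT", "6hAmAc", "24hAmAc")
               for r in (1, 2, 3)]
    data = pd.DataFrame(
        rng.uniform(10, 1000, (3, 9)),
        index=pd.Index(["Pa_K4", "Pb_K10", "Pc_K2"], name="site_id"),
        columns=samples,
    )
    meta = pd.DataFrame(
        {"condition": [c for c in ("UnT", "6hAmAc", "24hAmAc")
                       for _ in range(3)],
         "replicate": [1, 2, 3] * 3},
        index=pd.Index(samples, name="sample"),
    )
    return QuantTable(data, meta)
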