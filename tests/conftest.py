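import logging

import numpy as np
import pandas as pd
import pytest

from aqasm import OTUTable, generate_scenario, scenario_config

logging.getLogger("aqasm").setLevel(logging.ERROR)


@pytest.fixture
def rng():
    return np.random.default_rng(20160801)


@pytest.fixture
def small_table():
    counts = pd.DataFrame(
        [[5, 0, 3, 2], [1, 4, 0, 5], [2, 2, 2, 2]],
        index=["S1", "S2", "S3"],
        columns=["Otu1", "Otu2", "Otu3", "Otu4"],
    )
    return OTUTable(counts)


@pytest.fixture(scope="session")
def neutral_bundle():
    """A small neutral-regime dataset reused by read-only tests."""
    cfg = scenario_config("neutral", seed=11, n_otus=40, n_soil=3,
                          n_seepage=3, read_depth=4000)
    return generate_scenario(cfg)
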