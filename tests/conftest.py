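import numpy as np
import pandas as pd
import pytest

from phosphodyn import simulate


@pytest.fixture
def small_config():
    """A small but fully structured design: 2 drugs x 2 doses x 4 lines."""
    return simulate.SimulationConfig(
        seed=11,
        n_cell_lines=4,
        n_antibodies=6,
        drugs=("5FU", "CIS"),
        doses_per_drug=2,
        n_control_spots=8,
    )


@pytest.fixture
def default_config():
    return simulate.SimulationConfig(seed=7)


@pytest.fixture
def noiseless_config():
    """No spot noise, no outliers, flat-majority mix.

    Under these conditions quantification is an exact round trip: control
    division and per-sample log-median centering recover the planted log2
    fold changes to machine precision, provided every series keeps a
    flat-course majority (the tests assert that precondition on this seed).
    """
    return simulate.SimulationConfig(
        seed=0,
        n_cell_lines=2,
        n_antibodies=9,
        drugs=("5FU",),
        doses_per_drug=2,
        n_control_spots=8,
        noise_sd_log2=0.0,
        outlier_rate=0.0,
        class_mix={"early": 0.2, "intermediate": 0.1, "late": 0.1, "none": 0.6},
    )
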