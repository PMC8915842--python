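import numpy as np
import pandas as pd
import pytest

from htpp.design import small_screen_layout
from htpp.pipeline import demo_roster, run_screen
from htpp.simulate import ChemicalTruth, SimConfig, generate_study


@pytest.fixture(scope="session")
def small_study():
    """A compact 2-plate study shared by viability/profiling/pipeline tests."""
    roster, truths = demo_roster(n_features=80, affected_per_chemical=12)
    layouts = [small_screen_layout(roster, f"T{p}", seed=900 + p, n_vehicle=16)
               for p in range(2)]
    config = SimConfig(n_features=80, cells_per_well_mean=150.0)
    cells, truth_table = generate_study(layouts, truths, config, seed=42)
    return {"cells": cells, "truths": truths, "layouts": layouts,
            "config": config, "truth_table": truth_table}


@pytest.fixture(scope="session")
def small_screen_result(small_study):
    return run_screen(small_study["cells"], small_study["layouts"])


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
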