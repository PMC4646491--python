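import numpy as np
import pandas as pd
import pytest

import erythroscreen as es


@pytest.fixture(scope="session")
def default_specs():
    return es.simulate.default_population_specs()


@pytest.fixture(scope="session")
def small_screen():
    """A 12-compound duplicate screen with a known 3-inhibitor spike-in."""
    design = es.simulate.ScreenDesign(n_compounds=12, seed=7, n_cells_per_well=5000)
    library = es.simulate.make_library(
        n_compounds=12, n_arrest=2, n_delay=1, n_toxic=1, seed=7
    )
    wells, _ = es.simulate.simulate_screen(design, library, seed=7, mode="counts")
    return design, library, wells


@pytest.fixture(scope="session")
def default_screen():
    """The full default duplicate screen (324 compounds, counts mode)."""
    design = es.simulate.ScreenDesign(seed=11)
    library = es.simulate.make_library(seed=11)
    wells, _ = es.simulate.simulate_screen(design, library, seed=11, mode="counts")
    return design, library, wells


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_plate(values, plate_id="R1-P1", replicate=1, neg=(65.0, 64.0), pos=(2.0, 3.0)):
    """Build a minimal plate result table around compound-well values."""
    rows = []
    for i, v in enumerate(values):
        rows.append((plate_id, replicate, f"W{i + 2}", "compound", f"C{i + 1}", v))
    for i, v in enumerate(neg):
        rows.append((plate_id, replicate, f"N{i}", "neg_control", "DMSO", v))
    for i, v in enumerate(pos):
        rows.append((plate_id, replicate, f"P{i}", "pos_control", "CytoD", v))
    return pd.DataFrame(
        rows,
        columns=["plate_id", "replicate", "well_id", "role", "compound_id", "net_enucleation_pct"],
    )
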