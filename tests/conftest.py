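import numpy as np
import pandas as pd
import pytest

from comboscreen.screen import WELL_COLUMNS, WITH_TILS, WITHOUT_TILS


def make_wells(rows):
    """Build a wells frame from (compound_id, dose, til_status, rep, pct)
    tuples on tumor line L1."""
    records = [
        ("p1", f"w{i}", "L1", cid, dose, til, rep, pct)
        for i, (cid, dose, til, rep, pct) in enumerate(rows)
    ]
    return pd.DataFrame(records, columns=WELL_COLUMNS)


def condition_wells(cid, dose, til, pcts):
    return [(cid, dose, til, r + 1, p) for r, p in enumerate(pcts)]


@pytest.fixture
def simple_screen_wells():
    """One line, two compounds, single replicate, noise-free values chosen
    so comboscores are 3.0 (A, enhancer) and 0.5 (B)."""
    rows = []
    rows += condition_wells("DMSO", 0.0, WITHOUT_TILS, [0.0])
    rows += condition_wells("DMSO", 0.0, WITH_TILS, [20.0])
    rows += condition_wells("cmpdA", 1000.0, WITHOUT_TILS, [10.0])
    rows += condition_wells("cmpdA", 1000.0, WITH_TILS, [70.0])   # (70-10)/20 = 3
    rows += condition_wells("cmpdB", 1000.0, WITHOUT_TILS, [5.0])
    rows += condition_wells("cmpdB", 1000.0, WITH_TILS, [15.0])   # (15-5)/20 = 0.5
    return make_wells(rows)


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)
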