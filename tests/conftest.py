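import numpy as np
import pandas as pd
import pytest

import fsispace as f
from fsispace import synth


@pytest.fixture(scope="session")
def china_wm():
    return f.row_standardize(f.contiguity_weights(f.load_china_adjacency()))


@pytest.fixture(scope="session")
def table2():
    return f.load_table2_fixture()


@pytest.fixture(scope="session")
def default_panel():
    """One default synthetic panel with its truth record (seed fixed)."""
    return synth.generate_panel(synth.SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def recovery_panel():
    """Recovery-grade panel: spatial Durbin process is the only
    cross-sectional structure."""
    cfg = synth.recovery_config(seed=11, trend_slopes=(0, 0, 0), shock_magnitude=0.0)
    return synth.generate_panel(cfg)


@pytest.fixture()
def tiny_panel_df():
    """Minimal well-formed 3-unit x 3-year panel frame."""
    rows = []
    for u, r in (("a", "east"), ("b", "central"), ("c", "west")):
        for y in (2010, 2011, 2012):
            rows.append(
                {"unit": u, "region": r, "year": y, "v1": hash((u, y)) % 7 + 1.0, "v2": 2.0}
            )
    return pd.DataFrame(rows)


def make_scores(values: np.ndarray, years=None, units=None) -> pd.Series:
    """(unit, year)-indexed series from a units x years array."""
    values = np.asarray(values, float)
    n, T = values.shape
    units = units or [f"u{i:02d}" for i in range(n)]
    years = years or list(range(2010, 2010 + T))
    df = pd.DataFrame(values, index=units, columns=years)
    s = df.stack()
    s.index.names = ["unit", "year"]
    return s.rename("fsi")
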