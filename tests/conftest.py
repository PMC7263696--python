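import pandas as pd
import pytest

from recscreen.pinscore import COLONY_COLUMNS, ScreenConfig


def make_colonies(rows):
    """Build a colony table from (plate, row, col, strain, medium, area, circ)."""
    return pd.DataFrame(rows, columns=list(COLONY_COLUMNS))


@pytest.fixture
def default_screen_config():
    return ScreenConfig()


@pytest.fixture
def toy_plate():
    """One plate, one strain, four permissive/selective colony pairs.

    Permissive areas (100, 100, 100, 20): plate mean 80, 50% threshold 40,
    so three permissive colonies score.  Strain mean of scored permissive
    areas is 100, 10% threshold 10: selective areas (50, 9, 50, 50) score at
    positions 1 and 3 only — position 2 is too small and position 4's
    permissive partner failed.
    """
    rows = []
    perm_areas = [100.0, 100.0, 100.0, 20.0]
    sel_areas = [50.0, 9.0, 50.0, 50.0]
    for i, (pa, sa) in enumerate(zip(perm_areas, sel_areas), start=1):
        rows.append(("P1", 1, i, "strainA", "permissive", pa, 0.95))
        rows.append(("P1", 1, i, "strainA", "selective", sa, 0.95))
    return make_colonies(rows)
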