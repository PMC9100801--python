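import numpy as np
import pandas as pd
import pytest

from ulascreen.plate_io import ANNOTATION_COLUMNS, PlateSet
from ulascreen.synthetic_data import SyntheticConfig, simulate_screen


def make_plateset(rows, geometry=96, scale="raw"):
    """Build a PlateSet from (plate, rep, row, col, role, feature, value) tuples."""
    wells = pd.DataFrame(rows, columns=ANNOTATION_COLUMNS + ["value"])
    return PlateSet(geometry=geometry, wells=wells, scale=scale)


def tiny_plate(plate_id, rep_id, feature_values, control_values, scale="raw"):
    """One plate: samples in column 1.., controls appended after them."""
    rows = []
    letters = "ABCDEFGH"
    idx = 0
    for fid, val in feature_values.items():
        rows.append((plate_id, rep_id, letters[idx % 8], idx // 8 + 1, "sample", fid, val))
        idx += 1
    for cid, vals in control_values.items():
        role = "neg_control" if cid == "C2" else "pos_control_growth"
        for val in vals:
            rows.append((plate_id, rep_id, letters[idx % 8], idx // 8 + 1, role, cid, val))
            idx += 1
    return rows


@pytest.fixture(scope="session")
def small_screen():
    """A reduced screen (120 features, 3 reps, 4 plates) with spiked effects."""
    cfg = SyntheticConfig(
        n_features=120,
        plates_per_replicate=4,
        frac_suppressors=0.1,
        seed=11,
    )
    plateset, truth, design = simulate_screen(cfg)
    return cfg, plateset, truth, design


@pytest.fixture(scope="session")
def noise_free_screen():
    """Degenerate screen: every variance component zero, effects spiked."""
    cfg = SyntheticConfig(
        n_features=60,
        plates_per_replicate=2,
        frac_suppressors=0.2,
        noise_sd=0.0,
        plate_effect_sd=0.0,
        replicate_shift_sd=0.0,
        seed=5,
    )
    plateset, truth, design = simulate_screen(cfg)
    return cfg, plateset, truth, design
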