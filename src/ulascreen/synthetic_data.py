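"""Synthetic ULA-screen and validation-experiment generator with known truth.

The generative model mirrors the structure the analysis assumes.  Every raw
fluorescence reading is built on the log2 scale as

    log2(F) = baseline + a_r + b_{p,r} - e(feature) * delta + eps

with a replicate shift ``a_r ~ N(0, replicate_shift_sd)``, a plate offset
``b_{p,r} ~ N(0, plate_effect_sd)``, lognormal measurement noise
``eps ~ N(0, noise_sd)``, and ``delta`` the log2 viability gap between the
negative control (effect 0) and a full-strength growth suppressor (effect 1).
Effects therefore live on the same unitless scale as the lethality score, so a
noise-free pipeline recovers them exactly.

Randomness is hierarchical: one global seed spawns independent streams per
(replicate, plate), so omitting one plate never perturbs the draws of any
other plate.
"""

from __future__ import annotations

import string
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .plate_io import GEOMETRIES, PlateSet, ScreenDesign, ANNOTATION_COLUMNS

__all__ = ["SyntheticConfig", "SCREEN_CONTROLS", "simulate_screen", "simulate_validation"]

#: control feature ids used throughout the synthetic screens, with their role
#: and true effect on the lethality scale.  The transfection control (an
#: essential-gene siRNA) is deliberately stronger than the growth controls so
#: that positive-control selection has something to discriminate.
SCREEN_CONTROLS: dict[str, tuple[str, float]] = {
    "C2": ("neg_control", 0.0),
    "miR-137": ("pos_control_growth", 1.0),
    "miR-129-2-3p": ("pos_control_growth", 0.8),
    "UBB": ("pos_control_transfection", 1.3),
}

#: wells per plate devoted to each control in the 96-well primary screen
SCREEN_CONTROL_WELLS = {"C2": 6, "miR-137": 3, "miR-129-2-3p": 3, "UBB": 3}


@dataclass
class SyntheticConfig:
    """Parameters of the generative model.

    Defaults reproduce the primary screen design: a 2019-feature mimic library
    screened in triplicate over twenty-six 96-well ULA plates.  Variance
    components are plausible bench values (log2 units) and are not claimed to
    be the original study's; they are deliberately exposed here.
    """

    n_features: int = 2019
    n_replicates: int = 3
    plates_per_replicate: int = 26
    frac_suppressors: float = 0.05
    effect_grid: tuple[float, ...] = (0.25, 0.5, 1.0)
    plate_effect_sd: float = 0.2
    replicate_shift_sd: float = 0.3
    noise_sd: float = 0.15
    baseline_log2: float = 14.0
    delta_log2: float = 2.0
    ula_specific_fraction: float = 0.6
    adherent_shift_log2: float = 0.5
    n_validation_replicate_wells: int = 2
    drop_plate: tuple[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("plate_effect_sd", "replicate_shift_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.frac_suppressors <= 1.0:
            raise ValueError("frac_suppressors must be in [0, 1]")
        if not 0.0 <= self.ula_specific_fraction <= 1.0:
            raise ValueError("ula_specific_fraction must be in [0, 1]")
        if not all(np.isfinite(self.effect_grid)):
            raise ValueError("effect_grid values must be finite")
        if self.delta_log2 <= 0:
            raise ValueError("delta_log2 must be positive")
        if self.n_features < 1 or self.n_replicates < 1 or self.plates_per_replicate < 1:
            raise ValueError("counts must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _feature_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"mimic-{i + 1:0{width}d}" for i in range(n)]


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, *key]))


# stream name-space constants keeping the hierarchical streams disjoint
_TRUTH, _REPLICATE, _PLATE, _VALIDATION = 1, 2, 3, 4


def make_truth(config: SyntheticConfig) -> pd.DataFrame:
    """Assign true effects to features; deterministic in the config seed.

    A ``frac_suppressors`` fraction of features receives an effect from
    ``effect_grid`` (cycled so each grid value gets an equal share); the rest
    are null.  Each affected feature is ULA-specific (no adherent effect) with
    probability ``ula_specific_fraction``, otherwise equally toxic in both
    conditions.
    """
    rng = _rng(config.seed, _TRUTH)
    ids = _feature_ids(config.n_features)
    e_ula = np.zeros(config.n_features)
    e_adh = np.zeros(config.n_features)
    n_supp = int(round(config.frac_suppressors * config.n_features))
    if n_supp > 0:
        idx = rng.choice(config.n_features, size=n_supp, replace=False)
        grid = np.asarray(config.effect_grid, float)
        effects = grid[np.arange(n_supp) % len(grid)]
        e_ula[idx] = effects
        specific = rng.random(n_supp) < config.ula_specific_fraction
        e_adh[idx] = np.where(specific, 0.0, effects)
    return pd.DataFrame(
        {"feature_id": ids, "true_effect_ula": e_ula, "true_effect_adherent": e_adh}
    )


def make_screen_layout(config: SyntheticConfig) -> pd.DataFrame:
    """Annotation frame for the primary screen: samples filled row-major,
    controls in the right-hand columns of every plate."""
    n_rows, n_cols = GEOMETRIES[96]
    row_letters = string.ascii_uppercase[:n_rows]
    all_positions = [(r, c) for c in range(1, n_cols + 1) for r in row_letters]
    n_ctrl = sum(SCREEN_CONTROL_WELLS.values())
    sample_capacity = 96 - n_ctrl
    ctrl_positions = all_positions[-n_ctrl:]
    sample_positions = all_positions[:-n_ctrl]

    ids = _feature_ids(config.n_features)
    n_plates = config.plates_per_replicate
    per_plate = int(np.ceil(config.n_features / n_plates))
    if per_plate > sample_capacity:
        raise ValueError(
            f"{config.n_features} features do not fit on {n_plates} plates "
            f"with {sample_capacity} sample wells each"
        )
    # balanced split: first plates take ceil, the remainder floor
    bounds = np.linspace(0, config.n_features, n_plates + 1).round().astype(int)

    records = []
    for rep in range(config.n_replicates):
        rep_id = f"R{rep + 1}"
        for p in range(n_plates):
            plate_id = f"P{p + 1:02d}"
            feats = ids[bounds[p] : bounds[p + 1]]
            for (row, col), fid in zip(sample_positions, feats):
                records.append((plate_id, rep_id, row, col, "sample", fid))
            pos_iter = iter(ctrl_positions)
            for cid, n_wells in SCREEN_CONTROL_WELLS.items():
                role = SCREEN_CONTROLS[cid][0]
                for _ in range(n_wells):
                    row, col = next(pos_iter)
                    records.append((plate_id, rep_id, row, col, role, cid))
    return pd.DataFrame(records, columns=ANNOTATION_COLUMNS)


def _readings(
    ann: pd.DataFrame,
    effects: Mapping[str, float],
    config: SyntheticConfig,
    condition_shift: float = 0.0,
    stream: int = _PLATE,
) -> np.ndarray:
    """Raw readings for an annotation frame under the generative model."""
    rep_ids = sorted(ann["replicate_id"].unique())
    shifts = {
        rep: _rng(config.seed, _REPLICATE, i).normal(0.0, config.replicate_shift_sd)
        for i, rep in enumerate(rep_ids)
    }
    values = np.empty(len(ann))
    e = ann["feature_id"].map(lambda f: effects.get(f, 0.0)).to_numpy(float)
    base = config.baseline_log2 + condition_shift - e * config.delta_log2
    for (rep, plate), idx in ann.groupby(["replicate_id", "plate_id"]).groups.items():
        rng = _rng(config.seed, stream, rep_ids.index(rep), _plate_key(plate))
        b = rng.normal(0.0, config.plate_effect_sd)
        eps = rng.normal(0.0, config.noise_sd, size=len(idx))
        loc = ann.index.get_indexer(idx)
        values[loc] = base[loc] + shifts[rep] + b + eps
    return np.exp2(values)


def _plate_key(plate_id: str) -> int:
    digits = "".join(ch for ch in plate_id if ch.isdigit())
    # crc32, not hash(): the builtin str hash is salted per interpreter run
    return int(digits) if digits else zlib.crc32(plate_id.encode())


def simulate_screen(
    config: SyntheticConfig,
) -> tuple[PlateSet, pd.DataFrame, ScreenDesign]:
    """Generate a full primary screen.

    Returns the raw :class:`~ulascreen.plate_io.PlateSet`, the truth table
    (feature_id, true_effect_ula, true_effect_adherent) and the screen design.
    Identical seeds give bit-identical output; dropping a plate removes exactly
    that plate without changing any other reading.
    """
    truth = make_truth(config)
    ann = make_screen_layout(config)
    effects = dict(zip(truth["feature_id"], truth["true_effect_ula"]))
    effects.update({cid: e for cid, (_, e) in SCREEN_CONTROLS.items()})
    values = _readings(ann, effects, config)
    wells = ann.assign(value=values)

    missing: list[tuple[str, str]] = []
    if config.drop_plate is not None:
        rep, plate = config.drop_plate
        mask = (wells["replicate_id"] == rep) & (wells["plate_id"] == plate)
        if not mask.any():
            raise ValueError(f"drop_plate {config.drop_plate} not in layout")
        wells = wells[~mask].reset_index(drop=True)
        missing.append((rep, plate))

    design = ScreenDesign(
        n_replicates=config.n_replicates,
        plates_per_replicate=config.plates_per_replicate,
        control_roles={
            "neg_control": ("C2",),
            "pos_control_growth": ("miR-129-2-3p", "miR-137"),
            "pos_control_transfection": ("UBB",),
        },
    )
    plateset = PlateSet(geometry=96, wells=wells, scale="raw", missing_plates=missing)
    return plateset, truth, design


def make_validation_layout(
    feature_ids: Sequence[str],
    neg_panel_ids: Sequence[str],
    condition: str,
    n_wells: int = 2,
) -> pd.DataFrame:
    """384-well validation plate: every feature, panel member and control in
    ``n_wells`` replicate wells, filled column-major."""
    n_rows, n_cols = GEOMETRIES[384]
    row_letters = string.ascii_uppercase[:n_rows]
    positions = iter([(r, c) for c in range(1, n_cols + 1) for r in row_letters])
    records = []
    plate_id = f"V-{condition}"

    def place(fid: str, role: str) -> None:
        for _ in range(n_wells):
            row, col = next(positions)
            records.append((plate_id, "V1", row, col, role, fid))

    for fid in feature_ids:
        place(fid, "sample")
    for fid in neg_panel_ids:
        place(fid, "neg_panel")
    place("C1", "neg_control")  # secondary non-targeting control, not the anchor
    place("C2", "neg_control")
    place("UBB", "pos_control_transfection")
    return pd.DataFrame(records, columns=ANNOTATION_COLUMNS)


def simulate_validation(
    config: SyntheticConfig,
    truth: pd.DataFrame | None = None,
    candidates: Sequence[str] | None = None,
) -> tuple[PlateSet, PlateSet, pd.DataFrame]:
    """Generate paired ULA / adherent 384-well validation plates.

    ``truth`` may carry effects from a primary screen (only rows for
    ``candidates`` are used); otherwise a fresh small truth table is drawn from
    the config.  Adherent plates share the feature truth but apply the
    adherent-condition effect and a condition-specific intensity shift, which
    panel normalization must divide out.

    Returns ``(ula_plateset, adherent_plateset, truth_subset)``.
    """
    if truth is None:
        truth = make_truth(config)
    if candidates is None:
        candidates = list(truth["feature_id"])
    truth = truth.set_index("feature_id").loc[list(candidates)].reset_index()

    panel_ids = [f"panel-{i + 1:02d}" for i in range(16)]
    effects_ula = dict(zip(truth["feature_id"], truth["true_effect_ula"]))
    effects_adh = dict(zip(truth["feature_id"], truth["true_effect_adherent"]))
    for fid in panel_ids + ["C1", "C2"]:
        effects_ula[fid] = effects_adh[fid] = 0.0
    effects_ula["UBB"] = effects_adh["UBB"] = SCREEN_CONTROLS["UBB"][1]

    platesets = {}
    for cond, effects, shift, key in (
        ("ULA", effects_ula, 0.0, 0),
        ("adherent", effects_adh, config.adherent_shift_log2, 1),
    ):
        ann = make_validation_layout(
            candidates, panel_ids, cond, config.n_validation_replicate_wells
        )
        values = _readings(ann, effects, config, condition_shift=shift,
                           stream=_VALIDATION * 10 + key)
        platesets[cond] = PlateSet(geometry=384, wells=ann.assign(value=values))
    return platesets["ULA"], platesets["adherent"], truth
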