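"""Reading and writing plate layouts, well-level read-outs, and result tables.

Layouts and measurements are plain CSV/TSV files with a header; the delimiter
is sniffed from the file extension (``.tsv`` / ``.txt`` -> tab, anything else
comma).  Well addresses follow instrument conventions: lettered rows, 1-based
columns, accepted both zero-padded ("B07") and bare ("B7").
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GEOMETRIES",
    "ROLES",
    "WellAnnotation",
    "PlateSet",
    "ScreenDesign",
    "parse_well",
    "format_well",
    "read_layout",
    "read_measurements",
    "write_table",
    "validate_annotations",
]

#: supported plate geometries -> (n_rows, n_cols)
GEOMETRIES: dict[int, tuple[int, int]] = {96: (8, 12), 384: (16, 24)}

#: recognised well roles
ROLES = frozenset(
    {
        "sample",
        "neg_control",
        "pos_control_growth",
        "pos_control_transfection",
        "neg_panel",
        "empty",
    }
)

CONTROL_ROLES = frozenset(
    {"neg_control", "pos_control_growth", "pos_control_transfection", "neg_panel"}
)

_WELL_RE = re.compile(r"^([A-Pa-p])(\d{1,2})$")

ANNOTATION_COLUMNS = ["plate_id", "replicate_id", "row", "col", "role", "feature_id"]


def parse_well(well: str) -> tuple[str, int]:
    """Split a well address like ``"B07"`` or ``"B7"`` into ``("B", 7)``."""
    m = _WELL_RE.match(well.strip())
    if m is None:
        raise ValueError(f"unparseable well address: {well!r}")
    return m.group(1).upper(), int(m.group(2))


def format_well(row: str, col: int) -> str:
    """Inverse of :func:`parse_well`; always zero-pads the column."""
    return f"{row}{col:02d}"


@dataclass(frozen=True)
class WellAnnotation:
    """Static annotation of a single well: where it is and what it contains."""

    plate_id: str
    replicate_id: str
    row: str
    col: int
    role: str
    feature_id: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for well {self.address}")
        if self.role == "sample" and not self.feature_id:
            raise ValueError(f"sample well {self.address} lacks a feature_id")

    @property
    def address(self) -> str:
        return f"{self.plate_id}:{format_well(self.row, self.col)}"


@dataclass
class ScreenDesign:
    """Replicate/plate structure and control assignments of a screen."""

    n_replicates: int
    plates_per_replicate: int
    control_roles: dict[str, tuple[str, ...]] = field(default_factory=dict)
    neg_panel_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.plates_per_replicate < 1:
            raise ValueError("replicate and plate counts must be >= 1")
        negs = self.control_roles.get("neg_control", ())
        if len(negs) > 1:
            raise ValueError(
                f"exactly one designated negative-control feature expected, got {negs}"
            )

    @property
    def neg_control_id(self) -> str:
        negs = self.control_roles.get("neg_control", ())
        if not negs:
            raise ValueError("design has no negative control")
        return negs[0]

    @property
    def pos_control_candidates(self) -> tuple[str, ...]:
        return self.control_roles.get("pos_control_growth", ()) + self.control_roles.get(
            "pos_control_transfection", ()
        )


@dataclass
class PlateSet:
    """Well-level measurements for a set of plates with annotations.

    ``wells`` is a tidy DataFrame with columns
    ``plate_id, replicate_id, row, col, role, feature_id, value``.
    ``scale`` records whether values are raw reader units or log2.
    """

    geometry: int
    wells: pd.DataFrame
    scale: str = "raw"
    missing_plates: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"unsupported geometry {self.geometry}")
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        required = ANNOTATION_COLUMNS + ["value"]
        missing = [c for c in required if c not in self.wells.columns]
        if missing:
            raise ValueError(f"wells frame lacks columns: {missing}")
        dup = self.wells.duplicated(subset=["replicate_id", "plate_id", "row", "col"])
        if dup.any():
            bad = self.wells.loc[dup, ["plate_id", "row", "col"]].apply(
                lambda r: f"{r.plate_id}:{format_well(r.row, r.col)}", axis=1
            )
            raise ValueError(f"duplicate wells: {', '.join(sorted(set(bad)))}")
        if self.scale == "raw":
            bad = self.wells["value"] < 0
            if bad.any():
                names = _addresses(self.wells.loc[bad])
                raise ValueError(f"negative raw readings at: {', '.join(names)}")
        else:
            if not np.isfinite(self.wells["value"].to_numpy(float)).all():
                raise ValueError("log2-scale values must be finite")

    def replicate_ids(self) -> list[str]:
        return sorted(self.wells["replicate_id"].unique())

    def plate_ids(self) -> list[str]:
        return sorted(self.wells["plate_id"].unique())

    def subset(self, role: str) -> pd.DataFrame:
        return self.wells[self.wells["role"] == role]


def _addresses(frame: pd.DataFrame) -> list[str]:
    return sorted(
        f"{p}:{format_well(r, c)}"
        for p, r, c in zip(frame["plate_id"], frame["row"], frame["col"])
    )


def _sniff_sep(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","


def validate_annotations(ann: pd.DataFrame, geometry: int) -> None:
    """Enforce the layout invariants; raise with offending well names."""
    n_rows, n_cols = GEOMETRIES[geometry]
    valid_rows = set(string.ascii_uppercase[:n_rows])
    bad_pos = ~ann["row"].isin(valid_rows) | (ann["col"] < 1) | (ann["col"] > n_cols)
    if bad_pos.any():
        raise ValueError(
            f"wells outside {geometry}-well geometry: {', '.join(_addresses(ann[bad_pos]))}"
        )
    bad_role = ~ann["role"].isin(ROLES)
    if bad_role.any():
        raise ValueError(f"unknown roles: {sorted(ann.loc[bad_role, 'role'].unique())}")
    dup = ann.duplicated(subset=["replicate_id", "plate_id", "row", "col"], keep=False)
    if dup.any():
        raise ValueError(
            "duplicate well annotations: "
            + ", ".join(sorted(set(_addresses(ann[dup]))))
        )
    samples = ann[ann["role"] == "sample"]
    if (samples["feature_id"].astype(str).str.len() == 0).any():
        bad = samples[samples["feature_id"].astype(str).str.len() == 0]
        raise ValueError(f"sample wells without feature_id: {', '.join(_addresses(bad))}")
    dup_feat = samples.duplicated(
        subset=["replicate_id", "plate_id", "feature_id"], keep=False
    )
    if dup_feat.any():
        bad = samples[dup_feat]
        raise ValueError(
            "feature appears more than once on a plate: "
            + ", ".join(sorted(set(bad["feature_id"])))
        )


def read_layout(path: str | Path) -> tuple[ScreenDesign, pd.DataFrame]:
    """Read a layout table and derive the screen design from it.

    The file must have columns ``plate_id, replicate_id, well, role,
    feature_id``.  Returns the inferred :class:`ScreenDesign` and a tidy
    annotation frame with the well split into row letter and 1-based column.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    required = ["plate_id", "replicate_id", "well", "role", "feature_id"]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise ValueError(f"layout {path} lacks columns: {missing}")
    rows, cols = zip(*(parse_well(w) for w in raw["well"]))
    ann = pd.DataFrame(
        {
            "plate_id": raw["plate_id"].str.strip(),
            "replicate_id": raw["replicate_id"].str.strip(),
            "row": rows,
            "col": cols,
            "role": raw["role"].str.strip(),
            "feature_id": raw["feature_id"].str.strip(),
        }
    )
    geometry = 96 if (ann["col"].max() <= 12 and ann["row"].max() <= "H") else 384
    validate_annotations(ann, geometry)
    ann = ann.sort_values(["replicate_id", "plate_id", "row", "col"], kind="mergesort")
    ann = ann.reset_index(drop=True)

    control_roles: dict[str, tuple[str, ...]] = {}
    for role in ("neg_control", "pos_control_growth", "pos_control_transfection"):
        ids = sorted(ann.loc[ann["role"] == role, "feature_id"].unique())
        if ids:
            control_roles[role] = tuple(ids)
    neg_panel = tuple(sorted(ann.loc[ann["role"] == "neg_panel", "feature_id"].unique()))
    design = ScreenDesign(
        n_replicates=ann["replicate_id"].nunique(),
        plates_per_replicate=int(
            ann.groupby("replicate_id")["plate_id"].nunique().max()
        ),
        control_roles=control_roles,
        neg_panel_ids=neg_panel,
    )
    return design, ann


def read_measurements(path: str | Path, annotations: pd.DataFrame) -> PlateSet:
    """Join a readings file onto the layout annotations.

    The file must have columns ``plate_id, replicate_id, well, value`` with one
    reading per annotated non-empty well.  A plate that is entirely absent from
    the readings is flagged missing rather than treated as an error (readers
    occasionally skip a plate); individual missing wells are reported the same
    way through ``missing_plates`` bookkeeping only when the whole plate is
    gone, otherwise they raise.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=_sniff_sep(path))
    required = ["plate_id", "replicate_id", "well", "value"]
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise ValueError(f"measurements {path} lack columns: {missing_cols}")
    rows, cols = zip(*(parse_well(str(w)) for w in raw["well"]))
    meas = pd.DataFrame(
        {
            "plate_id": raw["plate_id"].astype(str).str.strip(),
            "replicate_id": raw["replicate_id"].astype(str).str.strip(),
            "row": rows,
            "col": cols,
            "value": pd.to_numeric(raw["value"]),
        }
    )
    neg = meas["value"] < 0
    if neg.any():
        raise ValueError(f"negative readings at: {', '.join(_addresses(meas[neg]))}")

    expected = annotations[annotations["role"] != "empty"]
    merged = expected.merge(
        meas, on=["plate_id", "replicate_id", "row", "col"], how="left"
    )
    # whole plates absent from the readings -> flagged missing
    plate_counts = merged.groupby(["replicate_id", "plate_id"])["value"].agg(
        ["size", "count"]
    )
    absent = plate_counts[plate_counts["count"] == 0].index.tolist()
    missing_plates = [(r, p) for r, p in absent]
    merged = merged[
        ~merged.set_index(["replicate_id", "plate_id"]).index.isin(absent)
    ].reset_index(drop=True)
    holes = merged["value"].isna()
    if holes.any():
        raise ValueError(
            "readings missing for wells: " + ", ".join(_addresses(merged[holes]))
        )
    geometry = 96 if (merged["col"].max() <= 12 and merged["row"].max() <= "H") else 384
    return PlateSet(
        geometry=geometry,
        wells=merged[ANNOTATION_COLUMNS + ["value"]],
        scale="raw",
        missing_plates=missing_plates,
    )


def write_table(records: pd.DataFrame, path: str | Path, float_fmt: str = "%.6g") -> None:
    """Write a result table as TSV with deterministic row order.

    Rows are sorted by ``feature_id`` when that column exists; floating values
    use a fixed precision so re-runs are byte-identical.
    """
    frame = records.copy()
    if "feature_id" in frame.columns:
        frame = frame.sort_values("feature_id", kind="mergesort")
    frame.to_csv(path, sep="\t", index=False, float_format=float_fmt)


def annotations_to_layout_frame(ann: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`read_layout`'s parsing: tidy frame -> writable layout."""
    out = ann.copy()
    out["well"] = [format_well(r, c) for r, c in zip(out["row"], out["col"])]
    return out[["plate_id", "replicate_id", "well", "role", "feature_id"]]
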