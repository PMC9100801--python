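"""Control-anchored normalization of raw plate read-outs.

The pipeline is: log2-transform, summarize per-plate control medians, pick the
positive control whose pooled median sits closest to the high-lethality tail
of the sample distribution, convert every well to a lethality score

    score = (value - med_neg(plate)) / (med_pos(plate) - med_neg(plate))

(0 = negative-control-like viability, 1 = positive-control-like lethality;
the per-plate anchoring is the plate-effect correction), then quantile
normalization across replicates and an optional sign flip to viability scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plate_io import PlateSet

__all__ = [
    "ControlSummary",
    "LethalityMatrix",
    "log2_transform",
    "summarize_controls",
    "select_positive_control",
    "lethality_scores",
    "quantile_normalize",
    "viability_scores",
    "normalize_screen",
]

#: minimum separation of control medians (log2 units) for a plate to be scorable
MIN_CONTROL_SEPARATION = 0.1


def log2_transform(p: PlateSet) -> PlateSet:
    """Return a log2-scale copy; zero or negative readings are a hard error
    (no silent pseudocount)."""
    if p.scale != "raw":
        raise ValueError("PlateSet is already log2-transformed")
    vals = p.wells["value"].to_numpy(float)
    bad = vals <= 0
    if bad.any():
        from .plate_io import format_well

        names = [
            f"{pl}:{format_well(r, c)}"
            for pl, r, c in zip(
                p.wells.loc[bad, "plate_id"],
                p.wells.loc[bad, "row"],
                p.wells.loc[bad, "col"],
            )
        ]
        raise ValueError(f"cannot log2-transform non-positive readings at: {names}")
    wells = p.wells.assign(value=np.log2(vals))
    return PlateSet(
        geometry=p.geometry,
        wells=wells,
        scale="log2",
        missing_plates=list(p.missing_plates),
    )


@dataclass
class ControlSummary:
    """Per-plate control medians plus the pooled sample distribution.

    ``plate_medians`` columns: replicate_id, plate_id, feature_id, median,
    count, iqr.  ``replicate_quantiles`` columns: replicate_id, q01, q05, q50.
    ``sample_values`` holds all pooled log2 sample readings so arbitrary
    quantiles of the sample distribution can be taken downstream.
    """

    plate_medians: pd.DataFrame
    replicate_quantiles: pd.DataFrame
    sample_values: np.ndarray
    neg_control_id: str

    def pooled_control_median(self, feature_id: str) -> float:
        sub = self.plate_medians[self.plate_medians["feature_id"] == feature_id]
        return float(sub["median"].median())

    def control_ids(self) -> list[str]:
        return sorted(self.plate_medians["feature_id"].unique())


def summarize_controls(p: PlateSet, neg_id: str = "C2") -> ControlSummary:
    """Per-plate medians/IQRs of every control feature and pooled sample
    quantiles per replicate.  A plate without the negative control cannot be
    anchored and is a hard error."""
    if p.scale != "log2":
        raise ValueError("summarize_controls expects log2-scale data")
    ctrl = p.wells[p.wells["role"].str.contains("control")]
    if ctrl.empty:
        raise ValueError("no control wells in PlateSet")

    grp = ctrl.groupby(["replicate_id", "plate_id", "feature_id"])["value"]
    med = grp.agg(
        median="median",
        count="size",
        iqr=lambda v: float(np.subtract(*np.percentile(v, [75, 25]))),
    ).reset_index()

    plates = p.wells[["replicate_id", "plate_id"]].drop_duplicates()
    has_neg = med.loc[med["feature_id"] == neg_id, ["replicate_id", "plate_id"]]
    lacking = plates.merge(has_neg, how="left", indicator=True)
    lacking = lacking[lacking["_merge"] == "left_only"]
    if not lacking.empty:
        names = [f"{r}:{pl}" for r, pl in lacking[["replicate_id", "plate_id"]].values]
        raise ValueError(f"plates lacking negative control {neg_id!r}: {names}")
    singletons = med[med["count"] == 1]
    if not singletons.empty:
        warnings.warn(
            f"{len(singletons)} plate-control medians rest on a single well",
            stacklevel=2,
        )

    samples = p.subset("sample")
    rq = (
        samples.groupby("replicate_id")["value"]
        .apply(lambda v: pd.Series(np.percentile(v, [1, 5, 50]), index=["q01", "q05", "q50"]))
        .unstack()
        .reset_index()
    )
    return ControlSummary(
        plate_medians=med,
        replicate_quantiles=rq,
        sample_values=samples["value"].to_numpy(float),
        neg_control_id=neg_id,
    )


def select_positive_control(
    cs: ControlSummary, candidates: list[str], q: float = 0.01
) -> str:
    """Choose the positive control whose pooled median log2 viability is
    closest to the sample distribution's high-lethality ``q``-quantile.

    Ties are broken toward the candidate with lower variance of its per-plate
    medians (then lexicographically), so the selection is deterministic.
    """
    if not candidates:
        raise ValueError("no positive-control candidates supplied")
    med = cs.plate_medians
    n_plates = med[["replicate_id", "plate_id"]].drop_duplicates().shape[0]
    target = float(np.percentile(cs.sample_values, 100 * q))

    rows = []
    for cand in candidates:
        sub = med[med["feature_id"] == cand]
        if sub.shape[0] < n_plates:
            continue  # must be measurable on every scored plate
        pooled = float(sub["median"].median())
        spread = float(sub["median"].var(ddof=1)) if len(sub) > 1 else 0.0
        rows.append((abs(pooled - target), spread, cand))
    if not rows:
        raise ValueError(
            f"no candidate among {candidates} is present on all {n_plates} plates"
        )
    rows.sort()
    return rows[0][2]


@dataclass
class LethalityMatrix:
    """Feature x replicate matrix of control-anchored lethality scores.

    ``scores`` is indexed by feature_id with one column per replicate; NaN
    marks masked entries (missing plate).  ``well_scores`` keeps the scored
    individual wells, controls included, for QC.
    """

    scores: pd.DataFrame
    neg_id: str
    pos_id: str
    well_scores: pd.DataFrame | None = None
    normalized: bool = False

    @property
    def mask(self) -> pd.DataFrame:
        return self.scores.isna()


def lethality_scores(
    p: PlateSet, neg_id: str, pos_id: str, min_separation: float = MIN_CONTROL_SEPARATION
) -> LethalityMatrix:
    """Anchor every well to its own plate's control medians.

    Scoring each plate against its own controls removes additive plate effects
    on the log2 scale by construction.  Plates whose control medians are
    closer than ``min_separation`` log2 units would divide by noise and raise.
    """
    if p.scale != "log2":
        raise ValueError("lethality_scores expects log2-scale data")
    med = (
        p.wells[p.wells["feature_id"].isin([neg_id, pos_id])]
        .groupby(["replicate_id", "plate_id", "feature_id"])["value"]
        .median()
        .unstack("feature_id")
    )
    for cid in (neg_id, pos_id):
        if cid not in med.columns or med[cid].isna().any():
            bad = med.index[med[cid].isna()].tolist() if cid in med.columns else "all"
            raise ValueError(f"plates lacking control {cid!r}: {bad}")
    denom = med[pos_id] - med[neg_id]
    weak = denom.abs() < min_separation
    if weak.any():
        raise ValueError(
            f"uninformative controls (|med_pos - med_neg| < {min_separation}) on "
            f"plates: {med.index[weak].tolist()}"
        )

    wells = p.wells.merge(
        med.rename(columns={neg_id: "_med_neg", pos_id: "_med_pos"}).reset_index(),
        on=["replicate_id", "plate_id"],
    )
    wells["score"] = (wells["value"] - wells["_med_neg"]) / (
        wells["_med_pos"] - wells["_med_neg"]
    )
    samples = wells[wells["role"] == "sample"]
    scores = samples.pivot(index="feature_id", columns="replicate_id", values="score")
    scores = scores.sort_index()
    scores.columns.name = None
    return LethalityMatrix(
        scores=scores,
        neg_id=neg_id,
        pos_id=pos_id,
        well_scores=wells.drop(columns=["_med_neg", "_med_pos"]),
    )


def _reference_quantiles(columns: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Mean of the columns' quantile functions on the grid of the longest."""
    n_ref = max(len(c) for c in columns)
    grid = np.linspace(0.0, 1.0, n_ref)
    acc = np.zeros(n_ref)
    for col in columns:
        s = np.sort(col)
        if len(s) == n_ref:
            acc += s
        else:
            p = np.linspace(0.0, 1.0, len(s))
            acc += np.interp(grid, p, s)
    return grid, acc / len(columns)


def quantile_normalize(m: LethalityMatrix) -> LethalityMatrix:
    """Force every replicate column onto the common reference distribution.

    The reference is the mean of the per-column quantile functions.  Within a
    column ranks are preserved; tied values receive the mean of the reference
    values their positions span; columns shortened by a missing plate are
    mapped through linear interpolation of the reference quantile function.
    Masked entries stay masked.
    """
    scores = m.scores
    if scores.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 replicate columns")
    cols = []
    for name in scores.columns:
        v = scores[name].dropna().to_numpy(float)
        if len(v) < 2:
            raise ValueError(f"replicate {name!r} has fewer than 2 unmasked scores")
        cols.append(v)
    grid, ref = _reference_quantiles(cols)

    out = scores.copy()
    for name in scores.columns:
        obs = scores[name].dropna()
        n = len(obs)
        v = obs.to_numpy(float)
        # would-be reference values by sort position (interpolated when the
        # column is shorter than the reference grid)
        would_be = np.interp(np.linspace(0.0, 1.0, n), grid, ref)
        assigned = np.empty(n)
        assigned[np.argsort(v, kind="mergesort")] = would_be
        # ties receive the mean of the values their positions span
        assigned = pd.Series(assigned).groupby(v).transform("mean").to_numpy()
        out.loc[obs.index, name] = assigned
    return LethalityMatrix(
        scores=out,
        neg_id=m.neg_id,
        pos_id=m.pos_id,
        well_scores=m.well_scores,
        normalized=True,
    )


def viability_scores(m: LethalityMatrix) -> pd.DataFrame:
    """Sign-flipped scores: negative = reduced viability, positive = increased."""
    return -m.scores


def normalize_screen(
    p: PlateSet,
    neg_id: str = "C2",
    pos_control: str | list[str] = "auto",
    candidates: list[str] | None = None,
    quantile: float = 0.01,
) -> tuple[LethalityMatrix, dict]:
    """Full normalization pipeline from a raw PlateSet.

    ``pos_control`` may name a control explicitly or be ``"auto"``, in which
    case it is selected from ``candidates`` (all growth/transfection controls
    by default) by proximity to the sample distribution's lethal tail.
    Returns the quantile-normalized lethality matrix and a QC dict.
    """
    logged = log2_transform(p) if p.scale == "raw" else p
    cs = summarize_controls(logged, neg_id=neg_id)
    if pos_control == "auto":
        if candidates is None:
            candidates = [c for c in cs.control_ids() if c != neg_id]
        pos_id = select_positive_control(cs, candidates, q=quantile)
    else:
        pos_id = pos_control
    lm = lethality_scores(logged, neg_id=neg_id, pos_id=pos_id)
    norm = quantile_normalize(lm)
    qc = {
        "neg_id": neg_id,
        "pos_id": pos_id,
        "plate_medians": cs.plate_medians,
        "replicate_quantiles": cs.replicate_quantiles,
        "missing_plates": list(p.missing_plates),
        "n_features": int(norm.scores.shape[0]),
        "n_replicates": int(norm.scores.shape[1]),
    }
    return norm, qc
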