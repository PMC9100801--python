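"""Validation-screen analysis: panel normalization and threshold classifiers.

Validation plates carry each candidate in duplicate wells alongside a panel of
16 mimics with no growth effect.  Per cell line and per plate type (ULA or
adherent) the mean of a candidate's wells is divided by the mean of all panel
wells, so 1 means negative-panel-like growth.  Two data-driven thresholds then
classify candidates:

* "ULA": among normalized ULA viabilities below 1, the threshold is
  mean + sd of those sub-1 values; a candidate is in the class if its ULA
  viability falls strictly below the threshold.
* "ULA-norm-Ad": the difference d = adherent - ULA is taken per candidate,
  the threshold is the sd of the positive differences, and a candidate joins
  the class if it is already "ULA" and d strictly exceeds that sd.  This
  removes mimics that are simply toxic regardless of anchorage.

Standard errors use first-order propagation for quotients and differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plate_io import PlateSet

__all__ = [
    "ClassificationResult",
    "normalize_to_panel",
    "build_validation_table",
    "classify_ula",
    "classify_ula_norm_ad",
    "classify_cell_line",
    "ratio_with_se",
    "difference_se",
    "dose_response_normalize",
    "relative_growth",
]


def ratio_with_se(
    mean_num: float, se_num: float, mean_den: float, se_den: float
) -> tuple[float, float]:
    """Quotient r = a/b with first-order propagated standard error
    SE(r) = r * sqrt((SE_a/a)^2 + (SE_b/b)^2)."""
    if mean_den <= 0:
        raise ValueError("denominator mean must be positive")
    r = mean_num / mean_den
    se = abs(r) * np.sqrt((se_num / mean_num) ** 2 + (se_den / mean_den) ** 2)
    return float(r), float(se)


def difference_se(se_a: float, se_b: float) -> float:
    """SE of a difference a - b: sqrt(SE_a^2 + SE_b^2)."""
    return float(np.sqrt(se_a**2 + se_b**2))


def _mean_se(values: np.ndarray) -> tuple[float, float, int]:
    n = len(values)
    mean = float(np.mean(values))
    se = float(np.std(values, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, se, n


def normalize_to_panel(
    measurements: PlateSet, neg_panel_ids: list[str], condition: str
) -> pd.DataFrame:
    """Panel-normalized viability per feature for one plate type.

    Duplicate wells are averaged first, then divided by the mean of all panel
    wells pooled across the condition's plates.  Columns: feature_id,
    condition, viability, se, n_wells.
    """
    wells = measurements.wells
    panel = wells[wells["feature_id"].isin(neg_panel_ids)]
    if panel["feature_id"].nunique() < 2:
        raise ValueError("need >= 2 negative-panel features in the measurements")
    panel_vals = panel["value"].to_numpy(float)
    panel_mean, panel_se, _ = _mean_se(panel_vals)
    if panel_mean <= 0:
        raise ValueError("negative-panel mean is not positive")

    records = []
    samples = wells[wells["role"] == "sample"]
    for fid, grp in samples.groupby("feature_id"):
        vals = grp["value"].to_numpy(float)
        if len(vals) < 2:
            raise ValueError(f"feature {fid!r} has fewer than 2 replicate wells")
        f_mean, f_se, n = _mean_se(vals)
        viab, se = ratio_with_se(f_mean, f_se, panel_mean, panel_se)
        records.append((fid, condition, viab, se, n))
    return pd.DataFrame(
        records, columns=["feature_id", "condition", "viability", "se", "n_wells"]
    ).sort_values("feature_id", kind="mergesort", ignore_index=True)


def build_validation_table(
    ula: PlateSet,
    adherent: PlateSet,
    neg_panel_ids: list[str],
    cell_line: str,
) -> pd.DataFrame:
    """Stack panel-normalized ULA and adherent viabilities for one cell line."""
    parts = [
        normalize_to_panel(ula, neg_panel_ids, "ULA"),
        normalize_to_panel(adherent, neg_panel_ids, "adherent"),
    ]
    out = pd.concat(parts, ignore_index=True)
    out.insert(0, "cell_line", cell_line)
    return out


@dataclass
class ClassificationResult:
    """Per-feature labels and the data-driven thresholds that produced them."""

    cell_line: str
    labels: pd.DataFrame  # feature_id, viability_ula, viability_adherent, diff, label
    t_ula: float
    t_diff: float

    @property
    def ula_set(self) -> set[str]:
        return set(self.labels.loc[self.labels["label"] != "not_validated", "feature_id"])

    @property
    def ula_norm_ad_set(self) -> set[str]:
        return set(self.labels.loc[self.labels["label"] == "ULA_norm_Ad", "feature_id"])


def classify_ula(vtable: pd.DataFrame, rule: str = "mean_plus_sd") -> tuple[set[str], float]:
    """Features with reduced ULA growth.

    S is the set of ULA viabilities below 1; the threshold is mean(S) + sd(S)
    (sample sd) under the default rule, or mean(S) - sd(S) under the stricter
    alternative reading (``rule="mean_minus_sd"``).  A feature is "ULA" iff
    its viability is strictly below the threshold.
    """
    ula = vtable[vtable["condition"] == "ULA"]
    below = ula[ula["viability"] < 1.0]
    if len(below) < 3:
        raise ValueError(
            f"only {len(below)} ULA viabilities below 1: threshold undefined"
        )
    s = below["viability"].to_numpy(float)
    if rule == "mean_plus_sd":
        t_ula = float(np.mean(s) + np.std(s, ddof=1))
    elif rule == "mean_minus_sd":
        t_ula = float(np.mean(s) - np.std(s, ddof=1))
    else:
        raise ValueError(f"unknown threshold rule {rule!r}")
    hits = set(ula.loc[ula["viability"] < t_ula, "feature_id"])
    return hits, t_ula


def classify_ula_norm_ad(
    vtable: pd.DataFrame, ula_hits: set[str], diff_sd_over_all: bool = False
) -> tuple[set[str], float]:
    """Subset of ULA hits whose adherent-minus-ULA viability difference
    exceeds one sd of the positive differences.

    Differences are computed over every feature in the table; by default the
    sd is over the positive differences only (``diff_sd_over_all=True``
    switches to all differences).  Membership additionally requires the
    feature to already satisfy the ULA criterion, so the class is always a
    subset of the ULA class.
    """
    wide = vtable.pivot(index="feature_id", columns="condition", values="viability")
    if not {"ULA", "adherent"}.issubset(wide.columns):
        raise ValueError("validation table must contain both ULA and adherent rows")
    d = (wide["adherent"] - wide["ULA"]).dropna()
    d_pos = d[d > 0]
    if len(d_pos) < 3:
        raise ValueError(f"only {len(d_pos)} positive differences: sd undefined")
    t_diff = float(np.std((d if diff_sd_over_all else d_pos).to_numpy(float), ddof=1))
    hits = {f for f in ula_hits if f in d.index and d[f] > t_diff}
    return hits, t_diff


def classify_cell_line(
    vtable: pd.DataFrame,
    cell_line: str,
    rule: str = "mean_plus_sd",
    diff_sd_over_all: bool = False,
) -> ClassificationResult:
    """Run both classifiers for one cell line and assemble labels."""
    sub = vtable[vtable["cell_line"] == cell_line] if "cell_line" in vtable else vtable
    ula_hits, t_ula = classify_ula(sub, rule=rule)
    norm_ad, t_diff = classify_ula_norm_ad(sub, ula_hits, diff_sd_over_all)
    wide = sub.pivot(index="feature_id", columns="condition", values="viability")
    labels = pd.DataFrame(
        {
            "feature_id": wide.index,
            "viability_ula": wide["ULA"].to_numpy(),
            "viability_adherent": wide["adherent"].to_numpy(),
            "diff": (wide["adherent"] - wide["ULA"]).to_numpy(),
        }
    )
    labels["label"] = [
        "ULA_norm_Ad" if f in norm_ad else ("ULA" if f in ula_hits else "not_validated")
        for f in labels["feature_id"]
    ]
    return ClassificationResult(
        cell_line=cell_line, labels=labels.reset_index(drop=True), t_ula=t_ula, t_diff=t_diff
    )


def dose_response_normalize(
    series: pd.DataFrame, reference_id: str = "C2"
) -> pd.DataFrame:
    """Normalize a dilution series to the negative control, per concentration
    and condition.

    ``series`` is tidy with columns feature_id, condition, concentration_nM,
    value (one row per well).  For each (feature, condition, concentration)
    the mean of the feature's wells is divided by the mean of the reference
    wells at the same concentration and condition, with the quotient SE rule.
    """
    required = {"feature_id", "condition", "concentration_nM", "value"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series lacks columns: {sorted(missing)}")
    records = []
    for (cond, conc), grp in series.groupby(["condition", "concentration_nM"]):
        ref = grp.loc[grp["feature_id"] == reference_id, "value"].to_numpy(float)
        if len(ref) < 2:
            raise ValueError(
                f"reference {reference_id!r} needs >= 2 wells at {conc} nM ({cond})"
            )
        ref_mean, ref_se, _ = _mean_se(ref)
        if ref_mean <= 0:
            raise ValueError("reference mean must be positive")
        for fid, fgrp in grp[grp["feature_id"] != reference_id].groupby("feature_id"):
            vals = fgrp["value"].to_numpy(float)
            if len(vals) < 2:
                raise ValueError(f"feature {fid!r} needs >= 2 wells at {conc} nM")
            f_mean, f_se, n = _mean_se(vals)
            r, se = ratio_with_se(f_mean, f_se, ref_mean, ref_se)
            records.append((fid, cond, float(conc), r, se, n))
    out = pd.DataFrame(
        records,
        columns=["feature_id", "condition", "concentration_nM", "viability", "se", "n_wells"],
    )
    return out.sort_values(
        ["feature_id", "condition", "concentration_nM"],
        ascending=[True, True, False],
        kind="mergesort",
        ignore_index=True,
    )


def relative_growth(treated, control) -> tuple[float, float]:
    """Growth of a treated population relative to control (colony counts or
    viability readings alike): quotient of means with propagated SE."""
    t = np.asarray(treated, float)
    c = np.asarray(control, float)
    if len(t) < 2 or len(c) < 2:
        raise ValueError("need >= 2 measurements for treated and control")
    t_mean, t_se, _ = _mean_se(t)
    c_mean, c_se, _ = _mean_se(c)
    if c_mean <= 0:
        raise ValueError("control mean must be positive")
    return ratio_with_se(t_mean, t_se, c_mean, c_se)
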