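import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_plateset, tiny_plate
from ulascreen.plate_io import PlateSet
from ulascreen.screen_normalize import (
    LethalityMatrix,
    log2_transform,
    summarize_controls,
    select_positive_control,
    lethality_scores,
    quantile_normalize,
    viability_scores,
    normalize_screen,
)
from ulascreen.synthetic_data import SyntheticConfig, simulate_screen


# ---------------------------------------------------------------- log2


def test_log2_transform_values_and_scale():
    ps = make_plateset([("P1", "R1", "A", 1, "sample", "m1", 1024.0),
                        ("P1", "R1", "B", 1, "sample", "m2", 1.0)])
    out = log2_transform(ps)
    assert out.scale == "log2"
    assert list(out.wells["value"]) == [10.0, 0.0]


def test_log2_transform_zero_is_error_naming_well():
    ps = make_plateset([("P1", "R1", "A", 1, "sample", "m1", 0.0)])
    with pytest.raises(ValueError, match="P1:A01"):
        log2_transform(ps)


# ---------------------------------------------------------------- control summaries


def _three_plate_set():
    rng = np.random.default_rng(0)
    rows = []
    for i, plate in enumerate(["P1", "P2", "P3"]):
        feats = {f"m{j}": float(2 ** (10 + rng.normal(0, 0.3))) for j in range(6)}
        ctrls = {
            "C2": [2.0 ** (10 + i * 0.1 + d) for d in (-0.05, 0.0, 0.05)],
            "miR-137": [2.0 ** (8 + i * 0.1 + d) for d in (-0.1, 0.0, 0.1)],
        }
        rows += tiny_plate(plate, "R1", feats, ctrls)
    return make_plateset(rows)


def test_per_plate_medians_match_brute_force():
    ps = log2_transform(_three_plate_set())
    cs = summarize_controls(ps)
    for (rep, plate, fid), grp in ps.wells[
        ps.wells["role"].str.contains("control")
    ].groupby(["replicate_id", "plate_id", "feature_id"]):
        row = cs.plate_medians.query(
            "replicate_id == @rep and plate_id == @plate and feature_id == @fid"
        )
        assert len(row) == 1
        assert row["median"].iloc[0] == pytest.approx(np.median(grp["value"]))
        assert row["count"].iloc[0] == len(grp)


def test_plate_median_example_and_single_well_warning():
    rows = tiny_plate("P1", "R1", {"m1": 2.0**9.5},
                      {"C2": [2.0**9, 2.0**10, 2.0**11], "miR-137": [2.0**7]})
    ps = log2_transform(make_plateset(rows))
    with pytest.warns(UserWarning, match="single well"):
        cs = summarize_controls(ps)
    c2 = cs.plate_medians.query("feature_id == 'C2'")
    assert c2["median"].iloc[0] == pytest.approx(10.0)


def test_plate_without_negative_control_is_error():
    rows = tiny_plate("P1", "R1", {"m1": 512.0}, {"miR-137": [128.0, 130.0]})
    ps = log2_transform(make_plateset(rows))
    with pytest.raises(ValueError, match="C2"):
        summarize_controls(ps)


# ---------------------------------------------------------------- positive-control selection


def test_transfection_control_below_sample_range_is_not_selected(small_screen):
    """The essential-gene control kills beyond the lethal sample tail, so the
    growth control sitting at the sample 1st percentile wins."""
    _, plateset, _, design = small_screen
    cs = summarize_controls(log2_transform(plateset))
    chosen = select_positive_control(cs, list(design.pos_control_candidates))
    assert chosen == "miR-137"


def test_single_candidate_is_returned(small_screen):
    _, plateset, _, _ = small_screen
    cs = summarize_controls(log2_transform(plateset))
    assert select_positive_control(cs, ["UBB"]) == "UBB"


def test_equidistant_candidates_tie_break_is_order_independent():
    rows = []
    for plate, off in (("P1", 0.0), ("P2", 0.2)):
        feats = {f"m{j}": 2.0 ** (10 + off - j * 0.01) for j in range(8)}
        ctrls = {
            "C2": [2.0 ** (10 + off)] * 3,
            # equidistant from the sample q-quantile; "steady" has zero spread
            "steady": [2.0 ** (9.0 + off)] * 3,
            "wobbly": [2.0 ** (9.0 + off + (0.3 if plate == "P1" else -0.3))] * 3,
        }
        rows += tiny_plate(plate, "R1", feats, ctrls)
    ps = log2_transform(make_plateset(rows))
    cs = summarize_controls(ps)
    q = 0.0  # target = sample minimum; both candidates sit 1 log2 unit below-ish
    a = select_positive_control(cs, ["steady", "wobbly"], q=q)
    b = select_positive_control(cs, ["wobbly", "steady"], q=q)
    assert a == b == "steady"  # lower variance across plates wins the tie


def test_candidate_absent_from_a_plate_is_error():
    rows = tiny_plate("P1", "R1", {"m1": 512.0},
                      {"C2": [512.0] * 2, "miR-137": [128.0] * 2})
    rows += tiny_plate("P2", "R1", {"m2": 512.0}, {"C2": [512.0] * 2})
    ps = log2_transform(make_plateset(rows))
    cs = summarize_controls(ps)
    with pytest.raises(ValueError, match="present on all"):
        select_positive_control(cs, ["miR-137"])


# ---------------------------------------------------------------- lethality scores


def test_anchor_points_and_formula_example():
    # med_neg = 10, med_pos = 8: v=10 -> 0, v=8 -> 1, v=9 -> 0.5
    feats = {"at_neg": 2.0**10, "at_pos": 2.0**8, "mid": 2.0**9}
    ctrls = {"C2": [2.0**10] * 3, "miR-137": [2.0**8] * 3}
    ps = log2_transform(make_plateset(tiny_plate("P1", "R1", feats, ctrls)))
    lm = lethality_scores(ps, "C2", "miR-137")
    s = lm.scores["R1"]
    assert s["at_neg"] == pytest.approx(0.0)
    assert s["at_pos"] == pytest.approx(1.0)
    assert s["mid"] == pytest.approx(0.5)


def test_noise_free_scores_recover_true_effects(noise_free_screen):
    _, plateset, truth, _ = noise_free_screen
    lm = lethality_scores(log2_transform(plateset), "C2", "miR-137")
    expected = truth.set_index("feature_id")["true_effect_ula"]
    for rep in lm.scores.columns:
        np.testing.assert_allclose(
            lm.scores[rep].to_numpy(), expected[lm.scores.index].to_numpy(), atol=1e-12
        )


def test_control_median_scores_are_exact_anchors(small_screen):
    """Per plate, the median score of the negative control is exactly 0 and
    of the chosen positive control exactly 1, before quantile normalization."""
    _, plateset, _, _ = small_screen
    lm = lethality_scores(log2_transform(plateset), "C2", "miR-137")
    ws = lm.well_scores
    for (rep, plate), grp in ws.groupby(["replicate_id", "plate_id"]):
        assert np.median(grp.loc[grp["feature_id"] == "C2", "score"]) == pytest.approx(0.0, abs=1e-12)
        assert np.median(grp.loc[grp["feature_id"] == "miR-137", "score"]) == pytest.approx(1.0, abs=1e-12)


def test_uninformative_controls_raise():
    feats = {"m1": 2.0**10}
    ctrls = {"C2": [2.0**10] * 2, "miR-137": [2.0**10.01] * 2}
    ps = log2_transform(make_plateset(tiny_plate("P1", "R1", feats, ctrls)))
    with pytest.raises(ValueError, match="uninformative"):
        lethality_scores(ps, "C2", "miR-137")


@settings(max_examples=25, deadline=None)
@given(
    shift=st.floats(-3, 3, allow_nan=False),
    scale=st.floats(0.1, 10, allow_nan=False),
)
def test_scores_invariant_to_plate_shift_and_global_rescale(shift, scale):
    """Additive per-plate shifts on the log2 scale and global multiplicative
    rescaling of raw values cancel in the anchored score."""
    feats = {"m1": 700.0, "m2": 300.0, "m3": 950.0}
    ctrls = {"C2": [1000.0, 1100.0, 900.0], "miR-137": [250.0, 240.0, 260.0]}
    base = make_plateset(tiny_plate("P1", "R1", feats, ctrls))
    lm0 = lethality_scores(log2_transform(base), "C2", "miR-137")

    shifted = base.wells.copy()
    shifted["value"] = shifted["value"] * scale * (2.0**shift)
    ps = PlateSet(geometry=96, wells=shifted)
    lm1 = lethality_scores(log2_transform(ps), "C2", "miR-137")
    pd.testing.assert_frame_equal(lm0.scores, lm1.scores, atol=1e-9, rtol=0)


def test_missing_plate_masks_its_features():
    cfg = SyntheticConfig(n_features=40, plates_per_replicate=2, seed=8,
                          drop_plate=("R2", "P01"))
    ps, _, _ = simulate_screen(cfg)
    lm = lethality_scores(log2_transform(ps), "C2", "miR-137")
    masked = lm.scores["R2"].isna()
    assert masked.sum() > 0
    # masked features are exactly those assigned to the dropped plate
    on_p1 = set(
        ps.wells.query("replicate_id == 'R1' and plate_id == 'P01' and role == 'sample'")[
            "feature_id"
        ]
    )
    assert set(lm.scores.index[masked]) == on_p1


# ---------------------------------------------------------------- quantile normalization


def _qn_oracle(mat):
    """Brute-force quantile normalization for equal-length, NaN-free columns:
    reference = mean of sorted columns; ties get the mean of their would-be
    reference values."""
    mat = np.asarray(mat, float)
    ref = np.sort(mat, axis=0).mean(axis=1)
    out = np.empty_like(mat)
    for j in range(mat.shape[1]):
        col = mat[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average ties
        for v in np.unique(col):
            m = col == v
            assigned[m] = assigned[m].mean()
        out[:, j] = assigned
    return out


def _lm(frame):
    return LethalityMatrix(scores=frame, neg_id="C2", pos_id="miR-137")


def test_quantile_normalize_worked_example():
    frame = pd.DataFrame({"R1": [1.0, 2.0, 3.0], "R2": [2.0, 4.0, 6.0]},
                         index=["a", "b", "c"])
    out = quantile_normalize(_lm(frame)).scores
    assert list(out["R1"]) == [1.5, 3.0, 4.5]
    assert list(out["R2"]) == [1.5, 3.0, 4.5]


def test_quantile_normalize_identical_columns_is_identity():
    frame = pd.DataFrame({"R1": [0.3, -0.1, 0.9], "R2": [0.3, -0.1, 0.9]},
                         index=["a", "b", "c"])
    out = quantile_normalize(_lm(frame)).scores
    pd.testing.assert_frame_equal(out, frame)


def test_quantile_normalize_matches_brute_force_oracle():
    rng = np.random.default_rng(17)
    for _ in range(250):
        n, k = rng.integers(3, 12), rng.integers(2, 5)
        mat = rng.normal(size=(n, k))
        if rng.random() < 0.3:  # inject ties
            mat[rng.integers(n), :] = mat[0, :]
            mat = np.round(mat, 1)
        frame = pd.DataFrame(mat, columns=[f"R{j}" for j in range(k)],
                             index=[f"f{i}" for i in range(n)])
        out = quantile_normalize(_lm(frame)).scores.to_numpy()
        np.testing.assert_allclose(out, _qn_oracle(mat), atol=1e-10)


def test_quantile_normalize_defining_properties():
    rng = np.random.default_rng(23)
    mat = rng.normal(size=(40, 3))
    mat[rng.integers(0, 40, 5), 1] = np.nan  # shorter column via mask
    frame = pd.DataFrame(mat, columns=["R1", "R2", "R3"],
                         index=[f"f{i}" for i in range(40)])
    out = quantile_normalize(_lm(frame)).scores
    # masks preserved
    assert out.isna().equals(frame.isna())
    # within-column rank order preserved
    for c in out.columns:
        a, b = frame[c].dropna(), out[c].dropna()
        assert (a.rank() == b.rank()).all()
    # full-length columns share identical sorted values; means all equal
    s1 = np.sort(out["R1"].to_numpy())
    s3 = np.sort(out["R3"].to_numpy())
    np.testing.assert_allclose(s1, s3, atol=1e-12)
    means = out.mean()
    assert means.max() - means.min() < 0.05  # short column interpolates the same reference


def test_quantile_normalize_short_column_errors():
    frame = pd.DataFrame({"R1": [1.0, 2.0, 3.0], "R2": [np.nan, np.nan, 1.0]},
                         index=["a", "b", "c"])
    with pytest.raises(ValueError, match="fewer than 2"):
        quantile_normalize(_lm(frame))


# ---------------------------------------------------------------- viability


def test_viability_is_negation_and_involution():
    frame = pd.DataFrame({"R1": [1.0, -0.3], "R2": [0.0, 0.7]}, index=["a", "b"])
    lm = _lm(frame)
    v = viability_scores(lm)
    assert v.loc["a", "R1"] == -1.0
    assert v.loc["b", "R1"] == 0.3
    pd.testing.assert_frame_equal(-v, frame)


# ---------------------------------------------------------------- pipeline


def test_normalize_screen_qc_reports_selection(small_screen):
    _, plateset, _, _ = small_screen
    matrix, qc = normalize_screen(plateset)
    assert qc["pos_id"] == "miR-137"
    assert matrix.normalized
    assert matrix.scores.shape == (120, 3)
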