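"""Empirical-Bayes moderated testing of normalized lethality scores.

After normalization the negative control is anchored at 0 on every plate, so
each feature's replicate scores are tested against 0 with a one-sample
moderated t-statistic: per-feature sample variances are shrunk toward a
pooled prior (d0, s0^2) estimated by the method of moments on log-variances,
and the resulting t has d0 + d_g degrees of freedom.  Hits are features with
Benjamini-Hochberg q-value strictly below alpha; the sign of the (negated)
viability score gives the direction.

A two-sample variant, testing feature scores against the pooled scores of the
negative-control wells, is available for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .screen_normalize import LethalityMatrix

__all__ = [
    "EBayesFit",
    "feature_stats",
    "ebayes_shrink",
    "moderated_test",
    "bh_fdr",
    "call_hits",
    "volcano_table",
    "screen_hits",
]


def feature_stats(scores: pd.DataFrame | LethalityMatrix) -> tuple[pd.DataFrame, list[str]]:
    """Per-feature mean, sample variance and residual df of replicate scores.

    One-sample formulation against the 0 anchor: for ``n_g`` unmasked
    replicates the variance has ``d_g = n_g - 1`` degrees of freedom.
    Features with fewer than 2 unmasked replicates cannot contribute a
    variance and are excluded; their ids are returned separately.
    """
    frame = scores.scores if isinstance(scores, LethalityMatrix) else scores
    n = frame.notna().sum(axis=1)
    excluded = sorted(frame.index[n < 2])
    kept = frame[n >= 2]
    out = pd.DataFrame(
        {
            "mean": kept.mean(axis=1, skipna=True),
            "s2": kept.var(axis=1, ddof=1, skipna=True),
            "df": n[n >= 2] - 1,
            "n": n[n >= 2],
        }
    )
    return out, excluded


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x <= 0:
        raise ValueError("trigamma inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(100):
        tri = float(special.polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += step
        if abs(step) < 1e-8 * y:
            break
    return y


@dataclass
class EBayesFit:
    """Hyperparameters and posterior variances of the variance prior.

    ``d0`` may be ``inf`` (no excess variability between features: every
    posterior variance equals ``s0_sq``) or 0 (no shrinkage).
    """

    d0: float
    s0_sq: float
    s_tilde_sq: np.ndarray
    df_total: np.ndarray

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValueError("prior variance must be positive")


def ebayes_shrink(variances, dfs, d0_override: float | None = None) -> EBayesFit:
    """Estimate (d0, s0^2) and shrink per-feature variances toward the prior.

    Method of moments on log variances: the excess of var(log s_g^2) over its
    chi-square sampling component identifies trigamma(d0/2).  If there is no
    excess, d0 = inf and all posterior variances collapse to the prior.
    Zero variances join the shrinkage like any other (their log is excluded
    from the hyperparameter fit) so no statistic becomes infinite.
    ``d0_override`` forces a given prior df (0 disables shrinkage entirely).
    """
    s2 = np.asarray(variances, float)
    df = np.broadcast_to(np.asarray(dfs, float), s2.shape).astype(float)
    if np.all(s2 == 0):
        raise ValueError("all variances are zero: degenerate input")
    pos = s2 > 0
    if pos.sum() < 10 and d0_override is None:
        raise ValueError("need >= 10 positive-variance features to fit the prior")

    if d0_override is not None:
        d0 = float(d0_override)
        s0_sq = float(np.median(s2[pos])) if pos.any() else 1.0
    else:
        z = np.log(s2[pos])
        dg = df[pos]
        e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
        e_mean = float(np.mean(e))
        e_var = float(np.var(e, ddof=1)) - float(np.mean(special.polygamma(1, dg / 2.0)))
        if e_var > 0:
            d0 = 2.0 * _trigamma_inverse(e_var)
            s0_sq = float(np.exp(e_mean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        else:
            d0 = np.inf
            s0_sq = float(np.exp(e_mean))

    if np.isinf(d0):
        s_tilde = np.full_like(s2, s0_sq)
    elif d0 == 0:
        s_tilde = s2.copy()
    else:
        s_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
    return EBayesFit(d0=d0, s0_sq=s0_sq, s_tilde_sq=s_tilde, df_total=df + d0)


def moderated_test(means, fit: EBayesFit, n_g) -> tuple[np.ndarray, np.ndarray]:
    """Moderated one-sample t against 0 and its two-sided p-value.

    t = mean / sqrt(s_tilde^2 / n); reference distribution t with d0 + d_g
    degrees of freedom, collapsing to the normal when d0 is infinite.
    """
    mean = np.asarray(means, float)
    n = np.broadcast_to(np.asarray(n_g, float), mean.shape)
    se = np.sqrt(fit.s_tilde_sq / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, np.where(mean == 0, 0.0, np.inf * np.sign(mean)))
    if np.isinf(fit.d0):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), fit.df_total)
    return t, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, original order restored."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def call_hits(
    viability_means, q_values, feature_ids, alpha: float = 0.01, extra: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Assemble the hit table: direction by sign of the mean viability score
    among features with q strictly below ``alpha`` (q = alpha is not a hit)."""
    v = np.asarray(viability_means, float)
    q = np.asarray(q_values, float)
    sig = q < alpha
    direction = np.where(~sig, "none", np.where(v < 0, "decreased", "increased"))
    table = pd.DataFrame(
        {
            "feature_id": list(feature_ids),
            "viability_score": v,
            "q_value": q,
            "direction": direction,
            "hit": sig,
        }
    )
    if extra is not None:
        table = table.merge(extra, on="feature_id", how="left")
    return table.sort_values(
        ["q_value", "viability_score"],
        key=lambda c: c.abs() if c.name == "viability_score" else c,
        ascending=[True, False],
        kind="mergesort",
    ).reset_index(drop=True)


def volcano_table(hits: pd.DataFrame, out_png: str | None = None) -> pd.DataFrame:
    """Plot-ready (viability score, -log10 q, hit flag) table; optionally
    renders the volcano plot to ``out_png``."""
    tbl = pd.DataFrame(
        {
            "feature_id": hits["feature_id"],
            "viability_score": hits["viability_score"],
            "neg_log10_q": -np.log10(hits["q_value"].clip(lower=np.finfo(float).tiny)),
            "hit": hits["hit"],
        }
    )
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        colors = np.where(
            ~tbl["hit"], "0.6", np.where(tbl["viability_score"] < 0, "crimson", "seagreen")
        )
        ax.scatter(tbl["viability_score"], tbl["neg_log10_q"], s=8, c=colors, lw=0)
        ax.axhline(2.0, color="red", ls="--", lw=1)  # q = 0.01
        ax.set_xlabel("viability score")
        ax.set_ylabel("-log10 FDR")
        fig.savefig(out_png, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return tbl


def screen_hits(
    m: LethalityMatrix,
    alpha: float = 0.01,
    d0_override: float | None = None,
    two_sample: bool = False,
) -> tuple[pd.DataFrame, EBayesFit]:
    """Moderated testing of a normalized lethality matrix end to end.

    Returns the hit table (sorted by q, then effect size) and the prior fit.
    With ``two_sample=True`` each feature is contrasted against the pooled
    negative-control well scores instead of the 0 anchor; the control sum of
    squares enters the residual variance and df.
    """
    if not m.normalized:
        import warnings

        warnings.warn("testing un-normalized lethality scores", stacklevel=2)
    st, excluded = feature_stats(m)
    if two_sample:
        if m.well_scores is None:
            raise ValueError("two-sample test needs well-level control scores")
        ctrl = m.well_scores
        ctrl = ctrl.loc[ctrl["feature_id"] == m.neg_id, "score"].to_numpy(float)
        if ctrl.size < 2:
            raise ValueError("two-sample test needs >= 2 negative-control wells")
        n_c = ctrl.size
        ss_c = float(np.sum((ctrl - ctrl.mean()) ** 2))
        n_g = st["n"].to_numpy(float)
        pooled_s2 = (st["s2"].to_numpy() * st["df"].to_numpy() + ss_c) / (
            n_g + n_c - 2
        )
        fit = ebayes_shrink(pooled_s2, n_g + n_c - 2, d0_override=d0_override)
        mean_diff = st["mean"].to_numpy() - ctrl.mean()
        se_scale = 1.0 / n_g + 1.0 / n_c
        t, p = moderated_test(mean_diff, fit, 1.0 / se_scale)
    else:
        fit = ebayes_shrink(st["s2"], st["df"], d0_override=d0_override)
        t, p = moderated_test(st["mean"], fit, st["n"])
    q = bh_fdr(p)
    extra = pd.DataFrame(
        {
            "feature_id": st.index,
            "lethality_score": st["mean"].to_numpy(),
            "moderated_t": -t,  # on the viability scale, matching the score sign
            "p_value": p,
            "n_replicates": st["n"].to_numpy(int),
        }
    )
    hits = call_hits(-st["mean"].to_numpy(), q, st.index, alpha=alpha, extra=extra)
    hits.attrs["excluded_features"] = excluded
    return hits, fit
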