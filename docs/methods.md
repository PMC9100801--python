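# Methods

## Generative model of the synthetic screens

Every raw reading is built on the log2 scale as

    log2(F_wrp) = baseline + a_r + b_pr − e(feature) · Δ + ε_wrp

with replicate shift a_r ~ N(0, σ_rep²), plate offset b_pr ~ N(0, σ_plate²),
and lognormal measurement noise ε ~ N(0, σ_noise²). Δ is the log2 viability
gap between the negative control (effect 0) and a full-strength growth
suppressor (effect 1); effects therefore live on the same unitless scale as
the lethality score, which makes parameter recovery closed-form: with all
variance components zero the lethality score of a feature with effect *e*
equals *e* exactly on every replicate (this is asserted to machine precision
in the suite).

Defaults, chosen once as plausible bench values and exposed in
`SyntheticConfig` (the generator does not claim they are any particular
study's values):

| parameter | default | meaning |
|---|---|---|
| n_features / n_replicates / plates_per_replicate | 2019 / 3 / 26 | primary-screen design |
| Δ (`delta_log2`) | 2.0 | 4-fold kill by a full-strength suppressor |
| σ_noise (`noise_sd`) | 0.15 | per-well log2 CV ≈ 10%, typical of CellTiter read-outs |
| σ_plate (`plate_effect_sd`) | 0.2 | per-plate intensity offsets |
| σ_rep (`replicate_shift_sd`) | 0.3 | day-to-day replicate shifts |
| `baseline_log2` | 14.0 | raw fluorescence ≈ 16 000 units |
| `frac_suppressors` | 0.05 | ≈ 100 true suppressors per screen |
| `effect_grid` | 0.25, 0.5, 1.0 | graded effect strengths, equal shares |
| `ula_specific_fraction` | 0.6 | share of suppressors acting only without anchorage |

Controls per 96-well plate: C2 ×6 (non-targeting negative), miR-137 ×3
(effect 1.0), miR-129-2-3p ×3 (effect 0.8), UBB siRNA ×3 (effect 1.3 — the
essential-gene transfection control is deliberately stronger than the
growth controls so positive-control selection has something to
discriminate). Sample wells fill each plate row-major (77–78 features per
plate), controls occupy the right-hand columns; real layouts are
user-supplied, so the fixed placement only matters for the generator.

Randomness is hierarchical (seed → replicate → plate streams), so omitting
one plate — e.g. the `drop_plate=("R2","P07")` failure mode — removes
exactly that plate's readings without perturbing any other draw. Plate
stream keys come from plate-id digits or crc32, never Python's salted
string hash, so output is bit-reproducible across processes.

What the generator does **not** emulate: within-plate spatial gradients and
edge effects, carry-over between plates, transfection-efficiency
heterogeneity between wells, or cell-line-specific biology beyond effect
sizes. Passing tests therefore demonstrate correctness of the statistical
pipeline under its own model assumptions — additive plate effects on the
log2 scale and exchangeable noise — not robustness to spatial artefacts,
which would need B-score/median-polish corrections that are deliberately out
of scope.

## Normalization

Lethality scores anchor each well to its own plate's control **medians**
(robust to a single aberrant control well; counts are reported for QC).
Plates whose control medians are separated by less than 0.1 log2 units are
rejected rather than scored: below measurement noise the score denominator
divides by noise. The anchored score is invariant to per-plate additive
shifts on the log2 scale and to global multiplicative rescaling of raw
values (property-tested).

Quantile normalization is applied to pooled per-replicate vectors (all
plates of a replicate concatenated), equalizing the score distributions
*between replicates*; the per-plate variant is a plausible alternative but
plate effects are already handled by the anchoring, so pooling is the
default and the choice is localized in one function. The reference
distribution is the mean of the per-column quantile functions; a column
shortened by a missing plate is mapped through linear interpolation of the
reference quantile function; ties receive the mean of the reference values
their sort positions span (deterministic); masked entries stay masked.
Features retaining fewer than two unmasked replicates are excluded from
testing and reported.

Positive-control selection: the candidate whose pooled median log2 viability
is nearest the sample distribution's 1st percentile (the lethal tail), with
ties broken toward the candidate with the lower variance of per-plate
medians, then lexicographically — fully deterministic.

## Moderated testing

One-sample formulation by default: normalization centres the negative
control at 0 on every plate, so feature scores are tested directly against
that anchor. A two-sample variant (feature replicates vs pooled
negative-control well scores, equal-variance, d_g = n_g + n_c − 2 entering
moderation) is available via `screen_hits(..., two_sample=True)` for
sensitivity analysis; on well-separated synthetic effects both variants
recover the same hits.

Hyperparameters (d₀, s₀²) are fitted by the method of moments on
log-variances: the excess of var(log s_g²) over its chi-square sampling
component identifies trigamma(d₀/2), inverted by Newton iteration
(tolerance 1e-8); no excess ⇒ d₀ = ∞ and all posterior variances collapse
to s₀². Zero sample variances are excluded from the hyperparameter fit but
shrunk like any other feature, so no statistic is infinite when d₀ > 0. The
implementation is cross-checked in the suite against the Bioconductor
reference implementation of moderated t-statistics (agreement < 1e-9 on t,
hyperparameters to 8 significant digits) and against closed-form limits
(d₀→0 gives the ordinary t; d₀=∞ gives a z-statistic).

Benjamini–Hochberg q-values follow the step-up definition
q_(i) = min_{j≥i} m·p_(j)/j capped at 1, verified against a brute-force
implementation and statsmodels. Hits use the strict inequality q < 0.01; a
feature at exactly q = 0.01 is not a hit.

## Validation classifiers

Panel normalization divides the mean of a candidate's duplicate wells by the
mean of all 16 negative-panel wells pooled per condition (averaging before
dividing; the per-plate panel variant would matter only with multiple
validation plates per condition). SEs propagate first-order:
SE(a/b) = |a/b|·sqrt((SE_a/a)² + (SE_b/b)²) and
SE(a−b) = sqrt(SE_a² + SE_b²) — accurate to <5% against Monte-Carlo when
all CVs are below 0.1 (tested).

The "ULA" threshold is implemented literally as T = mean(S) + sd(S) over the
sub-1 viabilities S with the sample (n−1) sd, hit iff viability < T
(strict). The wording admits a stricter reading, mean − sd, which is kept
available as `rule="mean_minus_sd"`. The "ULA-norm-Ad" threshold is the
sample sd of the positive adherent−ULA differences (the alternative, sd over
all differences, sits behind `diff_sd_over_all=True`); membership
additionally requires the ULA label, so ULA-norm-Ad ⊆ ULA holds by
construction and is asserted on every run. Both thresholds are data-driven:
with mostly-null candidate lists the ULA threshold drifts up toward 1 and
plain-ULA specificity degrades gracefully, while the difference criterion
stays discriminative — the classifier-fidelity test therefore targets the
ULA-norm-Ad labels, at an effect-to-noise separation comfortably above the
regime where a data-driven sd threshold is reliable.

## Reporting

Cross-cell-line intersection groups features by their exact membership
pattern; final hits are features validated in ≥2 cell lines (configurable).
Feature ids are compared case-insensitively after trimming because miRNA
nomenclature capitalization varies between tables. A published overlap
table of 40 validated anchorage-independence suppressors across SiHa, HeLa
and FK18B cervical/keratinocyte cell lines ships as a packaged TSV fixture;
intersecting its per-line sets reproduces the 22/5/11/2 pattern counts and
is part of the acceptance checks.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run screens at the full primary
design (2019 features × 3 replicates × 26 plates — a single screen
normalizes and tests in well under a second) and use 10–20 replicate null
screens for the false-positive-rate estimate, 500 random instances per
brute-force oracle comparison, and 1e5–2e5 Monte-Carlo draws for SE checks.
All randomness flows from explicit seeds; reruns are bit-identical.

## Known limitations

* No spatial (row/column/edge) correction; screens with strong gradients
  need an upstream B-score step before this pipeline.
* The moderated test assumes exchangeable replicate noise after quantile
  normalization; severe replicate-specific variance heterogeneity is only
  partially absorbed.
* The validation thresholds are those of the published rule — data-driven
  sds without an error model — so their operating characteristics depend on
  the composition of the candidate list, as noted above.
* Dose-response output reports normalized viabilities per dilution point;
  no IC50 curve fitting is attempted.
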