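# Methods

This note records the model behind `platescreen`, the parameters that
matter, the numerical choices, and what the synthetic-data tests do and do
not establish about real screens.

## Data model and assumptions

A screen is a set of experimental plates paired one-to-one (by order and
plate number) with control plates of identical strain layout, in one of
the standard densities (8×12, 16×24, 32×48). Colony sizes are treated as
multiplicative: size ≈ baseline × plate effect × positional effect ×
strain effect × lognormal noise. Under that model the log growth ratio
LGR = ln(control/experiment) is additive in the effects and normally
distributed, which justifies (a) taking the logarithm per colony before
averaging over replicates rather than after, and (b) median-ratio
corrections for the nuisance terms.

The key file is the single source of truth for strain layout. Replicates
are grouped by identical ID within a plate, not by assumed quadrant
geometry, so any replicate arrangement the key describes is supported.
Positions absent from the key are ignored; positions in the key but
missing from the data are counted and logged.

## Normalization and smoothing

* **Plate-median normalization** divides by the median of non-missing
  sizes. It assumes fewer than half the colonies on a plate are affected;
  when that fails the median tracks the affected population, so the
  `none` mode and control-median mode exist as alternatives.
* **Control-median normalization** divides by the median of live (> 0)
  `Control`-keyed colonies and requires at least 3 of them per plate — a
  median anchored on fewer points is too fragile. The count is a package
  choice, configurable via `min_live_controls`.
* **Spatial smoothing** is a multiplicative row/column-median correction:
  cell ÷ (row median / plate median) ÷ (column median / plate median),
  re-divided by its own median so the plate median returns to 1. It
  inverts an exact multiplicative row×column bias perfectly and is
  idempotent there; it is deliberately the simplest position-based
  correction consistent with row/column QC plots, and is isolated behind
  one function so a surface-fitting variant could replace it.
  Whole-missing rows or columns get a factor of 1 and a logged warning.

  **Caveat (important):** a median-based correction cannot distinguish
  real biology from spatial artifact once ≥ ~half the colonies in one row
  or column are truly affected — the row median then absorbs part of the
  effect and the recovered LGRs shrink. Smoothing (and plate-median
  normalization) should only be enabled when most colonies are expected
  unaffected; the simulator scatters planted strains randomly over the
  plate for exactly this reason, since regular or clustered placement
  lines hits up in shared rows/columns and triggers this failure mode.
* **Size floor** ε = 0.01 (plate-median units) is applied after
  normalization and smoothing, immediately before logarithms; it bounds a
  dead colony's LGR at ln(1/ε) ≈ 4.6 instead of infinity. ε must stay
  below the control-dead threshold so flooring can never mask a dead
  control.
* **Control-dead flagging** uses a strict `<` against 0.30 of the plate
  median (configurable), evaluated on the *control* plate's normalized
  (and, if enabled, smoothed) size. Flagged replicates are reported in
  the replicates file with their normalized sizes but excluded from mean
  LGRs and tests; the rule exists to drop positions where the comparison
  itself is meaningless because the control failed.

## Replicate testing and screen-wide statistics

The per-strain test is a two-sided pooled-variance Student's t-test of
the non-excluded control replicate sizes against the experimental ones
(df = n₁ + n₂ − 2). The alternative — a one-sample t-test on per-replicate
LGRs — is defensible, but the two-sample form uses all 2n observations
and matches the conventions of earlier colony-screen tools. p is missing
when either side has < 2 replicates or when a zero pooled variance meets
unequal means; identical constant samples give p = 1. The pipeline
computes these t-tests vectorised across strains; the scalar
`replicate_p_value` is the reference form and the two are cross-checked
in tests against `scipy.stats.ttest_ind`.

Benjamini–Hochberg runs once per analysis over all strains with a
non-missing p (m = their count): the screen is the natural testing
family, and per-plate correction would make q depend on plate layout.
Z-scores standardize mean LGRs with the sample (n−1) standard deviation
over the whole run. If every mean LGR is identical — which happens only
on noiseless synthetic data — the pipeline reports Z = 0 with a warning
rather than failing; the standalone `z_scores` function still raises on
zero variance.

Merging two controls joins on (Plate, ID): `avg_LGR` is the mean of the
two per-control mean LGRs and is missing unless both are present and
unexcluded (the merge exists to demand concordance); `max_p`/`max_q` are
maxima, never Fisher-combined, because the two comparisons share the
experimental data and are not independent; the merged Z-score is
recomputed from the avg_LGR distribution rather than averaged, so it
remains a genuine standardization.

## Mixture model

Mean (or merged) LGRs of screens with many growth defects are bimodal: a
central peak of unaffected strains and a hit peak at higher LGRs. A
two-component univariate Gaussian mixture is fit by EM with free
variances: responsibilities from weighted normal densities (computed in
log space), closed-form M-step, absolute log-likelihood improvement
< 1e-8 as convergence, ≤ 1000 iterations, variances floored at 1e-6 to
prevent collapse. Initialization anchors component 1 at the data median
with a MAD-based scale (screens are mostly null) and component 2 at the
90th percentile, weights (0.9, 0.1); 10 restarts perturb both means by
seeded Gaussian noise of 0.5 scale units and the best final likelihood
wins. Components are relabelled so component 2 has the higher mean.

The per-strain quantity is the posterior probability of the hit
component, q(x) = w₂φ₂(x) / (w₁φ₁(x) + w₂φ₂(x)), evaluated in logistic
form so an exact density tie gives exactly 0.5. The hit cut-off is the
root of q(x) = 0.5, bracketed between the component means (widened by
10 sd per side, with a grid-scan fallback when the posterior is
non-monotone because the variances differ) and solved by bisection to
1e-8; the smallest *observed* LGR reaching q ≥ 0.5 is reported beside the
continuous root. Strains are called hits at q ≥ 0.5 inclusive. No
further FDR adjustment is applied to q(x): it is a posterior probability,
not a frequentist q-value, and the mixture is fit to the non-excluded
mean LGRs only. Model selection (1 vs 2 components, heavier-tailed
families) is out of scope; the user chooses to run the mixture tool when
the histogram looks bimodal.

## Synthetic screens

`simulate_screen` generates: control size = baseline × plate multiplier ×
edge(r, c) × lognormal noise; experimental size = baseline × its own
plate multiplier × exp(−δ_strain) × independent noise, so a planted
strain's true LGR is exactly δ. Defaults are the conditions of a
full-scale screen: 1536 density, 17 plates, 4 replicates (6,528 strains),
noise σ = 0.1, plate-effect σ = 0.1, edge amplitude 0.3, failure rate
0.01 (a plausible robot-pinning miss rate), two controls, baseline 500
area units.

Choices worth stating:

* The **edge gradient** (border rows/columns × (1 + amplitude)) is
  applied to control plates only. A gradient identical on both members of
  a pair cancels exactly in every LGR and would make spatial correction
  pointless; a condition-specific gradient is the situation in which
  smoothing earns its keep, and one-sided application gives it a known
  sign and magnitude (border LGR bias = ln(1 + amplitude) without
  smoothing).
* **Planted strains are scattered** with a seeded random permutation over
  the replicate-block grid (see the smoothing caveat above).
* **Pinning failures zero the colony** (they are observations of a dead
  colony, not missing data) and are applied to control plates, so the
  control-dead rule is exercised; failed positions are recorded in the
  ground truth.
* An optional **control-1 artifact** inflates chosen strains' colonies on
  the first control only, producing single-control false hits that the
  two-control merge should remove.
* All draws come from one `numpy` PCG64 generator in a fixed order
  (layout permutation; plate multipliers per condition; per plate: noise
  fields and failure masks), so one seed reproduces the written input
  files byte for byte.

What the simulator does **not** emulate: nutrient competition between
neighbouring colonies, growth kinetics over time, agar-surface gradients
other than the border step, size-dependent measurement error, and
spatially correlated pinning failures. Passing tests therefore establish
that the algorithms invert the effects in this generative model, not that
real plates contain no other structure.

## Problem sizes and numerical conventions

The test suite and acceptance script run everything at the scales the
statistics need rather than the largest possible: property checks on
96/384 plates; hit-recovery at 1 × 1536 plate with 16 replicates over 20
seeds (sensitivity ≥ 0.99 and false-positive rate ≤ 0.01 at LGR ≥ 0.4 for
δ = 0.8, σ = 0.1); mixture recovery on 5,000 draws of
0.9·N(0, 0.1²) + 0.1·N(0.8, 0.2²); and one full-scale end-to-end run (17
plates × 1536, two controls, smoothing, merge, mixture, plots) that
completes in a few seconds and is budgeted at two minutes.

Medians of even counts are the mean of the two middle order statistics
(the NumPy convention) — stated because plate medians drive everything.
Result tables are CSV with 12-significant-digit floats and empty fields
for missing values, so write/read round trips are lossless at 1e-9
relative tolerance and below; all parsers use round-trip float parsing.
Hit thresholds are inclusive (≥). Ties in sorting are broken stably by
(Plate, Row, Column) or (Plate, ID). The CLI writes a manifest (options,
input SHA-256 checksums, package version, no timestamps) beside every
output, so repeated runs on identical inputs are byte-identical.

## Known limitations

* The row/column-median smoother handles separable multiplicative biases
  only; diagonal or blob-shaped gradients need a 2-D surface fit that is
  deliberately out of scope here.
* The t-test assumes equal variances between paired control and
  experimental replicates; with 4 replicates per side there is little
  power to detect otherwise.
* max_q from two controls is a concordance filter, not a calibrated
  significance level.
* The mixture model assumes exactly two normal components; heavy-tailed
  or multi-modal hit distributions will bias the cut-off toward the
  dominant secondary mode.
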