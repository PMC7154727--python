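# Methods

## The experimental design being analyzed

The package targets 30-day artificial-stream community tests analyzed by
regression rather than ANOVA: 4 replicated control streams and, per
exposure series, an unreplicated 6-level geometric concentration ladder
(dilution factor 2). Series are single metals or fixed-ratio mixtures
(e.g. Zn:Cu = 16:1, Zn:Cd = 200:1, ratios chosen to mimic mining-affected
waters). Insect communities colonize gravel trays in a river and are
transferred to the streams, so initial abundances are unknown and counts at
test end are overdispersed. Dissolved metals are dosed continuously and
sampled roughly twice weekly; residues are measured at test end in
periphyton, caddisfly tissue, and sediment.

## Exposure metrics

Dosing never fully reaches steady state, so each stream × metal series is
reduced to a time-weighted average (TWA): the trapezoidal integral of
concentration over the sampled window divided by elapsed days. The window
is the sampled span (not extrapolated to day 0) because dosing starts after
a 24-h acclimation. The end-of-test concentration is reported alongside;
TWA is the default regressor everywhere (which of the two the original
analyses used is not always stated, so both are emitted). Dosing kinetics
are summarized by least-squares fits of
`C(t) = C_bg + C_ss (1 − exp(−k_up t))` with a fixed multi-start grid over
`k_up ∈ {0.05 … 2}/d` (upper search bound 10/d) for determinism; a series
with no resolvable rise is flagged `degenerate`, non-convergence is flagged
rather than raised. Below-detection values are substituted at half the
detection limit (configurable; the flag is always retained).

## Taxa screening

Two rules, applied in a fixed order per taxon (aggregate metrics such as
total mayflies are handled first and never screened as taxa):

1. any control replicate count of zero excludes the taxon;
2. a negative normal-approximation Poisson lower 95% limit of the control
   counts, `mean − 1.96 √mean < 0` on the per-stream count scale, excludes
   it.

An exact Poisson bound is never negative, so rule 2 only makes sense as a
normal approximation; the per-stream variance (var = mean) is the default
and a mean-of-replicates variant (var = mean/n) is available by option.
Within a series, an observation below the control lower limit is attributed
to factors other than metals — and dropped from fitting — iff some
observation at a strictly higher concentration is at or above that limit;
a trailing run of low counts is always retained as the response.

## Concentration–response model

Responses are raw counts (a control-normalized option exists) regressed on
`x = log10 C` with the 3-parameter logistic
`y = y0 / (1 + exp(b (x − x50)))`, `b > 0` meaning decline. Controls enter
at a pseudo-log-concentration 2 decades below the lowest treatment (a
finite stand-in for zero concentration; at `b = 4` the curve is within
~1e-4 % of `y0` there). Fitting is multi-start Levenberg–Marquardt (5 × 5
grid of `x50` quantiles × slopes, fixed order, analytic Jacobian, tight
tolerances); the lowest residual sum of squares wins, so the fit is
deterministic. Two numerically deliberate choices:

* if every treated response stays at or above 80 % of the control mean, no
  decline was observed and the result is censored `> highest tested
  concentration` — no fit is attempted and no numeric EC50 is ever
  reported for such data;
* all-or-nothing patterns drive `b → ∞` with rss → 0; the iteration-capped
  solution (stable `x50`, huge `b`) is accepted as a fit rather than
  flagged, because the midpoint is well determined even when the slope is
  not.

`ECp = 10^(x50 + ln(p/(1−p))/b)` is closed form, strictly increasing in
`p`, with `EC50 = 10^x50` exactly.

Confidence intervals: with ≥ 2 partial-effect points (treated responses
strictly between 20 % and 80 % of `y0`; band configurable) a
case-resampling bootstrap percentile interval is used (2000 resamples by
default, seeded, refits warm-started from the full-data fit; degenerate
resamples with < 3 distinct x values are discarded). Otherwise the
interval brackets the highest concentration with no apparent response
(≥ 80 % of `y0`) and the lowest with complete or nearly complete reduction
(≤ 10 % of `y0`). The original analyses used a proprietary nonlinear
regression tool whose interval method is not described; the bootstrap is
this package's substitute and is labelled as such in the output
(`ci_method`).

The piecewise (breakpoint) alternative fits a flat plateau `y0` up to `x0`
and a linear decline `m` beyond; `x0` is searched over midpoints between
consecutive distinct tested log-concentrations with conditional least
squares for `(y0, m)`, global minimum rss, ties broken toward the larger
breakpoint. `EC0 = 10^x0` is a no-effect-concentration estimate; if no
candidate shows a decline the EC0 is censored above the highest tested
concentration.

## Mixture prediction and classification

Response addition (independent action): predicted mixture survival is the
product over components of `clamp(f_i(C_i)/y0_i, (0, 1])`, using the
concurrent single-metal fits; the clamp means apparent stimulation never
masks toxicity, and a censored (no-decline) single-metal fit contributes
survival 1. The focal response is the total-mayflies metric (summed
Ephemeroptera counts per stream). Observed/predicted abundance ratios are
classified with a symmetric factor-of-2 band: above it less-than-additive,
below it more-than-additive, inside approximately additive. The
"something-from-nothing" flag is raised for a mixture stream iff every
concurrent single-metal observation within 2× of each component
concentration sits at or above the control lower limit while the mixture
response falls below it; with no matchable single-metal stream for some
component the flag is reported not-evaluable rather than false.

## Accumulation

Ordinary least squares of `log10(residue)` on `log10(dissolved)` (decade
logs throughout; closed form), per compartment × metal × series type. The
single-vs-mixture contrast is a pooled regression with a series indicator
and indicator × slope interaction (statsmodels OLS), reporting Δintercept,
Δslope with standard errors, the interaction-term p-value, and the fitted
offset at a reference concentration (default: pooled median log10 C) —
because the source comparisons are qualitative, effect sizes are reported
alongside p-values. Reversal (parabolic) patterns are detected from the
quadratic fit: flagged iff the quadratic coefficient is negative and the
vertex `−b/(2q)` lies strictly inside the observed log-concentration range.
Enrichment factors (residue µg/g ÷ dissolved µg/L, L/g) are reported per
compartment.

## Criteria and SSDs

Hardness-based chronic criteria use the USEPA power-law form
`CCC(H) = exp(m ln H + b) · CF(H)` with `CF = cf_const − cf_slope ln H`.
Coefficient sets are editable config (criteria versions change over time);
defaults ship for Cd (m = 0.7977, b = −3.909, hardness-dependent CF), Ni
(0.846, 0.0584, CF 0.997) and Zn (0.8473, 0.884, CF 0.986). Cu's criterion
is bioavailability-model based and must be supplied as a plain CCC value.
Cumulative criterion units are `Σ C_i / CCC_i`. Effect concentrations can
be moved between water types with a multiplicative hardness power-law
adjustment and/or a user-supplied bioavailability factor (both
multiplicative, hence order-independent).

SSDs are lognormal by moments: duplicate species collapse to geometric
means, Hazen plotting positions `(i − 0.5)/n` are attached for display
(they do not affect the fit), `µ, σ` are the mean and n−1 standard
deviation of log10 values, `HC5 = 10^(µ − 1.6449 σ)`, and percentile
placement is the lognormal CDF. Moment fitting was chosen over maximum
likelihood because it is closed form, reproducible, and differs negligibly
at the 20–40 species counts typical of these compilations.

## The synthetic-data generator

`streammix.synthetic_data` emulates the statistical structure the analysis
assumes, with every parameter recorded in a ground-truth file:

* **Design**: 4 control replicates; default series Zn, Cu, Cd singles plus
  Zn+Cu (16:1) and Zn+Cu+Cd (16:1, 200:1) mixtures, 6-level geometric
  ladders (34 streams; the physical facility the design mirrors had 36
  units, the spares unassigned).
* **Exposure**: first-order approach to plateau per metal
  (`k_up = 0.25/d` for Zn and Cu, reaching plateau near day 10–14;
  `0.08/d` for Cd, which rises throughout a 30-d test), backgrounds 1.3
  (Zn), 0.6 (Cu), 0.01 (Cd) µg/L, 10 % multiplicative lognormal sampling
  noise, twice-weekly sampling days.
* **Counts**: negative binomial around `λ0 · S`, dispersion `k = 20`
  (calibrated so 4-replicate control variability matches the ±30 %
  confidence half-widths typical of colonized trays; large `k` recovers
  Poisson). Survival per taxon is logistic in log10 TWA with slope
  `b = 4`; the default community has six mayfly taxa summing to λ0 ≈ 200
  per stream with EC50s on the µg/L scales of chronic mayfly responses,
  tolerant caddisflies/diptera, and two sparse taxa that fail screening.
* **Mixtures**: joint survival `(Π S_i)^θ`; θ = 1 is response-additive,
  θ < 1 less than additive. θ is a one-parameter generator device — the
  simplest antagonism/synergy dial consistent with a factor-of-2
  classification — not a mechanistic model. It applies only in streams
  dosed with more than one metal, so single-metal fits remain valid
  inversion targets.
* **Residues**: `log10 R = a + b log10 C (+ q x²) + noise` per
  compartment × metal, intercepts ordered so periphyton enrichment ranks
  Cd > Cu > Zn, plus a −1.0 log10 mixture-suppression offset for Cd in
  periphyton and tissue (an order-of-magnitude suppression for the
  analysis to recover).

Counts respond to the TWA of the *sampled* (noisy) exposure series — the
same metric the pipeline uses — so with noise switched off
(`DesignConfig.without_noise()`) the pipeline is an exact inverse of the
generator up to integer rounding. All randomness flows from one seed
through per-table sub-seeds.

**What the generator does not emulate**: emergence timing and
within-test mortality dynamics, periphyton succession, correlated
colonization between taxa, day-to-day autocorrelation in dosing beyond the
kinetic curve, spatial water-bath effects, and chemical speciation. Passing
tests therefore demonstrate that the estimators invert the assumed
statistical structure at realistic noise levels — not that the structure is
a complete model of a physical mesocosm.

## Problem sizes used in the validation suite

Oracle-equivalence checks run on small noise-free fixtures constructed to
lie exactly on the fitted model (including controls evaluated at the
pseudo-log-concentration). Parameter recovery uses the default single-taxon
conditions (λ0 = 200, k = 20, 6-level Zn ladder) over 100 seeds for the
median-error check and 500 seeds with 200 bootstrap resamples each for the
coverage check; 200 resamples suffice because coverage of a percentile
interval is insensitive to resample count at that scale, while the library
default for reported intervals remains 2000. The end-to-end report default
is 500 resamples so a full pipeline run stays under a minute on one CPU.

## Known limitations

* The bootstrap percentile interval can be extremely wide (lower bounds far
  below any tested concentration) for taxa with few informative points —
  this is honest but differs from the unknown interval method of the
  original fitting tool.
* The logistic is fitted by unweighted least squares on counts (matching
  the source tool's continuous fitting); a log-count option stabilizes
  variance but no count-likelihood (GLM) fitting is offered.
* EC0 from the piecewise fit is grid-resolved at midpoints of tested
  concentrations; with 6-level designs this is coarse by construction.
* Criterion coefficient sets are snapshots; users tracking a specific
  regulatory version should supply their own via config.
* Hormesis, concentration-addition/toxic-unit interaction models, and
  biotic-ligand-model internals are out of scope (bioavailability enters
  only as a multiplicative hook).
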