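# Methods

## Design and data model

A North Carolina Design II (NCD II) trial crosses each of p female parents
to each of q male parents and evaluates the progeny in r complete blocks.
The pipeline's universal input is the plot-level table keyed by
(female, male, block) with one numeric column per trait; a cross-mean table
(one row per realized cross) is accepted for mean-only analyses, because
published trials often report only means. Incomplete factorials are
first-class: completeness is a flag, and all estimators work on the
realized subset of the p × q grid. Balance *within* realized cells (every
realized cross present in every block) is required; unbalanced cells are a
schema error, not a silent reweighting.

## ANOVA

Stage 1 is the randomized-complete-block decomposition
y = μ + genotype + block + error, treating each realized cross as a
genotype. Block × genotype interaction is pooled into error (the model has
no interaction term), so the error stratum has (c − 1)(r − 1) degrees of
freedom for c realized crosses — this matches how replicated trials of this
kind are conventionally reported.

Stage 2 partitions the cross variation into female, male and female × male
strata. On complete balanced grids the closed-form marginal-contrast sums
of squares are used (SS_F = rq·Σ(ȳ_f − ȳ)², etc.). On incomplete grids the
sums of squares are sequential (type-I) in the fixed, documented order
block → female → male → interaction, computed by rank-tracked least squares
on explicit dummy matrices; degrees of freedom are rank increments, so an
8-cell 4 × 3 grid yields interaction df = 7 − 3 − 2 = 2, never the
complete-grid (p−1)(q−1). Both paths are cross-checked against a
brute-force deviation-sum oracle in the tests.

F tests follow the expected-mean-squares ordering by default: female and
male mean squares over the interaction mean square, interaction over error
(`denominator="ems"`). A documented switch tests all strata over error,
which is what many published tables' significance stars correspond to.

## Combining ability

The default estimator is the simple-means (sum-to-zero) one on cross means:

    g_i  = ȳ_i − ȳ,     s_ij = y_ij − ȳ − g_i − g_j

which satisfies μ̂ + g_i + g_j + s_ij = y_ij identically on every realized
cross. On complete grids GCA effects sum to zero within each role and SCA
effects sum to zero along every row and column; on incomplete grids the
zero-sums hold with weights equal to each parent's realized cross count.

A reference-level least-squares fit is also provided (one female and one
male constrained to zero), mirroring how mixed-model software reports such
effects. Interaction terms are added greedily in row-major order only where
they increase the design rank after the main effects; the remaining cells'
SCA values are *structural zeros* — unidentifiable from the realized grid —
and flagged as such rather than reported as estimates.

Standard errors: SE(g_i) = √(MS_error/(n_i·r)) with n_i the parent's
realized cross count, and SE(s_ij) = √(MS_error·(p−1)(q−1)/(pqr)) (the
complete-grid interaction-contrast coefficient, used as an approximation on
incomplete grids). Significance is the t ratio effect/SE against the
two-sided critical value with the error-stratum df. Whether a published
trial used cross-mean or plot-level residual df for such tests is often
unstated; the df is an explicit argument.

## Variance components and genetic parameters

Method of moments on the EMS: σ²e = MS_E, σ²FM = (MS_FM − MS_E)/r,
σ²F = (MS_F − MS_FM)/(rq), σ²M = (MS_M − MS_FM)/(rp). Negative solutions
are truncated to zero and *flagged* — truncation is reported per component,
never silent, because it biases downstream ratios.

Genetic interpretation: σ²A = 2(σ²F + σ²M) and σ²D = 4σ²FM, the convention
of the bundled trial's source analysis (a `coeff_additive=4` option gives
the textbook half-sib coefficient 4σ²GCA). Then σ²G = σ²A + σ²D,
σ²P = σ²G + σ²e, narrow-sense h² = σ²A/σ²P (broad-sense σ²G/σ²P is reported
under its own name — the two are easily conflated in print), and degree of
dominance d = √(σ²D/σ²A), with d = 0 when both variances are zero and NaN
when only σ²A is.

The h² standard error is a delta-method approximation: var(MS_i) =
2·MS_i²/df_i from chi-square theory, propagated through a numerical
gradient of h² in the four mean squares, ignoring truncation. It is
documented as approximate; a simulation check in the tests confirms it
tracks the empirical SD of h² within a factor of two at trial-like sizes.

## Trial statistics and correlations

SE of a cross mean = √(MS_error/r); LSD at level α =
t(1 − α/2, df_error)·√(2·MS_error/r); CV% = 100·√(MS_error)/grand mean.
Pearson correlations are computed over realized cross means (n = crosses)
with p-values from t = r·√((n−2)/(1−r²)); stars are * p<0.05, ** p<0.01,
*** p<0.001. A plot-level option (n = crosses × blocks) exists because
published star patterns sometimes imply a larger n than the cross count;
with n = 8 crosses, r = −0.49 is not significant even where a source prints
it starred. Printed stars in the bundled fixture are stored as published
and never overwritten.

## Synthetic trials and what a green test establishes

The generator draws female, male, SCA, block and plot-error effects from
independent zero-mean normals with configured variances and sums them per
the model. Normality matches the ANOVA framework's assumptions and is a
choice, not a claim about field data. Determinism contract: one seed; per
trait, a fixed substream order (female, male, SCA over the full p × q grid,
block, error over the full grid), so restricting the realized mask or
adding traits never perturbs earlier draws.

Defaults of the bundled-trial configuration: p = 4, q = 3, r = 3, the 8-cell
realized mask, μ = 13.86 g and components back-solved from the published
grain-yield genetics (σ²F = σ²M = σ²A/4 = 7.65, σ²FM = σ²D/4 = 8.7,
σ²e = 12.84). Block variance was never published; 1.0 g² (small relative to
error) is assumed.

The generator emulates balanced, normal, single-environment trials with
independent effects. It does not emulate genotype × environment structure,
spatial field trends, non-normal or heteroscedastic errors, or epistasis —
so a green recovery test establishes correctness of the estimators under
the stated model, not robustness to those departures.

## Numerical choices

- Rounding for comparisons against printed tables is half-up at the printed
  decimals (matching how agronomy tables are typeset), via `round_half_up`.
- Sums of squares are clipped at zero against floating-point cancellation;
  F ratios with a zero or undefined denominator are NaN, as is the CV at a
  zero grand mean and d when σ²A = 0 < σ²D.
- CSV round-trips write floats with `%.17g` and parse with a correctly
  rounded reader path, so written trials reload bit-for-bit.
- Least-squares ranks use `numpy.linalg.lstsq`/`matrix_rank` defaults;
  sequential SS are order-dependent by construction and the order is fixed
  and logged.

## Known limitations

- On incomplete grids the complete-design EMS coefficients are an
  approximation; the recovery driver (`analysis/02_recovery_simulation.py`)
  quantifies the resulting bias at the bundled trial's own geometry (the
  male component, with one parent realized in a single cross, is noticeably
  biased). A general incomplete-design EMS would require the coefficients
  of the realized incidence matrix; out of scope here.
- Method-of-moments components with few parents are mean-unbiased but
  heavily skewed: at p = q = 5 the *median* female/male component estimate
  sits ~20% below truth (4-df chi-square skew), and truncation inflates
  small dominance components. Interpret single-trial components with their
  simulation-calibrated uncertainty, not at face value.
- The bundled trial's published GCA/SCA effect tables and additive/dominance
  variances came from a REML fit of plot-level data that was never
  published; they are not reproducible from cross means and are not
  asserted. The simple-means estimator is the documented, testable default.
- Published tables carry rounded inputs: a few printed summary cells
  (grain-shape ratios, one genotypic variance, the yield column of the
  correlation matrix) differ in the last printed digit from what the
  printed inputs imply; the fixtures store the printed values verbatim and
  the tests state which comparisons hold at which tolerance.
- No REML/mixed-model engine, no multi-environment strata, no reciprocal or
  maternal effects (NCD II has no reciprocal crosses), no epistatic
  partition.
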