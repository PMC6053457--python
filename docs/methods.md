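# Methods

`rsmga` implements the statistical machinery of a sequential
fermentation-medium optimization: a two-level Plackett-Burman screen to find
the medium components that matter, a central composite design (CCD) with a
second-order response-surface fit to model their joint effect on enzyme
yield, and a real-coded genetic algorithm (GA) that maximizes the fitted
surface inside concentration bounds.  Alongside it ships the enzymology
bookkeeping of such a study: purification-table arithmetic, Michaelis-Menten
parameter estimation, and relative-activity tables.  The bundled data are
the printed tables of a cholesterol-oxidase (COD) optimization study on
*Streptomyces rimosus* (activities in U/ml, concentrations in g/100 ml).

## Screening model

The 12-run Plackett-Burman design is the standard cyclic construction:
eleven rotations of the generator row `+ + − + + + − − − + −` plus a final
all-minus row.  All eleven columns are mutually orthogonal and balanced.
The bundled screening table binds seven components to construction columns
(0, 1, 2, 7, 4, 10, 3) — found by exhaustive search over column injections,
and frozen as `TABLE1_COLUMN_ASSIGNMENT` — leaving four dummy columns for
error estimation.

For factor X the concentration effect is

    E(X) = (Σ y at high − Σ y at low) / (N/2),

i.e. the difference of level means.  The error variance of an effect is
estimated from the dummy-column effects, `V_eff = Σ E_d² / n`, with
`S.E. = √V_eff`, and each factor is tested with `t = E / S.E.`.  Note the
source study's printed screening equation divides by N, but all of its
printed effects correspond to division by N/2 (the conventional difference
of means); this package implements N/2.

**Degrees of freedom and tails.**  The bundled table's p-values are
reproduced (to ≤0.3% relative) by a one-tailed Student t with df = 10 =
n_runs − 2, so that is the default.  The textbook alternative df = number
of dummy columns is available via `df="dummy"`, and two-tailed testing via
`tails="two"`.  Significance defaults to p < 0.10, the 90% confidence rule
under which the screen retains yeast extract, dextrose, starch and ammonium
carbonate.

Because the true dummy-column assignment of the original experiment is
unrecoverable from the printed table, `V_eff` can be supplied as an
override (the bundled analyses use the printed 0.001494, which gives
S.E. = 0.038652 exactly).  The reconstructed dummy columns give
V_eff = 0.001504 from the 3-decimal printed activities — within 1% — so the
construction is consistent with the published analysis.

## Response surface

The CCD varies k = 4 factors at five coded levels (−2, −1, 0, +1, +2):
8 factorial points, 8 star points at ±α = ±2, and replicated center points.
The bundled 27-run table parses to 11 center rows (its narrative says ten);
the table is stored as printed.  Its 8 factorial points are *not* a regular
half fraction (their sign products are not constant), so
`build_ccd_design` accepts an explicit factorial point set; the generator's
default is the regular 2^(k−1) fraction.

The model is the full quadratic

    y = b0 + Σ bᵢxᵢ + Σ bᵢᵢxᵢ² + Σ_{i<j} bᵢⱼxᵢxⱼ

fit by OLS (statsmodels).  Columns are ordered [1, linear, squares, pairs
(row-major i<j)]; rank deficiency is detected at a smallest-to-largest
singular-value ratio of 1e−10 and reported with the offending columns.
Natural concentration units are the default (the bundled coefficient set is
in natural units); coded-unit fits are supported and predict identically to
natural-unit fits on the same data (span invariance, verified to 1e−8).
ANOVA uses df = p−1 / n−p; R² = 1 − SS_res/SS_tot, defined as 0 for a
constant response.  `AnovaTable.from_sums_of_squares` recomputes MS, F, p
and R² from externally supplied SS/df — the arithmetic mode used to
reproduce the bundled ANOVA table, whose printed 4/22 df do not match a
15-coefficient fit on 27 runs and whose residual SS is inconsistent with
its own residual column.  Both printed versions are preserved as fixtures
and deliberately not reconciled.

The bundled coefficient set uses intercept −0.1801 (its companion equation
prints +0.1801): the negative sign reproduces the table's center-point
prediction 1.698545.  The non-center printed predictions deviate from this
coefficient set by up to ~0.025 and are not reproducible from any printed
coefficients; fixtures therefore anchor on the center point.

## Genetic algorithm

A single real-coded population with the study's printed optimizer settings
as defaults: population 200, elite count 2, crossover fraction 1.0,
generation cap 100, stall limit 50 generations (stall tolerance 1e−6
absolute).  Fitness is rank-scaled (expectation ∝ 1/√rank), parents are
drawn by stochastic universal sampling and shuffled, crossover is scattered
(per-gene uniform mask), and children are clipped into the bounds.  Elites
pass unchanged, so the best-fitness trace is non-decreasing; seeded runs are
bit-reproducible.  Non-finite objective values are penalized with −∞ and
warned about.

Mutation — uniform per-gene resampling at rate 0.01, or Gaussian with
linearly shrinking scale — only applies to the (1 − crossover fraction)
share of non-elite children, hence is inactive at the default crossover
fraction of 1.0.  A consequence worth knowing: with scattered crossover
alone, no gene value absent from the initial population can ever be
created, so the default configuration is a combinatorial search over the
initial per-gene samples.  That is faithful to the printed configuration
(and ample for ranking candidate media), but accuracy benchmarks in the
test suite use crossover fraction 0.85 with shrinking Gaussian mutation,
under which the GA matches an analytic constrained optimum and a dense
50⁴ grid search to better than 1e−2 on random concave quadratics.

Subpopulation migration settings in the printed configuration are not
implemented (single population; the subpopulation count was never stated),
and the printed initial-range and mutation-function entries are garbled in
the source, so initialization is uniform within bounds.

`quadratic_stationary_point` is the analytic companion: it solves
H x = −g for the stationary point, classifies it by the Hessian eigenvalue
signs (max / min / saddle / degenerate), and when that point is not an
interior maximum falls back to a dense grid plus L-BFGS-B polish, flagging
the result boundary-constrained.  On the bundled surface the stationary
point is a saddle and the box optimum sits on the boundary of the
star-point box ("ccd-box": yeast extract and dextrose 0–0.8, starch 0–1.6,
ammonium carbonate 0–0.04 g/100 ml).

**Bounds.**  The source study never states its GA bounds, and its reported
optimum (0.99, 0.8, 0.1, 0.05) lies outside the CCD ranges for yeast
extract and ammonium carbonate; its headline predicted activity of
5.41 U/ml is likewise not reproducible by evaluating the printed
coefficients at the printed optimum.  Bounds are therefore an explicit
input, with two presets: `ccd-box` (the star-point ranges) and
`extended-box` (0–1, 0–0.8, 0–1.6, 0–0.05), the smallest natural widening
that contains the reported optimum.  On `ccd-box` the GA-maximized surface
reaches ≈ 4.38 U/ml (seed 1), comfortably above the best observed run
(2.788 U/ml); the 5.41 figure is treated as a documented non-reproducible
value and the optimizer is validated against oracles instead.

## Enzymology arithmetic

Purification tables derive specific activity (U/mg), yield (% of the first
step's total activity) and fold (ratio of specific activities to the first
step).  Default output is full precision.  The bundled published table's
derived columns are consistently *truncated* to 2 decimals (5.2273 → 5.22,
12.375 → 12.37), and its folds are ratios of those truncated values;
`printed_mode=True` reproduces that display arithmetic (final fold 10.31
instead of the full-precision 10.28).

Kinetics: the Lineweaver-Burk method fits an unweighted least-squares line
to (1/[S], 1/v) and back-transforms (Vmax = 1/intercept, Km = slope·Vmax);
the direct method fits v = Vmax·S/(Km+S) by nonlinear least squares seeded
from the LB estimate.  Both are exact on noiseless data.  Their relative
merit depends on the error structure: under additive constant-sd noise the
direct fit is maximum likelihood and has about half the Km RMSE of LB
(Monte-Carlo over 500 seeds at 5% of Vmax), whereas under constant-CV
(multiplicative) noise the reciprocal transform's implicit weighting makes
the two comparable.  The bundled study's raw (S, v) points are not printed,
so kinetics validation is purely synthetic.

## Synthetic data

Three seeded generators mirror the estimators: screening responses
`y = baseline + Σ (effect/2)·coded + ε` (so the effect estimator is exact at
zero noise), CCD responses from any quadratic coefficient set, and
Michaelis-Menten curves with additive or multiplicative Gaussian noise.
Defaults emulate the study conditions: the 12-run/27-run designs above,
demo noise sd 0.05 U/ml (the scale of the bundled center-point scatter),
substrate grid 0.02–0.1 mM, Km 0.043 mM, Vmax 2.21 μmol/min/mg.  The
generators are pure functions of (parameters, seed).  What they do not
emulate: real fermentation batch effects, heteroscedastic assay error,
plate/block structure, or any growth kinetics — so passing round-trip tests
demonstrates estimator correctness, not robustness to those features.

## Problem sizes and numerical choices

Monte-Carlo checks use 500–2000 replicates (screening power and variance
calibration, kinetics RMSE comparison); oracle agreement uses 20 random
concave quadratics against a 50⁴-point grid evaluated in chunks; the
replication-scaling check fits 30 noise draws at m = 1, 4, 16 replicates.
Stationary-point classification uses an eigenvalue cutoff of 1e−12 relative
to the spectral radius; grid fallbacks cap at ~2·10⁶ points.  Ties in the
screening |t| ranking keep input factor order; duplicate non-center design
rows warn rather than error (replicated center points are the norm).
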