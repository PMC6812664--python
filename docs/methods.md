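# Methods

## The question the package simulates

Threshold hypotheses claim that a predictor–outcome association changes
character at some predictor value: for intelligence and creative
potential, a positive association below roughly IQ 120 and little or
none above it. `thresholdsim` implements a Monte-Carlo machine for a
competing explanation: if both measured scores are attenuated by the
*same* subject-level disturbance factor (low motivation, illness,
linguistic confusion, ...), a threshold-like pattern can appear in the
observed scores even when the true abilities are linearly related or
unrelated.

## Generative model

For each virtual subject *i*:

1. true scores `(T_iq, T_cr)` are bivariate normal with common mean
   `M` (default 100 score units; 120 in the worked example), common SD
   15, and population correlation `rho ∈ [0, 1]`. The pair is built by
   the conditional-normal construction
   `z2 = rho·z1 + sqrt(1 − rho²)·e`, which induces exactly the target
   joint distribution; any construction with the same joint law would
   do. Normal(100, 15) can in principle produce negative "scores"; we
   leave them untruncated (probability ≈ 1e-11 per draw) because
   truncation would distort the stated marginals.
2. a disturbance factor `D_i ~ Beta(α, β)` on [0, 1], *low = heavily
   disturbed*. Three shapes are studied: negatively skewed Beta(9, 1)
   (most subjects barely disturbed — the realistic case), approximately
   symmetric Beta(9, 9), positively skewed Beta(1, 9).
3. observed scores are `O = T × D`, with the **same** `D_i` multiplying
   both traits. One shared disturbance per subject is a deliberate
   simplification; real data would mix shared and trait-specific
   disturbances, and the shared component is what drives the artifact.

The Monte-Carlo arms draw a fresh `rho ~ U(0, 1)` for every replicate,
so each condition's replicates span the whole correlation range; the
per-replicate `rho` is the predictor of the condition-level logistic
summary. The no-disturbance (null) arm sets `D ≡ 1`, making observed
scores bit-identical to true scores, so any threshold "verification"
there is a false positive by construction.

There is no additive measurement error in the model: disturbance is the
only wedge between true and observed scores. Passing tests therefore
say nothing about how classical measurement error interacts with the
artifact.

## Segmented (broken-line) regression

The detection instrument is the continuous one-knot model

    E[y | z] = β0 + β1·z + β2·(z − ψ)·I(z > ψ)

fitted by profiling the knot: every distinct observed predictor value
between the 10th and 90th percentiles with at least 5 observations on
each side is a candidate `ψ`; an OLS fit is evaluated at each candidate
and the candidate minimising the residual sum of squares is selected.
Inference on the slope change `β2` is the Wald t-test from the OLS fit
at the selected knot, *treating the knot as known*.

Numerical choices:

- The profile is computed in closed form: with the predictor sorted,
  each candidate's 3×3 normal equations differ only in the hinge-column
  moments, which are suffix cumulative sums; the batched solves make a
  full profile O(n log n + m). Both x and y are centred before the
  solve for conditioning, and the intercept is translated back.
  The test suite checks the profile against a naive per-candidate
  least-squares loop on every fixture class.
- Candidates whose design is numerically singular (e.g. fewer than two
  distinct predictor values on a side) are excluded via a scaled
  determinant threshold; if no candidate survives, the fit raises
  `BreakpointNotEstimable` — a distinct outcome from a non-significant
  breakpoint.
- Ties in the selection objective (relative tolerance 1e-10) resolve to
  the smallest candidate `ψ`, deterministically.
- The 95% interval for `ψ` is profile-based: under Gaussian errors,
  `n·log(SSE(ψ)/SSE_min)` is compared to the χ²(1) 0.95 quantile and
  the interval is the span of candidates below the cut. On noiseless
  data (SSE_min = 0) it degenerates to the knot itself. Measured
  coverage on noisy broken-line data (n = 400, knot at the 60th
  percentile, unit slope change, residual SD 10) is above the 90%
  floor asserted in the acceptance tests.

**Selection-rule caveat.** The field's prose description of the
procedure — "the point with the largest absolute β2" — does not
literally work: profiling shows that a global max-|β2| scan is
dominated by leverage at the candidate-range edges and picks an edge
candidate even on noiseless fixtures (|β2| inflated roughly 2×). The
package keeps `selection="max_beta2"` as a documented option, and the
tests demonstrate the edge bias; minimum SSE is the default because it
is the continuous, statistically standard objective and recovers clean
knots exactly.

**Inference caveat.** The Wald p-value for `β2` ignores that `ψ` was
chosen to optimise fit over many candidates (the unidentified-nuisance-
parameter problem; a Davies-type correction is deliberately out of
scope). The test is therefore anticonservative for the *single*
criterion "significant breakpoint". In the null arm the three-criterion
conjunction still keeps the overall false-verification rate at or below
the nominal 5% within Monte-Carlo error, but the rate is not flat in
`rho`: near `rho = 1` the fitted probability curve can sit at or
slightly above 0.05. The null-control test asserts the defensible
statement — the curve nowhere *significantly* exceeds nominal — rather
than strict pointwise domination.

## Three-criterion verification

A cohort supports the threshold hypothesis iff, at level α (default
0.05, the conventional level throughout):

1. the segmented fit's slope change is significant (`p_β2 < α`);
2. the observed-score correlation below the knot (subjects with
   predictor ≤ ψ) is positive and significant;
3. that correlation is significantly larger below than above the knot
   by the Fisher r-to-z comparison, with `r_below > r_above` enforced
   explicitly so a significant difference in the wrong direction never
   verifies.

A significant correlation *above* the knot is not a veto. The knot is
always estimated from the same data being tested — that circularity is
part of the procedure being studied, not a bug. Cohorts with fewer
than 4 subjects on either side of the selected knot, or with constant
scores on a side, are flagged `estimable = False` and counted as
unverified; counting them as verified would inflate every rate, and 4
is the smallest group size at which the correlation tests are defined.
Raising α can only flip a verdict from unverified to verified, never
the reverse; the suite asserts this monotonicity.

## Experiment design and problem sizes

The full published design is 500 replicates for each of 12 conditions
(n ∈ {100, 400, 1600, 6400} × three disturbance shapes) plus 1,500
null-arm replicates at n = 6,400; it is available via
`ExperimentPlan.full_scale()` / `--full-scale`. The package's default
plan is a reduced version — 100 replicates per condition at
n ∈ {100, 400, 1600} and a 300-replicate null arm at n = 1,600 — chosen
so a complete run with summaries finishes in minutes on one CPU while
reproducing the qualitative pattern (verification probability grows
with n and falls with rho under disturbance; stays at or below nominal
without it). The acceptance script uses this reduced null arm.

Seeding: one root seed per experiment; replicate `(condition i, rep j)`
uses `SeedSequence(root, spawn_key=(i, j))`, so any replicate can be
regenerated in isolation (`replicate_rng`) and the experiment is a pure
function of the plan.

Condition summaries are maximum-likelihood logistic fits of the binary
verification outcome on the per-replicate population `rho`. Conditions
with all-identical outcomes or separation are flagged degenerate and
report the empirical rate instead of coefficients.

## The worked example

The published worked example draws n = 400 subjects with true means 120,
`rho = 0`, Beta(9, 1) disturbance, and shows the observed scores
acquiring a positive overall correlation and a "verified" threshold
near observed IQ 120. Its exact statistics are properties of one
deposited realisation whose RNG state is not recorded, so the package
regenerates the *setting* under its own seeds and asserts the pattern:
true correlation near zero, observed correlation strongly positive,
verification typical rather than incidental, and `r_below > r_above`
in every verified replicate. The loader accepts the deposited CSV's
column names via a rename table, tested on a synthetic stand-in file.

## Known limitations

- Only Wald inference at the selected knot (no Davies correction), so
  single-criterion significance statements are anticonservative.
- One breakpoint; no comparison against smooth (e.g. quadratic)
  alternatives.
- One shared disturbance variable; no additive measurement error; no
  trait-specific disturbances.
- The logistic condition summary conditions on the *population* rho (the
  controlled quantity); the realised sample correlation of true scores
  is recorded per replicate as an alternative predictor column.
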