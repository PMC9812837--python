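# Methods

This note documents the statistical models, the numerical choices, and the
synthetic-data design behind `rangeshift`, and what the test suite does and
does not establish about real survey data.

## Spatial preprocessing

**Coordinates.** All spatial operations assume planar projected coordinates
in kilometres (for real data, project to an appropriate UTM zone before
import; the package performs no CRS transformation). Distances are Euclidean.

**Grid thinning.** `resample_to_grid` keeps at most one record per
(cell, period) on a square grid (default cell 10 km, origin configurable).
Detections and non-detections are drawn independently within a cell and a
detection always wins when both are present: aggregation must never erase an
occurrence. The draw is seeded and idempotent (re-thinning a thinned table
reproduces it).

**Range centre and margin selection.** The reference range centre is the
coordinate-wise mean of a reference period's occurrences. Two margin rules
are provided, mirroring the two survey regimes they serve:

* *percentile* — occurrences strictly above the q-quantile (default q = 0.95,
  linear interpolation between order statistics) of that period's distances
  from the centre, restricted to sites north of the centre when
  `northern_only` is set. By default the quantile is computed over all of the
  period's occurrences and the northern restriction applied to the selected
  set; `quantile_on="northern"` computes the quantile within the northern
  subset instead. Strict inequality means a fully tied distance set selects
  nothing — ties are never split arbitrarily.
* *top-k* — the k most distant occurrences, ties broken by site identifier
  (stable and order-independent). In the pipeline, periphery-restricted
  periods use top-k with k copied from the reference period's percentile
  count (`k="auto"`), and rank only sites north of the centre, since the rule
  stands in for "the k northernmost sites" when a percentile is meaningless.

**Periphery extraction.** For each period, the minimum enclosing circle of
its margin occurrences delimits the sampled periphery; every survey record
(detection or not) inside the circle, with a 1e-9 km boundary tolerance,
enters the presence–absence series. One circle per period is the default —
the periphery tracks the moving edge; a single global circle is available
behind a flag. The circle itself is computed by Welzl's randomized
incremental algorithm with a fixed internal permutation seed, exact for one
and two points; tests verify it against an O(n⁴) enumeration of all
pair-diameter and three-point circumscribed circles, and against an
independent computational-geometry library.

**Pooled periods.** A period label spanning two campaigns ("2012-14") maps
to the midpoint year (2013) by default; the period-to-year map is
user-configurable.

## Trend models

Five mean structures (constant, linear, quadratic, one-breakpoint with the
left slope free or fixed at zero) are fitted by maximum likelihood under a
Gaussian/identity family for distances and a Bernoulli/logit family for
presence–absence. The Gaussian likelihood is profiled over the residual
variance, so the reported NLL is exact:
NLL = (n/2)(log 2π + log(RSS/n) + 1). The binomial solver is IRLS with a
deviance-change tolerance of 1e-10; complete separation is detected by
divergence of the linear predictor and reported as a flagged,
non-converged fit rather than silently. Both engines are cross-checked
against statsmodels OLS/GLM in the test suite. Binomial polynomial designs
are centred internally (raw-year quadratics make the weighted normal
equations numerically singular); coefficients are always reported on the
raw-year scale, matching the presentation of published parameter tables.

### Breakpoint estimation

The segmented forms add a hinge (x−ψ)₊ with slope difference γ; the right
slope is β₁ + γ. ψ is estimated by the standard iterative linearization:
augment the design with U = (x−ψ⁰)₊ and V = −1[x>ψ⁰], fit, update
ψ ← ψ⁰ + δ̂/γ̂ (δ̂ the V coefficient), damp oversized steps by a factor 0.5,
and stop when |Δψ| < 1e-8 years (at most 100 iterations). The iteration is
started from the best point of a profile grid scan (ten interior quantiles
of x plus the midpoints between adjacent distinct years). Because the
profile likelihood over ψ can be multimodal across inter-year intervals,
the result is then polished by bounded scalar minimization of the exact
profile NLL on every interval between adjacent distinct x values; the
reported ψ̂ is the global profile optimum, and the package invariant —
verified against 0.01-year grid refits — is that the free fit is never
worse than any fixed-ψ conditional fit.

**Admissible range.** ψ is confined to the closed interval from the second
to the second-to-last distinct survey year. Outside it one segment would
rest on a single design point; there the two-slope profile is exactly flat
(γ and ψ trade off along a ridge, the likelihood cannot distinguish any
interior value), and hinge fits are generally unstable. An optimum at an
endpoint of this interval is a legitimate result — e.g. an occupancy series
that rises until the penultimate survey and collapses afterwards breaks
exactly there — and is flagged (`psi_at_bound_`; the ψ standard error is
undefined there and reported as infinite). With `strict_interior=True` an
endpoint optimum raises a boundary-convergence error naming the side
instead. At least four distinct survey years are required for any segmented
fit; generators and the CLI warn on under-determined designs.

**Uncertainty.** SE(ψ) is the delta-method ratio SE(δ̂)/|γ̂| from the
augmented working fit at ψ̂ — approximate when distinct years are few, as
the reported intervals make visible. Coefficient covariances are also taken
from the augmented working model, so slope standard errors include the
breakpoint-estimation uncertainty; intervals are t-based for Gaussian fits
(df = n − np) and normal for binomial. In a 500-replicate experiment under
the default margin design (six observations at each of five survey years,
breakpoint 2006, right slope 5.48 km/yr, residual SD 17.6 km) the mean ψ̂ is
within 0.2 years of truth and the 95% interval for the right slope covers
at an observed 0.96.

### Breakpoint existence test

`pscore_test` implements a score-type test of "no breakpoint": the K
candidate breakpoints (default K = 10) are quantiles of x alone, so the
averaged hinge regressor s(x) = mean_k (x−ψ_k)₊ is a fixed covariate, and
the statistic is its added-variable t statistic under the null design
(linear, or constant when the alternative is the left-horizontal model).
For the Gaussian family this test is exact — its size at the 5% level is 5%
by construction, which the Monte-Carlo acceptance experiment confirms
empirically (rejection rate within [0.03, 0.08] over 500 null replicates).
For the binomial family it is an asymptotic Wald z. Because the published
weighting of candidate breakpoints in the original score-test proposal
admits variants, a seeded parametric-bootstrap likelihood-ratio mode
(`pscore_bootstrap`, default 999 replicates) is provided as the arbiter
wherever the analytic approximation is in doubt.

### Model ranking

AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1). The parameter count convention is
frozen to match published comparison tables for this analysis family: the
printed np counts mean-structure parameters including ψ (constant 1,
linear 2, quadratic 3, left-horizontal 3, two-slope 4); k adds one for the
Gaussian residual variance and equals np for binomial models. Note the
likelihood column such tables head "−2LL" is numerically −LL; the package
labels it NLL and reconstructs every printed AICc from it to within 0.015
(the rounding of the printed likelihoods). Akaike weights are normalized
over converged fits only — silently including a non-converged likelihood
would corrupt the evidence ratios; non-converged rows remain in the table,
flagged. The ΔAICc ≤ 2 "substantial support" convention appears as an
annotation column, not a decision rule.

## Synthetic data

The generator emulates a five-period survey series (1985, 2003, a pooled
2012-14 campaign mapped to 2013, 2019, 2021) with the stasis-then-expansion
structure the analysis targets.

* **Margin series** — six distance observations per period, mean flat at
  162.5 km until a 2006 breakpoint then rising at 5.48 km/yr, Gaussian noise
  with SD 17.6 km. The SD is not a published number: it is backed out of the
  published Gaussian model likelihood (NLL 128.68 at n = 30) through the
  closed-form profile-sigma likelihood, a derivation kept as a unit test.
  Distances are floored at zero.
* **Occupancy series** — 126 Bernoulli records split (26, 25, 25, 25, 25)
  across periods (per-period counts are configurable; only the total is a
  published quantity). The logit of detection probability is piecewise
  linear through logit(0.151) in 1985, logit(0.4) in 2006, logit(0.658) in
  2019, then falls to logit(0.289) by 2021 — a rise-then-collapse encoded
  with a second breakpoint at 2019 and a steep negative slope. Fitting
  still uses single-breakpoint models, deliberately: the analysis this
  emulates did the same, and the expected single-breakpoint description is
  a break at the penultimate survey year.
* **Spatial survey** — per period, the margin observations are planted as
  occurrence points at their trajectory distance from the range centre, at
  angles spread over the northern half-plane (margin selection is
  northward-directional; decoys south of the centre would be artefacts).
  The first period emulates a range-wide survey: dense interior filler
  occurrences (29 per margin site, full circle, strictly nearer the centre)
  so that the planted margins are the small top fraction a 95th-percentile
  rule selects even after grid thinning removes co-located filler. Later
  periods carry sparse northern filler and non-detections sprinkled through
  the northern margin annulus, emulating periphery-restricted campaigns.
  Planted per-site distances are recorded in the ground-truth metadata.

All draws flow from a single `numpy` Generator per call, so identical seeds
give byte-identical serialized output; ground truth round-trips through the
JSON sidecar.

**What passing tests do not show.** The generator draws i.i.d. noise around
an exactly piecewise-linear trajectory with known period years and perfect
detection. Real survey series carry imperfect and period-varying
detectability (explicitly not modelled here — no occupancy-detection
layer), spatial autocorrelation along river networks, unequal effort that
thinning only partly equalizes, and range centres that are themselves
estimates. Parameter-recovery and coverage results under the generator are
therefore statements about the estimator under its own assumptions, not
about field data.

## Problem sizes

The default test run uses the study-scale designs throughout: n = 30
margin observations and n = 126 periphery records per dataset; 500
replicates for the recovery and test-size experiments; 50 datasets against
the 0.01-year profile-grid oracle; 200 random instances against the O(n⁴)
enclosing-circle oracle; 999 bootstrap replicates for the score-test
cross-check. These sizes were chosen to give stable Monte-Carlo estimates
(binomial SE ≈ 0.01 at 500 replicates) while keeping the suite quick on a
single core.

## Known limitations

* One breakpoint only; no multi-phase models, random effects, or residual
  autocorrelation.
* SE(ψ) is a delta-method approximation, fragile with few distinct years;
  the bootstrap score test is the more defensible inference there.
* Naive occupancy (detection-free) is a density surrogate, not occupancy in
  the detection-corrected sense.
* The quadratic form on raw years is numerically touchy in the Gaussian
  normal equations; covariances are computed through a QR factorization for
  that reason, and an optional centred parameterization
  (`center=True`, back-transformed for reporting) is available.
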