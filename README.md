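# rangeshift

Quantifying species range shifts from presence–absence surveys: range-margin
distance statistics, segmented (breakpoint) trend regression for Gaussian and
binomial responses, and AICc-based model selection — with a synthetic survey
generator carrying known ground truth.

## The problem

When a species recovers after a historical contraction (the motivating case
is the Eurasian otter *Lutra lutra* re-expanding northward through central
Italy between 1985 and 2021), the questions are *when* the range edge started
moving, *how fast* it moves, and whether occupancy at the expanding front
rises before the edge does — the signature of stratified diffusion, where
local colonization must first build density before long-distance dispersal
can push the margin outward.

The data for such questions are sparse and heterogeneous: a handful of
surveys decades apart, georeferenced detections and non-detections, differing
spatial effort. `rangeshift` implements the standard analysis pipeline:

1. **Thin** each survey to one record per grid cell (default 10 km), without
   ever letting a non-detection mask a detection.
2. **Select range-margin occurrences** per survey period — sites above the
   95th percentile of distance from a reference range centre (for range-wide
   surveys), or the k northernmost/most-distant sites (for periphery-only
   surveys).
3. **Build two series**: distance of each margin site from the reference
   centre vs. year (Gaussian response), and presence–absence of every survey
   site inside the minimum enclosing circle of each period's margin sites
   vs. year (binomial response, a naive-occupancy surrogate for density).
4. **Fit five candidate trend models** to each series and rank them by AICc.

## The models

For response *y* over years *x*, with identity link (distances) or logit link
(presence–absence):

| form | mean structure | np |
|---|---|---|
| constant | β₀ | 1 |
| linear | β₀ + β₁x | 2 |
| quadratic | β₀ + β₁x + β₂x² | 3 |
| left-horizontal | β₀ + γ(x−ψ)₊ | 3 |
| two-slope | β₀ + β₁x + γ(x−ψ)₊ | 4 |

(x−ψ)₊ = max(0, x−ψ) is the hinge term and ψ the breakpoint year, estimated
jointly with the slopes by iterative linearization (augment the design with
U = (x−ψ)₊ and V = −1[x>ψ], update ψ ← ψ + δ̂/γ̂, damp, iterate), started
from a profile grid scan and polished to the global profile optimum. The
slope left of the breakpoint is "year 1", the right slope
"year 2" = β₁ + γ; the left-horizontal form fixes year 1 ≡ 0, describing
stasis followed by expansion. SE(ψ) comes from the delta method; slope SEs
carry the breakpoint uncertainty through the augmented working model.

Models are ranked by the small-sample Akaike criterion

    AICc = 2·NLL + 2k + 2k(k+1)/(n−k−1),

where np counts mean-structure parameters *including* ψ and k = np + 1 for
Gaussian models (residual variance) or k = np for binomial ones. Akaike
weights wᵢ = exp(−Δᵢ/2)/Σⱼexp(−Δⱼ/2) express relative evidence. A
pseudo-score test (`pscore_test`) tests for the existence of a breakpoint
without fitting ψ under the null, with a seeded parametric-bootstrap
likelihood-ratio cross-check.

## Worked example

```python
import rangeshift as rs

series = rs.simulate_margin_series(seed=7)   # 6 sites x 5 survey years
x, y = series["year"].to_numpy(), series["distance"].to_numpy()

fit = rs.fit_segmented(x, y, left_constrained=True)
print(f"breakpoint year: {fit.psi_:.1f} (SE {fit.psi_se_:.2f})")
print(f"post-break slope: {fit.slopes_()['year2']:.2f} km/yr")

table = rs.akaike_table(rs.fit_suite(x, y))
print(table.round(4)[["Model", "AICc", "dAICc", "w", "NLL", "np"]])

test = rs.pscore_test(x, y, left_constrained_null=True)
print(f"breakpoint existence: p = {test.p_value:.2e}")
```

prints

```
breakpoint year: 2006.0 (SE 2.71)
post-break slope: 4.70 km/yr
          Model     AICc   dAICc      w      NLL  np
      Quadratic 249.1849  0.0000 0.6458 119.7925   3
Left-horizontal 251.2667  2.0818 0.2280 120.8333   3
      Two-slope 252.4581  3.2732 0.1257 119.9790   4
         Linear 263.5236 14.3387 0.0005 128.3003   2
       Constant 298.4060 49.2211 0.0000 146.9808   1
breakpoint existence: p = 1.11e-12
```

The generator planted stasis at 162.5 km until 2006 followed by expansion at
5.48 km/yr with 17.6 km residual SD; the left-horizontal fit recovers the
breakpoint and rate, the non-monotonic models absorb essentially all Akaike
weight, and the score test rejects "no breakpoint" decisively. `fit` objects
are scikit-learn style estimators (`fit`/`predict`/`get_params`), so they
compose with sklearn tooling; `predict_interval` returns the mean trend with
pointwise Wald bands (inverse-logit mapped for binomial fits).

The same analysis runs from the shell on any conforming CSV
(`site_id, x, y, period, detected`, planar km coordinates):

```
rangeshift simulate --out sim --seed 7
rangeshift margins  --input sim/survey.csv --out series --seed 7
rangeshift fit      --margin-series series/margin_series.csv \
                    --periphery-series series/periphery_series.csv \
                    --out fits --seed 7
rangeshift report   --fits-dir fits
```

Exit codes: 0 success, 2 configuration error, 3 data error, 4 convergence
failure. Every output CSV records the package version, a configuration hash,
and the seed in `#` header lines.

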