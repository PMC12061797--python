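# Methods

This note documents the models, conventions and design choices behind
`qsmflora`, in the order the pipeline runs them.

## Branch data and preprocessing

A branch record is one cut-off branch or subbranch: cut-off diameter (mm),
crown stratum (bot/mid/top — vertical thirds of the crown), crown layer
(in/out — the outer layer is the 2 m from the crown surface inward),
compass direction (stored but not modelled; it drops out of model
selection), its own flower count, and optionally a series of along-shoot
diameter measurements. Flower totals per branch include all subbranches;
`cumulate_flower_counts` performs that summation over the (acyclic) parent
graph and is order-independent.

Detailed shoots are segmented into 5 mm diameter classes assuming linear
taper between consecutive measurements. Classes are half-open
`[lower, upper)`, so a diameter exactly on a boundary belongs to the upper
class exactly once; segment lengths conserve total shoot length to 1e-9 cm.
Simplified records (diameter + total count only) carry no measurements;
they are excluded from density summaries but included in model fitting.
When flower attachment positions are unknown, densities are attributed
only when the whole shoot lies in a single class.

## Farthest-distance subsampling

Branch hierarchies pseudo-replicate: a subbranch's flowers are part of its
parent's total. Each branch is embedded in a six-dimensional space
(ln branch diameter, layer, stratum, compass, tree index, dbh), each
dimension z-standardized (zero-spread dimensions map to 0; a missing
compass maps to the dimension mean). Selection starts at the largest
cut-off diameter and greedily adds the branch maximizing the minimum
distance to the selected *set* (not just the previous pick — the
interpretation that best serves the balance goal); every pick removes its
ancestors and descendants from the pool; ties break on the smallest branch
id, making the result deterministic and permutation-invariant. Selection
stops when the pool is exhausted, so the selected set is maximal.

## The hurdle model

Occurrence is binomial-logit; abundance is a zero-truncated NB2 whose
linear predictor is ln μ of the **untruncated** distribution (the
convention of truncated-NB2 software, which makes published coefficient
sets directly usable). The reported conditional expectation is
μ / (1 − (θ/(θ+μ))^θ) ≥ max(μ, 1). Reference levels are layer = out,
stratum = bot.

Fixed-effects fitting delegates to statsmodels (`Logit`,
`TruncatedLFNegativeBinomialP`), with a moment-based start (OLS on log
counts, α = 0.7) and a method ladder (BFGS → Nelder–Mead → BFGS) for the
truncated part; a stalled line search is accepted only when the score is
numerically zero. Nested random intercepts (cut-off branch within tree)
are integrated by a Laplace approximation: per-tree blocks are maximized
by damped Newton steps exploiting the arrow structure of the penalized
Hessian (diagonal in the branch deviations with a dense border for the
tree deviation), giving O(k) steps and log-determinants. Outer parameters
(β, log σ_tree, log σ_branch, log θ) are optimized by L-BFGS-B. Variance
components of binary data with small groups are weakly identified (the
Laplace profile can go flat for separable groups); the σ upper bound of
5.0 guards that drift and hitting it raises a warning. The
fixed-effects-only path is the deterministic default used everywhere a
reproducible fit is needed.

Marginal means average the linear predictor over a balanced grid of the
other crown factor with ln D and dbh at their training means; pairwise
contrasts use the studentized-range (Tukey) adjustment, which reduces to
the unadjusted z-test for two levels. The reference grid is balanced
(observed-frequency weighting would be an alternative; the choice is
recorded here). R² follows the Nakagawa scheme with the delta-method
residual variance: 1/(p̄(1−p̄)) for the binomial part and 1/μ̄ + 1/θ for
the count part; the variant is recorded in the metrics object. Marginal
metrics use fixed effects only; conditional metrics add the conditional
modes. The LOOCV unit is the random-effect group (the cut-off branch),
refit without the group and predicted marginally.

## QSM geometry

Cylinders are meters in a right-handed +z-up frame (start point + axis +
length, the TreeQSM convention). dbh comes from the trunk cylinder whose
axial span contains 1.3 m above the stem base (at forks, the thickest
continuation on the root path). Crown base height is the lowest base of a
branch-order ≥ 1 cylinder; crown points are the start/end points of crown
cylinders. Crown projection area is the 2D convex hull of those points;
crown diameter defaults to the mean extent over 8 azimuthal directions
(max-extent is available); crown volume is a Delaunay alpha shape (keep
tetrahedra with circumradius < α, default α = 1 m), written in-house
because no installed library provides a 3D alpha shape — the convex hull
(α = ∞) is both the fallback and the oracle used in tests.

Branch units are found by a root-down traversal: the first cylinder along
any path with diameter ≤ 30 mm roots a unit that absorbs its whole
subtree, so units are disjoint and duplicates are impossible. The unit's
bounding-box center is classified into a stratum (thirds of
[crown base, tree top], half-open upward; centers below the crown base
count as bot) and a layer: the convex hull of the crown points in the
center's 0.5 m slice (boundary points go to the upper slice) is eroded
**inward** by 2 m — the field definition of the outer layer is the 2 m
from the crown surface inward — and centers inside the eroded polygon are
`in`; degenerate slices (< 3 points) fall back to `out` with a log entry.

## Upscaling

For each branch unit: D is the root-cylinder diameter (mm), dbh comes from
the replicate's metrics, random effects are zero (marginal prediction for
unobserved branches). A Bernoulli draw at the occurrence probability
decides flowering; flowering units contribute the ZTNB *expected* count by
default — the procedure randomizes occurrence only, which keeps variance
attributable — with full ZTNB sampling behind a flag. Expected counts are
kept fractional (no rounding). Per-replicate streams derive from a master
seed and the replicate index, so runs are exactly reproducible. Per-tree
estimates are medians over replicates (even counts: mean of the central
pair).

## Tree-level allometry and resources

Candidate predictors (dbh, height, crown diameter, projection area,
volume) are screened with Pearson correlations; |r| > 0.7 between
predictors flags collinearity, which is why only single-predictor NB2
models (log link, free intercept) are fitted. Upscaled totals are rounded
to the nearest integer for the NB likelihood (recorded in the model
metadata). Predictions outside the calibration range (dbh 9–28 cm, crown
volume 13.8–282.7 m³ for the reference models) warn rather than fail.

Resource budgets per flower: pollen volume is the sphere volume of the
mean grain diameter (32.63 μm, SE 0.73) times the mean grain count
(16,059, SE 3,327) ≈ 0.29 mm³; nectar production is 3.7 mg/flower/24 h
(range 1.4–6.0) with 23.5% sugar (range 10–37%), the range midpoints.
Larvae counts floor-divide pollen volume by a per-larva requirement; the
shipped requirements (L. laticeps ≈ 10.98 mm³, B. terrestris ≈ 61.6 mm³)
are back-solved from the reference study's printed pollen/larvae pairs and
are configuration defaults, not primary measurements — other species need
user-supplied values. 95% CIs combine a bootstrap over trees (refitting
the dbh model each repetition; a failed refit drops the repetition, > 10%
failures abort) with normal Monte Carlo draws of the four flower-level
parameters: measured SEs serve as SDs, literature ranges are read as 95%
intervals (range/4 as SD), and draws are floored at 1% of the mean to
guard negativity. CIs are 2.5%/97.5% percentiles of the B predictions;
larvae CIs transform the same B pollen predictions per species.

## Synthetic data

The generator emulates the study conditions: 39 trees across 9–28 cm dbh
(uniform), cut-off branches with lognormal diameters clipped to 3–55 mm,
nested subbranches, and counts drawn Bernoulli × ZTNB from the reference
coefficients with independent nested normal random intercepts per part
(θ = 1.5 and SDs 0.3 are generator configuration — the reference study
reports neither). Flower attachment in detailed shoots is
rejection-sampled onto segments thinner than 20 mm, mirroring the
empirical finding that flowers sit only below 2 cm. Cylinder trees are
schematic: a vertical linearly-tapering trunk whose 1.3 m cylinder gets
exactly the requested radius (derived dbh matches by construction),
branches spawned along the crown with multiplicative taper (0.75 per
0.4 m segment) and recursive subbranches down to the 3 mm minimum
diameter; replicates jitter radii and lengths by 1 + N(0, 5%). The
geometry exercises the pipeline (taper, topology, crown extent) but is
not a biological crown-architecture model, crown shapes are simpler and
crown volumes smaller than real cherry crowns — so passing tests validate
the machinery, not cherry-specific magnitudes.

## Problem sizes and numerical choices

The analysis scripts run 12 trees × 5 QSM replicates with 6 cut-off
branches per tree — a size chosen so the whole chain (and its tests)
re-runs comfortably on one CPU while leaving every stage non-trivial.
Parameter-recovery checks use ~620 branches per replicate (50 replicates)
and n = 39 trees (100 replicates); a 200-replicate verification run put
the 2-SE coverage of every fixed effect at ≈ 0.95. Newton/optimizer
tolerances: 1e-8 on the gradient where exposed; Laplace inner iterations
cap at 50 with step halving; ZTNB tail quantities are computed in log
space (`log1p`/`expm1`) for stability.

## Known limitations

* The Laplace variance components for the *binomial* part are unreliable
  on small binary groups (documented warning); glmm-grade inference for
  that part would need adaptive quadrature.
* Stepwise model selection is not automated; the final model formulas are
  the default specification.
* Crown volume from the alpha shape depends on α; no data-driven α
  selection is attempted.
* Resource budgets propagate flower-model and flower-level parameter
  uncertainty only — QSM reconstruction noise enters through replicate
  medians but hurdle-coefficient uncertainty is not propagated into
  per-tree totals.
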