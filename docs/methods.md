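# Methods

## Data model and geometry

Environmental data live in an `EnvStack`: named 2-D grids over one
geographic extent (WGS84 decimal degrees), one resolution (default
1/120° = 30 arc-seconds), a shared boolean validity mask (the union of
per-layer nodata on read), and a per-layer kind, `continuous` or
`categorical`.  Grids are stored rows north→south and indexed row-major
from the NW corner.  A point (lon, lat) belongs to cell
⌊(lon − lon_min)/res⌋, ⌊(lat_max − lat)/res⌋ with half-open intervals;
points on the outer south/east edge are assigned to the last cell so the
extent is closed.  A snap of 1e-9 cell-units in the floor keeps points
sitting exactly on an edge in their intended cell despite floating-point
rounding.

Pixel areas use the spherical formula
A = R²·Δλ·(sin φ_top − sin φ_bot), R = 6371 km, evaluated at each row's
centre latitude; at 30 arc-seconds this is ≈ 0.86 km² at the equator and
≈ 0.61 km² at 45°S, and summed over a latitude band it reproduces the
analytic zone area to ~1e-9 relative error.  A Cartesian mode (unit cell
areas) exists for synthetic fixtures, where exact integer-area arithmetic
makes the fragmentation oracles exact.

Raster I/O is ESRI ASCII grid (`.asc`), one layer per file, nodata
honoured both ways.  Cropping snaps the requested bounds outward to the
source cell grid and is idempotent.

## Occurrence processing

Coordinates are rounded to two decimal places (half away from zero —
stable across platforms, and ~1 km at these latitudes, hence "one record
per cell"); within-species duplicate (lon, lat, presence) rows are
dropped; rows outside the configured extent are removed and counted.
Where one species has both a presence and an absence at the same rounded
location, the presence wins: a confirmed detection overrides a
non-detection.  That conflict rule is a documented choice — nothing in
the protocol we follow specifies it — and the operation is idempotent by
construction.

Absences for a focal species come from the survey-compilation argument:
any cell where some *other* species was recorded (or the focal species
was explicitly recorded absent) was searched; if the focal species was
never found there, the cell contributes exactly one absence.  Presence
and absence cell sets are therefore disjoint by construction.

## Collinearity filtering

VIF_j = 1/(1 − R²_j) from an intercept-included least-squares regression
of predictor j on the others (exact collinearity reports +inf rather than
erroring, so the filter can still rank the pair).  The iterative filter
finds the variable pair with the largest |Pearson r|; while that value
strictly exceeds the threshold (default 0.85), the member with the larger
VIF is removed (ties: the later variable in input order) and everything
is recomputed.  Strictness carries a 1e-12 guard so a correlation equal
to the threshold up to float rounding does not trigger removal.  By
default the filter runs on the design matrix sampled at occurrence
points; `vif_scope: raster` computes it over all masked-in cells instead.
Both are defensible; the point-sample default matches the data the models
actually see.

## Candidate models

Ten methods, each run on 3 independent stratified 80/20
calibration/evaluation splits (per-class test counts rounded to nearest;
classes with ≥ 2 members always appear in both parts; a singleton class
is forced into calibration with a warning).  Record weights solve the
prevalence-0.5 balance: presence weight n/(2·n₁), absence weight
n/(2·n₀), so each class carries half the total weight and weights sum
to n.

Two learners are implemented directly:

* **GLM** — weighted logistic regression fitted by IRLS with a 1e-8 ridge
  on the normal equations (predictions converge under separation even as
  coefficients diverge); categoricals enter as indicator terms.
* **SRE** — the surface range envelope: per continuous variable the
  [q, 1−q] presence-only quantile interval (q = 0.025); prediction is 1
  iff every continuous value is inside its interval and every categorical
  value is a level observed among training presences.

The rest go through a uniform adapter (shared indicator coding for
categoricals; unseen levels map to the all-zero block) over scikit-learn
estimators at their documented defaults, weighted where the backend
supports `sample_weight`:

| method | backing formulation |
|---|---|
| GBM | `GradientBoostingClassifier` |
| CTA | `DecisionTreeClassifier` |
| RF  | `RandomForestClassifier` |
| ANN | `MLPClassifier` (no per-record weights; prevalence acts upstream) |
| FDA | `LinearDiscriminantAnalysis` on a paired-hinge basis, priors ½/½ |
| GAM | logistic regression on a cubic `SplineTransformer` basis (5 knots) |
| MARS | logistic regression on paired hinge features max(x−k,0), max(k−x,0) at 5 quantile knots |
| MAXENT | L1-penalised logistic regression on linear + quadratic features — the maxnet formulation of maximum entropy for presence/absence data |

GAM, MARS and MAXENT are thus our own basis-expansion formulations of the
standard methods rather than bindings to their canonical packages; they
reproduce the methods' functional form (smooth additive terms, adaptive
hinges, regularised feature expansion) with pinned, reproducible
defaults.  A backend failure is recorded as a failed model and excluded
downstream; it never aborts the pipeline.

## Evaluation

ROC is the Mann–Whitney estimator (rank-based; ties get ½ credit).  TSS
scans every midpoint between consecutive distinct predictions plus the
all-present and all-absent extremes; classification is presence iff
prediction > cutoff (strict), and the maximising cutoff (lowest, on ties)
is stored for binarisation.  Sensitivity/specificity are reported in
percent at that cutoff, so TSS = sens/100 + spec/100 − 1 holds exactly.
TSS is reported at its maximising cutoff, not at a fixed 0.5 — the
convention of the ensemble-modelling framework this reproduces.

Permutation importance: for each variable, 1 − max(r, 0) where r is the
Pearson correlation between predictions on intact and column-shuffled
data, averaged over 3 permutations and clipped to [0, 1]; zero-variance
predictions define importance 0 for every variable.

## Ensemble

Members are candidates with evaluation ROC strictly above 0.9; if none
qualifies the gate falls back to 0.8; below that the species gets no
ensemble and is reported, not failed.  Weights are member ROCs normalised
to sum 1, and the ensemble prediction is the pointwise weighted mean.
The ensemble is scored on the full species dataset (the framework
convention; there is no ensemble-level holdout, so treat the ensemble ROC
as resubstitution-flavoured).

Ensemble variable importance: per method, importances are averaged over
all of that method's runs in the candidate set — whether or not each run
is itself a member — then scaled by the method's total member weight
(zero for fully gated-out methods), summed per variable, divided by the
number of methods configured (10 by default, deliberately also counting
methods that contributed no member), and normalised to percentages
summing to 100.

## Range change

The consensus binary map sets a pixel to 1 iff the fraction of candidate
models whose suitability strictly exceeds their own stored cutoff is
strictly greater than 0.5.  The vote is over *all* successfully fitted
candidates, not only ensemble members (configurable).  Transition
classes never/always/lost/gained partition the masked-in pixels — an
assertion checked on every run.  Loss% = 100·lost/current and
gain% = 100·gained/current with current = always + lost; net = gain −
loss.  The no-dispersal mode re-labels the *future* binary map
(8-connectivity by default, queen's case) and counts a gained pixel only
when its patch contains at least one always pixel; this makes
no-dispersal net ≤ dispersal net an invariant, and makes habitat that
shifts wholly to a disconnected island score −100% without dispersal
regardless of how large the gain is with it.  Island separation is
enforced purely by connectivity across the masked sea channel — no
additional island rule exists.

## Fragmentation

Patch identity uses 8-connectivity (configurable to 4) with deterministic
row-major label order; AI adjacencies are rook-only (4), following the
standard FRAGSTATS definitions in which the two concepts differ.  Patch
areas are geodesic via the per-row cell area; patches < 0.1 km² are
removed from the patch set, the metric denominators, and the AI habitat
map.  At ~0.6–0.9 km² cells the filter removes nothing (no single pixel
is that small); it is retained for resolution independence.  SPLIT uses
the total masked-in landscape area; empty habitat reports NaN sentinels;
a single habitat pixel defines AI = 0 (g_max = 0 guard).

## Synthetic study system

`generate_world` builds: a strictly monotone north–south
temperature-analogue gradient (standardised), Gaussian random fields for
precipitation analogues (seeded white noise smoothed with a Gaussian
kernel of 8-cell length scale, standardised — simple, reproducible
spatial autocorrelation), and one categorical soil layer (an independent
field binned into 4 quantile levels).  The default two-island geometry is
a vertical sea channel (6 cells wide), the minimal structure that
exercises the disconnected-gain rule.  Species niches are logistic in the
layers; the default compilation has 14 species, mostly cold-adapted
(negative temperature coefficient, |β| ~ 1–2.5) with a few warm-adapted
lowland relatives, matching the kind of survey compilation the absence
derivation assumes.  Warming scenarios are additive shifts on the
temperature layer — +1.0 and +3.7 layer units by default, the low- and
high-emission analogues — with categorical layers static.

Survey sampling draws sites without replacement from land cells and
records every species at every site as Bernoulli(true suitability), so
both explicit absences and cross-species derived absences exist, as in
real compilations.  What this generator does *not* emulate: spatially
biased sampling effort, observation error/misidentification, niche
responses that are non-logistic or interaction-driven, topographic
microclimate, and temporal mismatch between records and climate
normals.  Passing recovery tests therefore demonstrate that the pipeline
machinery is correct and well-calibrated under its own assumptions, not
that real-data projections carry this accuracy.

## Recovery experiments and problem sizes

The recovery experiment (`enmrange.recovery`) uses a 100×100 world with
400 survey sites and a focal niche dominated by the temperature layer
(|β| = 3), all 10 methods × 3 runs; it measures truth correlation
(Pearson r over land pixels), consensus/truth Jaccard, and — for a
warming scenario calibrated by bisection on the closed-form truth maps to
a −50% true net range change — the pipeline's net-change estimates.
These sizes keep a full experiment at a few seconds on one CPU while
leaving the sampling noise small relative to the recovery tolerances
(r > 0.8, Jaccard > 0.6, ±15 percentage points).  Default test and
pipeline examples use 40–60-cell worlds with 200–300 sites for the same
reason.

## Known limitations

* Ten-method parity with the original modelling framework is functional,
  not bit-for-bit: backends and defaults differ, so per-model scores are
  comparable in distribution, not in value.
* No reprojection: all inputs must already share one geographic grid.
* No partial-dispersal kernels; the two dispersal extremes only.
* GeoTIFF is not read or written; use ESRI ASCII grids.
* The ensemble is evaluated without a dedicated holdout (see above).
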