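# Methods

This note documents the models implemented in `landchange`, the
numerical conventions, the design choices that were genuinely open, and
what the synthetic benchmarks do and do not demonstrate.

## Cross-tabulation and the change budget

All analysis starts from the transition matrix of an aligned map pair:
`C_ij` is the share of the jointly valid (non-nodata at both dates)
study area that was class *i* at time 1 and class *j* at time 2.
Internally the matrix is held in cell counts at full floating precision;
percent conversion divides by the total valid cell count, so the cell
and percent bases are consistent by construction. Nodata cells are
excluded from every denominator: "study area" always means cells valid
at both dates. Classes listed in a caller-supplied class order but
absent from both maps are retained as zero rows/columns so report
shapes stay stable across periods.

Per class, gross gain `C_+j − C_jj`, gross loss `C_j+ − C_jj`, net
change `|gain − loss|`, swap `2·min(gain, loss)` and total change
`gain + loss = net + swap`. These identities hold to 1e-9 on any
matrix built from counts and are enforced by property tests on random
Dirichlet-distributed matrices.

### Published (rounded) matrices

A matrix re-keyed from a printed table is a different numerical animal:
its cells are rounded to two decimals, it rarely sums to exactly 100
(the packaged fixtures drift by ~0.05; tolerance ±0.2, residual
recorded in the report metadata), and its printed marginal vectors —
row/column totals and the gain/loss columns — are rounded independently
of the cells, so they can disagree with the recomputed sums by a few
hundredths (e.g. one fixture row prints a total of 21.23 while its
cells sum to 21.19). Since a publication's derived statistics are only
reproducible from its own marginals, `TransitionMatrix` carries the
printed marginals when available and all downstream formulas prefer
them; matrices built from data always use exact sums. With this
convention the packaged fixtures reproduce every printed budget cell to
two decimals and all but one printed signal cell within ±0.02 (the one
exception, the gain-side deviation for the forest→immature-forest pair
in the first period, is unreachable from its own printed matrix by more
than print rounding and is documented in the regression test).

## The random-process null model for transitions

Under "random gain", a class *j*'s observed total gain is taken as
given and distributed across donor classes proportionally to their
time-1 prevalence, with persistence held fixed:

    G_ij = gain_j · C_i+ / (100 − C_j+),   i ≠ j.

Symmetrically, "random loss" distributes class *i*'s loss across
recipients by time-2 prevalence: `L_ij = loss_i · C_+j / (100 − C_+i)`.
Both satisfy the conservation identity Σ_{i≠j} G_ij = gain_j (so the
deviations sum to zero per class), which the test suite checks to 1e-9.
The deviation `D_ij = C_ij − expectation` is in percentage points of
study area; the ratio `R_ij = D_ij / expectation` is dimensionless and
prevalence-corrected. If a class occupies the whole area at the
conditioning date the expectation is undefined and marked NaN; if the
expectation is zero, R is NaN and the pair is labelled random with an
`undefined_ratio` flag.

### Labelling thresholds

A pair is *systematic-to* when `D > d₀` and `R > r₀`, *systematic-avoid*
when `D < −d₀` and `R < −r₀`, otherwise *random*. No canonical
thresholds exist; the defaults are `d₀ = 0.15` percentage points and
`r₀ = 0.5`. The rationale: D alone is blind to small classes —
construction land in the packaged case study gains only ~0.2–0.3 % of
the study area, yet does so almost exclusively from orchards (R up to
~29) — while R alone explodes on near-zero expectations. Requiring
both, with a deliberately small D floor, keeps exactly the three narrated
dominant transitions (immature forest→forest, cultivated→orchards,
orchards→construction) on both packaged fixtures while dropping
rounding-level noise. Both thresholds are arguments everywhere they
matter.

The ranking of dominant signals keeps only pairs systematic from *both*
perspectives and orders them by `min(|D_gain|, |D_loss|)` descending
(a transition must stand out from the null on the gaining and the
losing side); ties break on class order.

### Rounding modes

Default mode computes at full precision. `rounding="paper"` rounds D
and the expectation to two decimals before forming R, mimicking tables
computed from already-rounded intermediates; this is how a printed
ratio of 29.00 (full precision ≈ 35.5) on a 0.008-expectation cell is
reproduced. Ratio cells with expectation below 0.5 are treated as
rounding-fragile and only regression-tested in paper mode.

## Zone dynamics (LUCDI)

Per zone and class, `Nochange_i` is the area persisting in class *i*,
`Increase_i` the area entering it, `Decrease_i` the area leaving it.
The change dynamic index is the changed-area fraction

    LUCDI = (Σ Increase + Σ Decrease) / (2 · zone valid area),

which is 0 iff the zone is unchanged, 1 iff no cell persists, invariant
to class relabelling, and aggregates as an area-weighted mean over zone
unions (all property-tested). The two-way form deliberately counts
gains as well as losses, so rapidly growing classes in small areas
(urban land) are not underestimated as they are by one-way rate
indices. Dividing by elapsed time inside the index would break the
[0, 1] range, so the annualized value `LUCDI / (t₂ − t₁)` is a separate
field. Zero-area zones yield NaN and a flag rather than an error.

## Kernel surface

Zone values are attached to zone representative points (polygon
centroid, or mean cell centre for raster zones — kept even for
non-convex zones whose centroid falls outside them) and interpolated as
an unnormalized weighted kernel density evaluated at cell centres:
`s(x) = Σ_k w_k K_h(|x − c_k|)`. The default kernel is the planar
quartic (biweight) `K_h(d) = 3/(πh²)·(1 − d²/h²)²` for `d < h`, the
kernel family GIS density tools use; Gaussian is available. Default
bandwidth is one tenth of the longer map extent — with village-scale
zones this keeps neighbouring zones overlapping without flattening the
field — and is configurable. The surface is a relative intensity
(linear in the weights, verified against a double-loop oracle to
1e-9); the kernel and bandwidth used are recorded on the object.

The covariate report is purely descriptive: Spearman rank correlation
of zone LUCDI against per-zone numeric covariates (population growth
rate, GDP, ...), refusing fewer than three matched zones.

## Raster conventions

Row-major grids, origin at the top-left corner, cell centres at
half-cell offsets; areas are cell counts × cell area. The CRS is an
opaque text identifier compared for equality; misaligned or
CRS-mismatched pairs are refused rather than resampled, because
resampling categorical data silently corrupts transition counts.
GeoTIFF georeferencing uses the standard pixel-scale/tiepoint tags with
legend, timestamp and CRS id embedded as JSON in the image description;
ESRI ASCII grids carry a `.legend.csv` (and optional `.prj`) sidecar.
Round-trips are bit-exact for both formats.

## Synthetic data

The generator emulates the structure of classified Landsat map pairs:
a six-class composition drawn i.i.d. from target shares (defaults match
the case-study time-1 composition: ~21 % forest, 31 % immature forest,
35 % cultivated, 10 % orchards, small construction/water classes, on a
Landsat-like 30 m grid), evolved per cell under a row-stochastic Markov
matrix — by default derivable from either packaged fixture via
`markov_from_matrix` (rows `C_ij / C_i+`, identity rows for absent
classes). Optional majority-smoothing passes (3×3 neighbourhood, ties
to the lowest class code, applied after stochastic assignment) create
spatial autocorrelation deterministically, so every output is exactly
reproducible from its seed; change-clustering passes smooth only the
changed cells. Zones are Voronoi regions grown from uniformly sampled
seed cells — a wall-to-wall partition resembling village boundaries.

What the generator does *not* emulate: classification error and its
spatial structure, radiometry, cloud masks, real village geometry, or
spatially heterogeneous transition probabilities (the Markov law is
stationary in space). Passing the recovery benchmarks therefore shows
the estimators are correct for the stated generative model, not that
classification noise in real maps is handled — on real data,
misclassification inflates apparent change and especially the swap
component.

## Benchmark problem sizes

The statistical recovery checks use 500×500 grids (250 000 cells),
where each joint transition share has binomial standard error below
0.1 percentage points, comfortably inside the ±0.5 acceptance band;
oracle-equivalence checks use 20 pairs of 200×200 cells with 4–25
zones, and conservation properties use 100 random 6×6 matrices. These
sizes were chosen to make sampling error negligible relative to the
tolerances while keeping the full suite fast.

## Known limitations

- Only two-date analyses; no chained multi-date matrices or intensity
  analysis across intervals.
- No significance testing of deviations; D/R thresholds are descriptive
  cutoffs, not hypothesis tests.
- No accuracy-adjusted (error-matrix-weighted) area estimation.
- No reprojection: inputs must already share grid and CRS.
- The published-matrix mode can only be as self-consistent as the
  printed table it is given; residuals and marginal drift are surfaced
  in metadata rather than corrected.
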