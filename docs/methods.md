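# Methods

## Model

`worldseasons` treats season delineation as a constrained clustering problem
on the climatological year of one location. The twelve months are points in a
small feature space; a season is a cluster of months; and, outside the
tropics, a season must occupy one circularly contiguous run of months — once
it ends it cannot reappear within the annual cycle. The number of seasons is
fixed per climate zone (4 temperate, 2 elsewhere), which turns k-means'
usual weakness — having to choose k — into a strength.

### Zonation

Zonation is a fixed decision list (desert → arctic/high-montane → tropical →
temperate). Evaluation order matters and is part of the model: aridity is
tested first because cold deserts (Gobi, Tibetan plateau, arid tundra) also
satisfy the arctic temperature criterion, and their seasonality is thermal,
not nival. The arctic criterion is read on the monthly-mean *minimum*
temperature (max over months ≤ 10 °C), i.e. a frost is possible in any
month; this deliberately differs from the classic Köppen criterion on mean
temperature. The tropical gate combines high rainfall seasonality (range >
81.972 mm), low thermal seasonality (range < 7.52 °C) and year-round warmth
(coldest-month midpoint ≥ 18 °C); the warmth floor excludes
ocean-moderated cold coasts that are thermally flat but not tropical.

Boundary comparisons are strict (">" / "<") on the two tunable ranges and
inclusive elsewhere. The desert cutoff (AI < 0.2) is the UNEP arid/semi-arid
boundary; it and the 18 °C and 10 °C thresholds are fixed by convention and
excluded from tuning, consistent with the nine-parameter space.

### Features and weighting

Every feature is z-scored per pixel with the sample (n−1) standard
deviation before clustering, making clustering invariant to each variable's
units and to positive affine rescaling. Zero-variance series normalize to
zeros rather than NaN, so a degenerate variable (NDVI over barren ground)
drops out of the distance rather than poisoning it — the reason deserts need
no NDVI imputation.

A weight w scales a z-scored column by √w, so it multiplies that variable's
contribution to squared Euclidean distance by exactly w; "four times the
weight" means four times the influence on the clustering objective, not on
the coordinates. A linear-scaling toggle exists for comparison
(`build_feature_matrix(..., linear_weights=True)`).

The temperate and tropical feature sets use the precipitation *lag* rather
than the precipitation level (a `precip_level=True` switch substitutes the
level): the lag encodes when rainfall is rising or falling, which is what
separates transitional seasons. The temperature lag is excluded in the
tropics, where month-to-month temperature change is small and non-smooth, so
its sign is mostly noise.

### Clustering and the contiguity constraint

`kmeans_months` is a purpose-built k-means for twelve points: one
deterministic farthest-point start plus k-means++-style random restarts (50
by default), all restarts iterated in a single vectorized Lloyd loop, best
SSE kept, empty clusters re-seeded with the worst-fit point. It is exact
enough that on random 12×2 matrices it attains the global optimum over all
2047 bipartitions in ≥ 90% of instances (verified against exhaustive
enumeration in the tests), and fast enough (~100 µs) that the tuner can
afford ~10⁵ pixel classifications. scikit-learn's KMeans is used in the test
suite as an independent cross-check, never in the pipeline.

Contiguity is enforced post-hoc: the k-means labeling is projected onto the
circularly contiguous k-arc partition (C(12,k) cut-sets: 66 for k=2, 495 for
k=4) that disagrees with it in the fewest months, arcs matched to clusters by
optimal assignment; ties resolve to the lower within-cluster SSE, then to
the lexicographically smallest cut-set. An exhaustive SSE-optimal contiguous
solver (`contiguous_partition_oracle`) serves as the exact reference: the
projected partition can never beat it, and on feature matrices of randomized
two-season pixels it coincides with it in ~96% of instances. On
structureless (iid Gaussian) matrices the coincidence rate drops to ~50%,
because the unconstrained optimum's nearest contiguous neighbour need not be
the best contiguous partition; real annual cycles are smooth, so the
pipeline's inputs behave like the former, not the latter.

Degenerate pixels: if a temperate pixel cannot support four distinct
clusters (near-constant climate), the exact k=4 contiguous solver is used
directly — it always returns four nonempty arcs. A fully constant feature
matrix collapses to a single flagged cluster in two-season zones.

### Naming

Two-season zones are named by contrast between cluster means: warmer =
summer (arctic) / hotter (desert), rainier = wet (tropical). Temperate arcs
are anchored on the extreme months: the arc containing the coldest month is
winter, the arc containing the warmest is summer, the arc running forward in
circular time from winter to summer is spring and the remaining arc autumn.
Anchoring on extremes rather than arc means is deliberate: with arcs of
unequal length, a long cold arc's mean is dragged up by its shoulder months,
and a mean-based rule then hands "winter" to a short transitional arc that
excludes midwinter — an artefact, not a climate signal. Arc means remain the
fallback when both extremes fall in one arc, and a warming-tendency
tie-break separates spring from autumn if winter and summer are adjacent.

## Reference data and the error function

Reference calendars are per-city month→season records in a canonical
six-word vocabulary (winter/spring/summer/autumn/dry/wet). Heterogeneous raw
tropical labels are canonicalized through a fixed 19-row recoding table
("Harmattan" → dry, "Long Rainy Season" → wet, ...); temperate names pass
through lowercased; unknown labels are an error, not a guess.

A prediction scores one error point per mismatching month (0–12). When the
reference vocabulary and the predicted calendar disagree about the
temperate/tropical distinction itself, the city's error is capped at 6,
applied symmetrically to both confusion directions: zone confusion is
penalized, but not allowed to contribute double the weight of a fully
misaligned within-zone calendar. Desert and arctic predictions compare
month-wise with no cap. The 70/30 train/test split rounds the training size
to the nearest integer (573 of 818).

## Tuning

The nine free parameters are fitted by iterated random search: 40% of the
budget samples uniformly within bounds (temperature range 3–14 °C,
precipitation range 80–130 mm, weights 0.25–4), the rest perturbs randomly
chosen current elites with Gaussian noise (σ = 8% of each bound's width),
truncated to bounds. Every candidate is scored on the full training set —
at ~2 ms per pixel classification, per-instance racing would save nothing at
these scales. The five lowest-training-error configurations are re-scored on
held-out cities and the lowest test error wins (ties: lower training error).
The search is deterministic given its seed; classification inside the tuner
uses 20 k-means restarts (50 elsewhere), a cost/robustness trade-off that
does not change results on well-separated seasonal data.

## The synthetic generator

The generator emulates the *structure* that defines each zone — sinusoidal
temperate cycles, monsoonal tropical rainfall (one or two peaks) under
near-constant heat, high-amplitude arid temperature cycles over near-zero
rainfall, year-round-cold arctic cycles with a solstice-peaked radiation
curve — with parameters chosen so each noise-free archetype passes its
zone's gate with a wide margin (and for temperate/tropical archetypes, under
*every* in-bounds threshold setting, which is what makes tuning
recoverable). NDVI tracks temperature (temperate) or rainfall (tropics) with
a one-month delay, reproducing the phenological lag the lag-features are
designed to detect.

What it does not emulate: spatial autocorrelation beyond smooth ±8%
parameter drift within raster blocks, interannual variability, coastal and
orographic effects, or the mixed/marginal climates that straddle zone gates.
Passing tests on synthetic data therefore demonstrate the algorithm's
internal correctness and robustness to measurement-scale noise, not
classification accuracy at real zone boundaries.

Ground truth is analytic, from the generating series rather than the
classifier: two-season truth takes the six months with the warmest (or
rainiest) noise-free values; temperate truth is the phase quarters of the
temperature sinusoid centred on its coldest month. Reference-record noise is
modelled as uniform same-zone label flips with probability p per month (the
simplest emulation of offset-style disagreement), giving a calibrated
expected mean error of 12p months.

Default noise (`noise_sd = 1`) corresponds to σ = 0.5 °C on monthly
temperature, 6% on precipitation, 4% on PET, 0.02 NDVI and 5 units of
radiation — roughly the scale of disagreement between gridded climatologies.

## Numerical and I/O choices

* Monthly aridity is precip/PET with the denominator floored at 0.1 mm;
  annual aridity is Σprecip/ΣPET (an error if ΣPET = 0).
* Weekly→monthly NDVI aggregation assigns each observation wholly to the
  month containing its timestamp; empty months propagate NaN.
* Continuous rasters resample bilinearly onto the target grid; categorical
  outputs reproject nearest-neighbour.
* Focal smoothing is a 3×3 modal filter per month layer (window
  configurable, odd ≥ 3); nodata and *different-zone* neighbours do not
  vote, so labels cannot bleed across zone boundaries; ties retain the
  centre value. Because the vote is spatial only, a mandatory per-pixel
  repair pass (`repair=False` to disable) afterwards projects every
  non-tropical pixel back onto its Hamming-nearest contiguous calendar.
* Equal Earth (EPSG:8857) is implemented from its closed-form polynomial on
  the WGS84 authalic sphere (forward exact; inverse by Newton iteration,
  tolerance 1e−12 on the auxiliary latitude).
* GeoTIFF I/O writes/reads the ModelPixelScale, ModelTiepoint,
  GeoKeyDirectory and GDAL_NODATA tags directly; north-up transforms only.

## Problem sizes

The test suite and acceptance checks run at desk scale by design: rasters of
4×4–10×10 cells, reference cohorts of 30–102 synthetic cities, tuning
budgets of 2000 evaluations over ~25 training cities (≈ 1 minute per seed),
and 100–500-instance Monte-Carlo checks for the oracle-match and
winter-recovery rates. Full-resolution global runs use the same code paths
through the CLI but are not part of the tests.

## Known limitations

* The zonation thresholds fixed by convention (0.2 aridity, 18 °C, 10 °C)
  are configurable but untuned; real-world sensitivity near those gates is
  unquantified here.
* Season naming in the temperate zone assumes a thermally driven cycle;
  Mediterranean-type climates where the ecological year is rain-driven still
  receive thermal names.
* The contiguity projection is greedy in Hamming distance; it is provably
  never better than the exact contiguous solver and empirically matches it
  on seasonal data, but pathological (non-seasonal) inputs can land on a
  suboptimal contiguous partition.
* `city_error` compares calendars month-by-month with no tolerance for
  one-month offsets, which real reference data exhibit; mean errors on real
  cities are therefore expected to be substantially above the synthetic
  recovery errors reported by the tests.
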