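# Methods

`freshmap` implements an automated cropland-extent mapping scheme for the
situation where no in-season ground truth exists but an outdated land cover
map does. The chain has four stages — spectral-temporal compositing,
reliable-pixel harvesting, stratified soft classification with fusion, and
confidence-weighted post-filtering — followed by a global and spatially
explicit accuracy assessment. Every stage is exercised on seeded synthetic
scenes, so the whole pipeline is testable offline.

## Synthetic scenes

`scene_sim` generates the inputs the method assumes rather than emulating a
particular sensor. A scene is a jittered rectangular tiling of fields
(default side 8–24 px), each assigned one of nine land cover classes
(cropland, irrigated cropland, grassland, shrubland, forest, water,
built-up, bare, wetland) with cropland-heavy weights typical of an
agricultural region. Each class carries a seasonal NDVI trajectory
`base + amplitude·sin(2π(t − phase))`; red and NIR are back-computed from
the trajectory (so the noise-free NDVI of a pixel matches its class curve
exactly) and the two SWIR bands interpolate between a senescent/bare level
and a peak-canopy moisture level as NDVI rises. Defaults: 24 observations
over one season, Gaussian reflectance noise sd 0.02, 25 % of (pixel, date)
observations removed as "cloud", three vertical stratum bands. Identical
(config, seed) pairs are bit-identical.

The degraded "outdated" map injects the two error types an old map
accumulates: a uniform per-pixel relabeling (classification error; default
experiments use 20–25 %) and whole-field relabeling (spatially coherent
land cover change; 10 % of fields). What the generator deliberately does
*not* model: mixed (sub-pixel) field-boundary signal, sensor point-spread
effects, co-registration shifts, topographic or atmospheric residuals.
Passing tests therefore demonstrate the internal consistency and the
statistical behaviour of the method, not its accuracy on real imagery —
on real data boundary pixels are the dominant error source, which is why
the erosion steps exist at all.

A separate helper, `scene_sim.simulate_memberships`, produces a noisy soft
classification of a truth map directly (one-hot class logits + Gaussian
noise through a softmax). It exists for filter experiments: argmax errors
arise from near-ties, so wrong pixels are isolated and carry systematically
lower ERP — the structure the weighted filter exploits — without paying for
a full classification run per replicate.

## Spectral-temporal features

Per pixel, only clear observations enter; three statistics of the four
bands give twelve features: per-band median; mean reflectance over the
observations in the lowest decile of the pixel's NDVI values (`minNDVI.*`,
targeting bare soil at planting); the same for the highest decile
(`maxNDVI.*`, peak canopy). Decile membership is inclusive of the empirical
0.1/0.9 quantile, which guarantees a non-empty composite for any number of
valid observations. Observations with undefined NDVI (red+NIR = 0) are
excluded from decile selection but still count toward medians. Pixels with
fewer than `min_valid = 3` clear observations become nodata: below three,
the "decile" degenerates to the same single observation as the extremes and
the median is fragile. Even-length medians are the mean of the central
pair. A pixel missing any feature band is wholly nodata, since
classification needs the complete 12-vector.

## Reliable-pixel harvesting

1. **Erosion.** A class-wise 3×3 (8-connected) erosion, one iteration,
   removes every pixel adjacent to a different label or to nodata; the
   image border counts as nodata. This guards against co-registration
   artefacts and, on synthetic scenes, removes nearly all isolated label
   flips.
2. **Cluster purity.** For each focal class: up to 5,000 focal pixels and
   10,000 pixels of the remaining classes are drawn without replacement,
   standardized, and clustered with a self-organizing map. Focal pixels in
   clusters whose focal-class share is ≥ 0.75 (inclusive) are reliable.
   Pixels relabeled by simulated land-cover change survive erosion (they
   are coherent blocks) but land in clusters dominated by their spectral —
   i.e. true — class, and are rejected here.
3. **Distribution filter.** Reliable rows outside the empirical
   [2.5, 97.5] percentile interval of their class in *any* of the 12 bands
   are dropped. Percentiles, not mean ± 1.96 sd: robust to the heavy tails
   that surviving mislabels create. Below 20 rows the filter passes
   everything through (the interval would be noise).
4. **Proportional re-sampling.** Class quotas follow the class proportions
   of the eroded outdated map within the stratum (largest-remainder
   rounding to a 5,000-row target); within a class, rows are picked by
   greedy farthest-point (max–min) selection in standardized feature space,
   starting from the row nearest the class centroid, which spreads the
   sample across the class's spectral variability. Classes with fewer
   reliable rows than quota contribute everything they have.

The SOM is a small seeded online Kohonen map (Gaussian neighbourhood,
linearly decaying rate and radius, data-point initialisation, 1,000 sample
presentations; default grid ≈ 5·√n nodes capped at 16×16, and a fixed 8×8
in the pipeline defaults). It is used purely as a quantizer — cluster id =
best-matching unit.

## Classification, fusion, confidence

Each stratum trains a 500-tree random forest with ⌊√12⌋ = 3 candidate split
variables per node; forests tolerate the residual label noise the
harvesting leaves (robustness to ~25 % symmetric flips is checked in the
tests). Prediction covers the stratum polygon plus a buffer (default 8 px
on synthetic scenes; a third of a degree is the geographic convention), so
neighbouring strata overlap. Overlapping membership vectors are fused by a
componentwise geometric mean renormalized to sum 1; zero votes are floored
at 1e-6 first so a single zero cannot annihilate a class. Models trained on
different class subsets are first widened to the union class list with zero
membership for unseen classes. The final label is the maximum membership;
exact ties go to the lowest class id and are counted.

**ERP.** The Equivalent Reference Probability maps a membership vector
p (n ≥ 2) to the M ∈ [1/n, 1] such that the reference distribution
(M, (1−M)/(n−1), …) has the same Shannon entropy as p, using 0·log 0 = 0.
The reference entropy is strictly decreasing in M on [1/n, 1], so bisection
(tolerance 1e-8) finds the unique root. ERP = max(p) exactly when p is
reference-shaped, 1/n for uniform, 1 for degenerate vectors, and is
monotone decreasing in the entropy of p.

## Post-filtering

The conventional majority filter relabels each pixel to the most frequent
class in its 3×3 window; the weighted variant scores each class by the sum
of the window-normalized ERP values of its members. Since window
normalization rescales all class scores by the same positive factor, the
implementation accumulates raw ERP sums; the argmax is unchanged. Ties keep
the centre label (conservative: the input survives where evidence is
balanced); windows truncate at borders; nodata members are excluded from
votes and normalization; nodata centres stay nodata; one pass. Both filters
are verified against a brute-force per-window tally. Binarization collapses
the legend to cropland = {cropland, irrigated cropland} vs everything else.

## Assessment

Overall accuracy comes with a binomial standard error √(OA(1−OA)/N) (the
reference set is a complete relabeling, so a binomial model is the natural
choice). Per-class F-scores are the harmonic mean of user's and producer's
accuracy. The edge-eroded variant discards reference boundary pixels with
the same erosion as the sampler before counting. Local accuracy repeats the
computation in square windows centred on a regular grid (defaults mirror a
40-unit spacing with 90-unit windows, interpreted in map units — pixels for
synthetic scenes); points with fewer than 500 reference pixels are masked,
and the point OA is interpolated with inverse-distance weighting (power 2),
which is exact at the points and bounded by their extrema.

Confidence separation uses a two-sided Mann–Whitney–Wilcoxon test (midrank
convention) between the ERP of correctly and incorrectly classified
cropland pixels; groups below 20 pixels yield an explicit not-applicable
result, and an all-tied comparison reports p = 1.

Feature importances (per-stratum Gini) are compared with a tie-corrected
Friedman test on within-stratum midranks (rank 1 = most important) and a
post-hoc Nemenyi critical difference CD = q_{α,k}/√2 · √(k(k+1)/(6N)), with
q from the studentized-range distribution at infinite df by default. The
df is exposed as a parameter because published CD values sometimes follow a
finite-df convention (for k = 12, N = 9 the infinite-df constant gives
CD ≈ 5.55). The Friedman statistic is validated two ways: against an
independent library implementation, and against an exhaustive permutation
null at k = 3, N = 4. That null is discrete (the largest deterministic
level below 0.05 is ≈ 0.042), so the exact level-0.05 calibration check
uses the standard randomized p-value P(T > t) + U·P(T = t), which is
uniform under the null.

## Problem sizes and numerical conventions

The end-to-end experiments run five 256×256 scenes with 24 dates and three
strata; harvesting experiments use 128×128 scenes, and filter-ordering
experiments ten 96×96 scenes with simulated memberships. These sizes give
stable statistics (≈ 65k pixels, ≈ 2,000–5,000 training rows per stratum)
while keeping a full study in the low minutes on one core. Tolerances:
membership normalization 1e-9, ERP bisection 1e-8, filter score ties 1e-12.
All stochastic steps descend from a single integer seed through
`numpy.random.default_rng`; equal seeds give bit-identical outputs.

## Known limitations

- Field geometry is rectangular and pure-pixel; there is no mixed-signal
  boundary regime, so the edge-eroded accuracy gain is far smaller on
  synthetic scenes than it would be on resampled real imagery.
- The intra-class dissimilarity subsampling is a greedy farthest-point
  stand-in for the published-but-unspecified original procedure.
- The ERP construction is entropy matching; it satisfies all the
  documented properties of the original confidence measure (consistency
  with the maximum for reference-shaped vectors, full use of the
  probability vector, unity for confident pixels) but has not been checked
  against the original reference implementation.
- Strata are vertical bands by default; arbitrary polygons are accepted but
  the buffered-overlap logic assumes a planar (non-geographic) grid for
  synthetic scenes.
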