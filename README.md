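# freshmap

Automated cropland-extent mapping when no in-season ground truth exists but
an **outdated land cover map** does.

Producing up-to-date cropland maps over large areas is limited by the cost
of collecting calibration data. `freshmap` implements a fully automated
alternative: it treats an old land cover map as a noisy label source,
repairs it spectrally, and trains regionally stratified classifiers on the
repaired labels. The package is aimed at remote-sensing practitioners and
methods researchers; every stage runs on seeded synthetic scenes, so the
whole pipeline can be developed, tested and benchmarked offline.

## The method

Given a multi-date 4-band reflectance stack (red, NIR, SWIR1, SWIR2) with a
per-observation cloud mask, an outdated categorical map on the same grid,
and stratum polygons:

1. **Spectral-temporal features.** Each pixel's masked time series is
   collapsed into 12 features: per-band median, mean reflectance over the
   lowest decile of the pixel's NDVI values (bare-soil/minimum-vegetation
   target), and the same for the highest decile (peak canopy), with
   NDVI = (NIR − red)/(NIR + red).
2. **Reliable-pixel harvesting.** Per stratum and class *c*: erode class
   boundaries (3×3, 8-connected); draw ≤ 5,000 class-*c* pixels plus
   ≤ 10,000 others; cluster with a self-organizing map; keep the class-*c*
   pixels in clusters with purity ≥ 75 %; drop rows outside the class's
   95 % band interval in any feature; rebuild a 5,000-row training set at
   the map's class proportions with greedy farthest-point selection.
3. **Stratified soft classification.** One 500-tree random forest per
   stratum (⌊√12⌋ = 3 split candidates); prediction over the buffered
   stratum; overlaps fused by a renormalized componentwise geometric mean
   of the membership vectors p = (p₁,…,pₙ); label = argmax pᵢ. Per-pixel
   confidence is the Equivalent Reference Probability (ERP): the
   M ∈ [1/n, 1] whose reference distribution (M, (1−M)/(n−1), …) has the
   entropy of p.
4. **Post-filtering.** 3×3 majority filter M(s) = argmax_i Σⱼ I(hⱼ(s)=i),
   or its confidence-weighted form M_w(s) = argmax_i Σⱼ ωⱼ I(hⱼ(s)=i) with
   ωⱼ the window-normalized ERP; then binarization to cropland vs
   non-cropland.
5. **Assessment.** Confusion matrix, overall accuracy OA ± √(OA(1−OA)/N),
   per-class F-scores (harmonic mean of user's and producer's accuracy),
   optionally after eroding reference edges; local accuracy on a regular
   grid of square windows with an inverse-distance-weighted surface;
   Mann–Whitney separation of ERP between correct and wrong cropland
   pixels; Friedman + Nemenyi ranking of per-stratum Gini importances.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```bash
python examples/03_full_pipeline.py
```

builds a 128×128 scene (24 dates, two strata), degrades its map with 20 %
label flips and 10 % changed fields, and runs the full pipeline:

```
binary cropland map vs truth (16384 pixels):
  OA    = 0.937 +/- 1.90e-03 (binomial SE)
  FS_C  = 0.927  (cropland F-score)
  FS_NC = 0.945  (non-cropland F-score)
  OA after edge erosion = 0.939
  argmax ties broken: 0
ERP confidence: mean 0.944, 78.5% of pixels above 0.9
```

OA is the fraction of pixels whose binary label matches the truth; FS_C /
FS_NC are the class-specific F-scores; the edge-eroded OA discards
reference boundary pixels before counting. Despite training exclusively on
the degraded map, the harvested labels are almost entirely correct
(`examples/02_features_and_harvest.py` prints the repair: ~68 % raw map
agreement → ~100 % training-label correctness), which is what carries the
final accuracy.

The other examples cover scene simulation (`01`), harvesting (`02`), filter
comparison and confidence separation (`04`), and local accuracy surfaces
plus feature-importance ranking (`05`). A thin CLI wraps the two shell
entry points: `freshmap simulate` and `freshmap run` (see `--help`).

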