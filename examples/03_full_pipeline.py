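"""Run the complete mapping pipeline and assess the binary cropland map.

Feature compositing -> per-stratum harvesting and random forests ->
buffered prediction, geometric-mean fusion, ERP confidence -> weighted
majority filtering -> binarization -> accuracy against the scene truth.
"""

from freshmap import scene_sim
from freshmap.pipeline import run_pipeline

cfg = scene_sim.SceneConfig(width=128, height=128, n_dates=24, stratum_count=2, seed=1)
bundle = scene_sim.generate_scene(cfg)
outdated = scene_sim.make_outdated_map(
    bundle.truth, flip_rate=0.2, change_fraction=0.1, seed=2, fields=bundle.fields
)

result = run_pipeline(bundle, outdated, seed=3, n_training=2000)

rep = result.report
print(f"binary cropland map vs truth ({rep.n} pixels):")
print(f"  OA    = {rep.oa:.3f} +/- {rep.se_oa:.2e} (binomial SE)")
print(f"  FS_C  = {rep.f_score(1):.3f}  (cropland F-score)")
print(f"  FS_NC = {rep.f_score(2):.3f}  (non-cropland F-score)")
print(f"  OA after edge erosion = {result.report_eroded.oa:.3f}")
print(f"  argmax ties broken: {result.tie_count}")
conf = result.confidence.erp[~result.confidence.nodata_mask]
print(f"ERP confidence: mean {conf.mean():.3f}, "
      f"{(conf > 0.9).mean():.1%} of pixels above 0.9")
print("-> high OA despite the degraded training source: the harvesting,")
print("   fusion and confidence-weighted filtering each remove one error mode")
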