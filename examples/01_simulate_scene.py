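"""Generate a synthetic agricultural scene and degrade its land cover map.

Builds a 128x128 scene of rectangular fields with class-specific seasonal
reflectance, then injects the two error types of an outdated map: uniform
label flips and whole-field land cover change.
"""

import numpy as np

from freshmap import scene_sim

cfg = scene_sim.SceneConfig(width=128, height=128, n_dates=24, seed=42)
bundle = scene_sim.generate_scene(cfg)
outdated = scene_sim.make_outdated_map(
    bundle.truth, flip_rate=0.2, change_fraction=0.1, seed=43, fields=bundle.fields
)

print(f"scene: {bundle.shape[0]}x{bundle.shape[1]} pixels, "
      f"{bundle.stack.n_dates} dates, {len(bundle.fields)} fields")
print(f"cloud gaps: {1 - bundle.stack.valid.mean():.1%} of observations invalid")
for cid, name in bundle.truth.legend.items():
    share = (bundle.truth.labels == cid).mean()
    if share:
        print(f"  class {cid} ({name}): {share:.1%} of area")
agreement = (outdated.labels == bundle.truth.labels).mean()
print(f"outdated map agrees with truth on {agreement:.1%} of pixels")
print("-> the disagreement combines isolated flips (classification error)")
print("   and whole relabeled fields (simulated land cover change)")
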