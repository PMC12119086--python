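"""Vessel cross-section dynamics and variance attribution.

Estimates the vessel cross-section from the dark lumen (0.5th-percentile
binarization + moment ellipse), extracts the lumen-ROI fluorescence
proxy, and asks how much of the neuronal population signal the vessel
dynamics explain (R^2 after 0.5 s smoothing).
"""

import numpy as np

from hemoccl import (SceneConfig, dff_pipeline, moving_average, simulate_scene,
                     variance_explained, vessel_area_trace, vessel_lumen_trace)
from hemoccl.pipeline import scene_rois

scene = simulate_scene(SceneConfig(duration_s=300.0, n_mismatch=6, n_opto=4,
                                   seed=2))
rate = scene.config.frame_rate
rois = scene_rois(scene)
box = next(r for r in rois if r.kind == "vessel_box")
lumen_roi = next(r for r in rois if r.kind == "vessel_lumen")
somas = [r for r in rois if r.kind == "soma"]

measurement = vessel_area_trace(scene.stack, box)
lumen = vessel_lumen_trace(scene.stack, lumen_roi, rate)
traces, _ = dff_pipeline(scene.stack, somas, rate, register=False)
neurons = np.mean([t.values for t in traces.values()], axis=0)

smooth = lambda x: moving_average(x, rate, 0.5)
true_area = scene.cross_section_um2
print(f"fitted ellipse area vs true cross-section: "
      f"r = {np.corrcoef(measurement.area_px2, true_area)[0, 1]:.3f}")
print(f"lumen proxy vs true cross-section: "
      f"r = {np.corrcoef(lumen, true_area)[0, 1]:.3f} (anticorrelated: the "
      "lumen brightens as the vessel constricts)")
r2 = variance_explained(smooth(lumen), smooth(neurons))
print(f"variance of the neuronal population signal explained by the "
      f"lumen proxy: R^2 = {r2:.2f}")
print("High R^2 with zero injected neuronal activity is the signature of "
      "hemodynamic occlusion.")
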