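"""Extract drift-corrected dF/F0 traces from a rendered stack.

Registers the stack (integer-pixel cross-correlation), averages soma
ROIs, removes slow drift with an 8th-percentile 66 s filter, and
normalizes by the median fluorescence F0.
"""

import numpy as np

from hemoccl import SceneConfig, register_frames, simulate_scene, dff_pipeline
from hemoccl.pipeline import scene_rois

scene = simulate_scene(SceneConfig(duration_s=120.0, photon_scale=2.0,
                                   jitter_amplitude_px=2, seed=2))
rois = [r for r in scene_rois(scene) if r.kind == "soma"]

registered, shifts = register_frames(scene.stack, radius=5)
recovered = np.array_equal(shifts, scene.truth.injected_shifts)
print(f"registration: max |shift| {np.abs(shifts).max()} px, "
      f"injected jitter recovered exactly: {recovered}")

traces, _ = dff_pipeline(registered, rois, scene.config.frame_rate,
                         register=False)
for roi_id, tr in list(traces.items())[:3]:
    print(f"{roi_id}: F0 = {tr.f0:.1f} a.u., dF/F0 range "
          f"{tr.values.min():+.3f}..{tr.values.max():+.3f}")
print("dF/F0 is dimensionless; occlusion-driven deviations of a few "
      "percent mimic the amplitude of real indicator transients.")
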