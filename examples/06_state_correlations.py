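"""State-dependent pairwise correlations.

A shared occlusion signal driven by locomotion raises correlations
between simultaneously imaged neurons specifically while the animal
runs — a population-level fingerprint distinguishing occlusion from
independent neuronal noise.
"""

import numpy as np

from hemoccl import (SceneConfig, locomotion_state_mask,
                     pairwise_state_correlations, simulate_scene, dff_pipeline)
from hemoccl.pipeline import scene_rois

scene = simulate_scene(SceneConfig(duration_s=600.0, photon_scale=2.0,
                                   soma_noise_sd=0.05, seed=4))
somas = [r for r in scene_rois(scene) if r.kind == "soma"]
traces, _ = dff_pipeline(scene.stack, somas, scene.config.frame_rate,
                         register=False)
state = locomotion_state_mask(scene.behavior.running_speed_cmps)

results = pairwise_state_correlations(
    {rid: t.values for rid, t in traces.items()}, state)
loc = np.nanmean([r.corr_locomoting for r in results])
sta = np.nanmean([r.corr_stationary for r in results])
print(f"frames: {int(state.sum())} locomoting / {int((~state).sum())} stationary")
print(f"mean pairwise correlation while locomoting:  {loc:.3f}")
print(f"mean pairwise correlation while stationary: {sta:.3f}")
print("Correlations rise during locomotion because every soma is dimmed "
      "by the same dilating vessel.")
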