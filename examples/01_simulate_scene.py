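"""Simulate a synthetic occlusion session and inspect its ingredients.

Builds a 5-minute closed-loop session: locomotion bouts, gratings, 1 s
visuomotor mismatches, a surface vessel whose cross-section responds to
events, and a rendered 64x64 frame stack in which soma fluorescence is
multiplicatively occluded by vessel dilation.
"""

import numpy as np

from hemoccl import SceneConfig, simulate_scene

config = SceneConfig(duration_s=300.0, n_mismatch=6, n_opto=4,
                     photon_scale=2.0, seed=1)
scene = simulate_scene(config)

log = scene.behavior
area = scene.cross_section_um2
print(f"frames: {len(log)} at {config.frame_rate:g} Hz "
      f"({config.duration_s:.0f} s)")
print(f"locomoting fraction: {np.mean(log.running_speed_cmps >= 0.25):.2f}")
print(f"mismatch events: {int(np.sum(np.diff(log.mismatch_on.astype(int)) == 1))}")
print(f"vessel cross-section: baseline {config.baseline_cross_section_um2:.0f} um^2, "
      f"range {area.min():.0f}..{area.max():.0f} um^2")
print(f"stack: {scene.stack.shape}, mean intensity {scene.stack.mean():.1f} photons/px")

# dilation darkens the measured soma signal: the attenuation factor dips
# below 1 whenever the vessel is larger than its baseline
atten = scene.truth.attenuation[0]
print(f"attenuation of soma 0: min {atten.min():.3f}, max {atten.max():.3f} "
      "(1 = unoccluded)")
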