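"""Event-triggered responses and per-neuron responsiveness.

Detects locomotion onsets (0.25 cm/s, 1 s persistence), slices
peri-event windows, subtracts pre-onset baselines, and tests each ROI's
per-trial response means against zero with a t-test at alpha = 0.05.
"""

import numpy as np

from hemoccl import (RunConfig, SceneConfig, run_pipeline)

cfg = SceneConfig(duration_s=300.0, n_mismatch=6, n_opto=4,
                  photon_scale=2.0, soma_noise_sd=0.05, seed=3)
summary = run_pipeline(cfg, RunConfig(seed=3))

print("events detected:", summary["events"])
for kind, r in summary["responsiveness"].items():
    print(f"{kind}: {r['n_responsive']}/{r['n_tested']} ROIs responsive "
          f"(fraction {r['fraction_responsive']:.2f})")
curve = summary["population_curves"].get("grating_onset")
if curve:
    peak = max(np.abs(curve["mean"]))
    print(f"population grating response: peak |dF/F0| = {peak:.3f} "
          "(hierarchical-bootstrap mean across neurons)")
print("Even though the somata carry no stimulus-driven activity, "
      "vessel occlusion alone makes many ROIs 'responsive'.")
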