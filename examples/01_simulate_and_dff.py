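"""Generate a small synthetic experiment and extract ΔF/F traces.

The generator plants odor-tuned voxel ensembles in olfactory regions and
returns the full ground truth; ΔF/F uses the sliding-window baseline
(mean of the lowest 30% of the previous 200 frames).
"""

import numpy as np

from odoresp import preprocess as pre
from odoresp import synthgen as sg

cfg = sg.SynthConfig(grid_shape=(8, 8, 4), n_sessions=10, rest_duration=30.0,
                     noise_sd=0.1, seed=0)
exp = sg.generate_experiment(cfg)
print(f"channels: {list(exp.fluorescence)}; "
      f"trials: {cfg.n_trials}; frames: {exp.fluorescence['calcium'].shape[1]}")

dff = pre.dff_from_experiment(exp, "calcium")
trials = pre.extract_trials(dff, exp.trial_table, 0, 14)
gt = exp.ground_truth.ensemble_membership["calcium"]
tuned = int(np.flatnonzero(gt[:, 0])[0])
sel = np.asarray(trials.odor_labels) == cfg.odors[0]
peak = trials.values[sel, tuned].mean(axis=0).max()
print(f"voxel {tuned} (planted amplitude {gt[tuned, 0]:.2f} for {cfg.odors[0]}): "
      f"trial-averaged ΔF/F peak = {peak:.3f}")
# The recovered peak sits near the planted amplitude: the ΔF/F baseline
# tracks resting fluorescence, so planted kinetics survive extraction.
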