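"""Compute wrist/elbow/shoulder joint moments for one landing trial.

The trial is filtered (GRF at 50 Hz, angles at 6 Hz, zero-phase Butterworth),
trimmed to the landing phase (vertical GRF > 10 N through maximum elbow
flexion), and passed through the planar three-link Newton-Euler recursion:
ground force and carpal-link kinematics give the wrist moment, then the
recursion walks proximally to the elbow and shoulder.
"""

import numpy as np

from felanding import (GeneratorConfig, generate_cohort, preprocess_trial,
                       trial_joint_loads, moments_to_trajectories)

cohort = generate_cohort(GeneratorConfig(n_cats=1, trials_per_cat_per_height=1, seed=3))
trial = cohort[120][0]

trimmed, normalized = preprocess_trial(trial)
print(f"landing phase: {trimmed.n_samples} samples "
      f"({trimmed.n_samples / trimmed.sample_rate * 1000:.0f} ms) "
      f"out of {trial.n_samples} recorded")

loads = trial_joint_loads(trimmed)
for name, series in (("wrist", loads.wrist), ("elbow", loads.elbow),
                     ("shoulder", loads.shoulder)):
    print(f"  {name:>8} moment: peak {np.max(np.abs(series)):6.2f} N*m")
print("(moments grow distal to proximal: each joint supports everything below it)")

curves = moments_to_trajectories(loads)
print(f"\ntime-normalized to {len(curves['wrist_moment'])} phase points; "
      f"wrist moment at 0%/50%/100% phase: "
      f"{curves['wrist_moment'][0]:.2f} / {curves['wrist_moment'][49]:.2f} / "
      f"{curves['wrist_moment'][-1]:.2f} N*m")
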