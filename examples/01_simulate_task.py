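"""Simulate the serial match-to-template task and its behavior.

Builds one full session (8 blocks x 480 stimuli, 16 orientations), prints
the exact task statistics, and simulates von Mises-tuned button presses.
"""

import numpy as np

from popdecode import taskgen

trials = taskgen.generate_task_sequence(taskgen.TaskConfig(seed=0))
print(f"stimuli in one session:   {len(trials)}")
print(f"target fraction:          {trials['is_target'].mean():.4f} (= 1/16)")
print(f"orientations:             {trials['stimulus_deg'].nunique()} values, "
      f"max {trials['stimulus_deg'].max()} deg")
print(f"templates per session:    {trials.groupby('block')['template_deg'].first().tolist()}")

responses = taskgen.generate_behavior(trials, p_max=0.7, kappa=4.5, seed=1)
hit = trials["is_target"].to_numpy()[responses["true_stimulus_index"]]
print(f"\nresponses: {len(responses)} "
      f"({hit.sum()} to targets -> hit rate "
      f"{hit.sum() / trials['is_target'].sum():.2f})")
print("Each stimulus triggers a press with probability "
      "p_max * exp(kappa*(cos(2*tilt)-1)); at kappa=4.5 near-targets "
      "(11.25 deg) still draw ~50% false alarms, like a human observer.")
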