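"""Population tuning-curve decoding of stimulus, template and distance.

Simulates one subject with all three orientation codes and runs the
forward-model inversion under leave-one-block-out cross-validation for
each decoding scheme, printing the slope (orientation information) in
characteristic time windows.
"""

import numpy as np

from popdecode import encoder, taskgen

task = taskgen.TaskConfig(n_blocks_per_session=8, n_stimuli_per_block=48,
                          seed=0)
trials = taskgen.generate_task_sequence(task)
sim = taskgen.SimConfig(n_sensors=24, tmin_ms=-250, tmax_ms=600, dt_ms=12,
                        stim_gain=0.6, stim_window_ms=(50, 500),
                        template_gain=0.4, template_window_ms=(-100, 300),
                        distance_gain=0.5, distance_onset_ms=350, seed=1)
epochs = taskgen.generate_sensor_epochs(trials, sim)
t = epochs.times_ms

windows = {"stimulus": (100, 450), "template": (-50, 250),
           "distance": (380, 580)}
print("scheme     baseline slope   in-window slope")
for scheme, (lo, hi) in windows.items():
    res = encoder.decode_timecourse(epochs, scheme=scheme)
    base = res.slope[t < -150].mean()
    win = res.slope[(t > lo) & (t < hi)].mean()
    print(f"{scheme:<10} {base:+.5f}        {win:+.5f}")

print("\nA positive tuning-curve slope (channel response falling off with "
      "tilt from the decoded label) marks time windows carrying that "
      "code: stimulus after onset, template transiently around onset, "
      "angular distance late in the trial.")
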