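"""Task-axis projection and the sign of the decision variable.

Reduces simulated sensor data to principal components, fits the
six-regressor task GLM (sin/cos of stimulus, template, and angular
distance), symmetrically orthogonalizes the axes, and projects held-out
condition means.  A late sin(2*delta) sensor code produces a clockwise /
counterclockwise split on the task-irrelevant sign axis.
"""

import warnings

import numpy as np

from popdecode import statespace, taskgen

warnings.simplefilter("ignore")

task = taskgen.TaskConfig(n_blocks_per_session=8, n_stimuli_per_block=48,
                          seed=0)
trials = taskgen.generate_task_sequence(task)
sim = taskgen.SimConfig(n_sensors=24, tmin_ms=-250, tmax_ms=600, dt_ms=12,
                        stim_gain=0.4, distance_gain=0.6,
                        distance_onset_ms=350.0, seed=1)
epochs = taskgen.generate_sensor_epochs(trials, sim)
t = epochs.times_ms

proj = statespace.task_axis_projection(epochs, n_components=24)
div = statespace.sign_axis_divergence(proj.projections,
                                      proj.condition_values)
pre = np.nanmean(np.abs(div[:, t < 300]))
post = np.nanmean(np.abs(div[:, t > 400]))
print(f"sign-axis divergence (cw - ccw, pairs 11/22/34 deg): "
      f"before 300 ms {pre:.2f}, after 400 ms {post:.2f}")

mag = proj.projections[:, list(proj.axis_names).index("distance_magnitude"), :]
late = t > 400
target_row = int(np.flatnonzero(np.isclose(proj.condition_values, 0.0))[0])
far_row = int(np.flatnonzero(np.isclose(proj.condition_values, 90.0))[0])
print(f"magnitude axis, late window: target {np.nanmean(mag[target_row, late]):+.2f}, "
      f"orthogonal non-target {np.nanmean(mag[far_row, late]):+.2f}")

print("\nThe magnitude axis orders conditions by decision value; the sign "
      "axis separates +tilt from -tilt non-targets only after the injected "
      "350-ms onset.  A pure accumulator (magnitude-only) code would leave "
      "the sign axis silent.")
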