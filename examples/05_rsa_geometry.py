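"""Mahalanobis RSA: stable geometry under a rotating neural pattern.

Even when the sensor patterns encoding orientation rotate through sensor
space (dynamic coding), the *relative* dissimilarities between orientations
stay fixed.  The odd/even-split RDM correlation shows this stability, and
the RDM is well fit by a circular simplex; classical MDS recovers the
circular arrangement.
"""

import warnings

import numpy as np

from popdecode import encoder, rsa, taskgen

warnings.simplefilter("ignore")

task = taskgen.TaskConfig(n_blocks_per_session=8, n_stimuli_per_block=48,
                          seed=0)
trials = taskgen.generate_task_sequence(task)
sim = taskgen.SimConfig(n_sensors=24, tmin_ms=-250, tmax_ms=600, dt_ms=12,
                        stim_gain=0.8, stim_dynamics="rotating",
                        stim_rotation_period_ms=400.0, seed=1)
epochs = taskgen.generate_sensor_epochs(trials, sim)
t = epochs.times_ms

data = encoder.preprocess(epochs, "stimulus")
cm = rsa.condition_mean_split(data, epochs.trials["stimulus_deg"].to_numpy())
rdm0 = rsa.rdm_timecourse(cm.means[0], cm.covariance)
rdm1 = rsa.rdm_timecourse(cm.means[1], cm.covariance)

corr = rsa.rdm_crosstemporal_correlation(rdm0, rdm1)
win = (t > 100) & (t < 450)
block = corr[np.ix_(win, win)]
off = block[~np.eye(win.sum(), dtype=bool)]
print(f"odd/even RDM correlation, 100-450 ms: diagonal "
      f"{np.diag(block).mean():.2f}, off-diagonal {off.mean():.2f}")

model = rsa.circular_simplex(cm.condition_values)
coef = rsa.simplex_fit(rdm0 + rdm1, model)
print(f"circular-simplex fit peaks at {np.nanmax(coef):.3f} "
      f"(pre-stimulus mean {np.nanmean(coef[t < 0]):+.3f})")

mid = int(np.flatnonzero(win)[win.sum() // 2])
coords = rsa.mds_embed(rdm0[mid] + rdm1[mid])
radii = np.linalg.norm(coords, axis=1)
print(f"MDS at {t[mid]:.0f} ms: radius spread {radii.std() / radii.mean():.2f} "
      "(small = points lie on a circle, in orientation order)")
print("\nThe off-diagonal correlation stays close to the diagonal: the "
      "representational geometry is time-stable even though the underlying "
      "patterns rotate - the dissociation at the heart of the analysis.")
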