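"""Univariate per-sensor orientation sensitivity.

Each sensor/time-point signal is regressed on the sine and cosine of the
doubled task angle (plus a constant); the amplitude

    A = sqrt(beta_cos^2 + beta_sin^2)

is phase-invariant and measures how strongly that sensor modulates with the
angle.  Because A is positively biased, it is z-scored against a label-
permutation null; per-location topographies average the z scores over each
sensor triplet (two planar gradiometers + one magnetometer sharing a
location on 306-channel systems).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

from .circular import cos2, sin2


def _design(angles_deg: np.ndarray) -> np.ndarray:
    return np.column_stack([sin2(angles_deg), cos2(angles_deg),
                            np.ones(len(angles_deg))])


def sincos_amplitude(signal: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
    """Sine/cosine regression amplitude.

    ``signal`` is trials, or trials x features (sensors, sensor-time
    columns, ...); returns a scalar or one amplitude per feature.  A
    constant signal gives A = 0 (the constant regressor absorbs it).
    """
    sig = np.asarray(signal, dtype=float)
    scalar = sig.ndim == 1
    if scalar:
        sig = sig[:, None]
    if sig.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    X = _design(np.asarray(angles_deg, dtype=float))
    beta, *_ = np.linalg.lstsq(X, sig, rcond=None)
    A = np.hypot(beta[0], beta[1])
    return float(A[0]) if scalar else A


def permutation_z(
    signal: np.ndarray,
    angles_deg: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> np.ndarray:
    """Permutation z score of the sine/cosine amplitude.

    The angle labels are permuted ``n_perm`` times; the observed amplitude's
    rank yields p = (1 + #perm >= observed) / (n_perm + 1), transformed to z
    with the inverse standard-normal CDF.  p is floored at 1/(n_perm+1), so
    z saturates when the observed amplitude beats every permutation.
    """
    sig = np.asarray(signal, dtype=float)
    scalar = sig.ndim == 1
    if scalar:
        sig = sig[:, None]
    angles = np.asarray(angles_deg, dtype=float)
    rng = np.random.default_rng(seed)
    obs = sincos_amplitude(sig, angles)
    count = np.zeros(sig.shape[1])
    for _ in range(n_perm):
        perm = rng.permutation(len(angles))
        count += sincos_amplitude(sig, angles[perm]) >= obs
    p = (1.0 + count) / (n_perm + 1.0)
    z = sps.norm.isf(p)
    return float(z[0]) if scalar else z


def triplet_topography(z_per_sensor: np.ndarray,
                       sensor_locations: np.ndarray) -> tuple:
    """Average z scores over the sensor triplet at each location.

    Returns (location ids, mean z per location).  Locations without exactly
    three sensors are skipped with a warning.
    """
    z = np.asarray(z_per_sensor, dtype=float)
    loc = np.asarray(sensor_locations)
    if len(z) != len(loc):
        raise ValueError("one location per sensor required")
    ids, means = [], []
    for u in np.unique(loc):
        sel = loc == u
        if sel.sum() != 3:
            warnings.warn(f"location {u} has {sel.sum()} sensors; skipped")
            continue
        ids.append(u)
        means.append(z[sel].mean(axis=0))
    return np.asarray(ids), np.asarray(means)


def sensitivity_map(
    epochs_data: np.ndarray,
    angles_deg: np.ndarray,
    n_perm: int = 200,
    seed: int | None = 0,
) -> dict:
    """Amplitude and permutation z for every sensor and time point.

    ``epochs_data`` is trials x sensors x time.  Returns a dict with
    ``amplitude`` and ``z`` arrays of shape sensors x time.  All
    sensor-time columns share the same label permutations, as in a single
    permuted design applied to the whole data matrix.
    """
    n_tr, n_sens, n_t = epochs_data.shape
    flat = epochs_data.reshape(n_tr, -1)
    A = sincos_amplitude(flat, angles_deg).reshape(n_sens, n_t)
    rng = np.random.default_rng(seed)
    count = np.zeros(n_sens * n_t)
    for _ in range(n_perm):
        perm = rng.permutation(n_tr)
        count += sincos_amplitude(flat, np.asarray(angles_deg)[perm]) >= A.ravel()
    p = (1.0 + count) / (n_perm + 1.0)
    return {"amplitude": A, "z": sps.norm.isf(p).reshape(n_sens, n_t)}
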