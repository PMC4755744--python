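"""Population tuning-curve (forward encoding / inversion) model.

Sensor data are described as a linear mixture of orientation-selective
virtual channels.  A half-cosine basis raised to a power tiles orientation
space; a design matrix C1 expresses every training trial's orientation in
that basis; ordinary least squares gives the sensor weights

    W = B1 C1' (C1 C1')^-1

which are inverted on held-out data

    C2 = (W' W)^-1 W' B2

to recover virtual-channel responses.  Per-trial channel profiles are
circularly recentered on the presented orientation and averaged into a
population tuning curve whose linear slope (from -90 deg to 0) indexes
orientation information at each time point.

Three decoding schemes are supported under leave-one-block-out
cross-validation: ``stimulus`` (16-channel design, 20-ms sliding window,
baseline -150..-50 ms), ``template`` (8 equally spaced regressors over the
session's 8 template angles, 32-ms window, baseline -200..-150 ms, 32-ms
pre-smoothing, linear interpolation of the 8 estimated tuning values onto
the 16-point grid), and ``distance`` (the signed stimulus-template angular
distance treated as the circular label).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .circular import signed_diff, wrap_orientation
from .taskgen import SensorEpochs

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# basis and design


@dataclass(frozen=True)
class BasisSet:
    """Half-cosine basis raised to a power, tiling [0, 180) deg."""

    centers_deg: np.ndarray
    power: int

    @property
    def n_channels(self) -> int:
        return len(self.centers_deg)

    def evaluate(self, theta_deg) -> np.ndarray:
        """Basis responses, shape (n_channels,) + shape(theta)."""
        theta = np.asarray(theta_deg, dtype=float)
        d = signed_diff(theta[None, ...], self.centers_deg.reshape(
            (-1,) + (1,) * theta.ndim))
        return np.cos(np.deg2rad(d)) ** self.power


def build_basis(n_channels: int = 16, power: int = 15,
                centers_deg=None) -> BasisSet:
    """Build the channel basis.

    Each function peaks at 1 on its center and falls to 0 at 90 deg tilt
    (half-cosine support), is 180-deg periodic, and the default centers are
    the 16 task orientations 5.625 + k * 11.25 deg.
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    if centers_deg is None:
        spacing = 180.0 / n_channels
        centers_deg = spacing / 2.0 + spacing * np.arange(n_channels)
    return BasisSet(centers_deg=np.asarray(centers_deg, dtype=float), power=power)


def build_design(orientations, basis: BasisSet, add_constant: bool = True
                 ) -> np.ndarray:
    """Design matrix C1 of shape (n_channels (+1), n_trials)."""
    oris = np.asarray(orientations, dtype=float)
    if np.any(oris < 0) or np.any(oris >= 180):
        raise ValueError("orientations must lie in [0, 180)")
    C = basis.evaluate(oris)
    if add_constant:
        C = np.vstack([C, np.ones(C.shape[1])])
    return C


# ---------------------------------------------------------------------------
# weight estimation and inversion


def estimate_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Ordinary least squares weights W = B1 C1' (C1 C1')^-1.

    ``B1`` is sensors x trials, ``C1`` regressors x trials; returns
    sensors x regressors.  Rank-deficient designs fall back to the
    pseudo-inverse (logged).
    """
    G = C1 @ C1.T
    try:
        return np.linalg.solve(G, C1 @ B1.T).T
    except np.linalg.LinAlgError:
        logger.debug("design matrix rank-deficient; using pseudo-inverse")
        return B1 @ C1.T @ np.linalg.pinv(G)


def invert_channels(W: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Invert the encoder on test data: C2 = (W'W)^-1 W' B2.

    Returns regressors x trials.  A singular W'W falls back to the
    pseudo-inverse (logged).
    """
    G = W.T @ W
    try:
        return np.linalg.solve(G, W.T @ B2)
    except np.linalg.LinAlgError:
        logger.debug("W'W singular; using pseudo-inverse")
        return np.linalg.pinv(G) @ W.T @ B2


# ---------------------------------------------------------------------------
# tuning curves


@dataclass
class TuningCurve:
    """Trial-averaged virtual-channel profile on a zero-centered tilt axis."""

    offsets_deg: np.ndarray          # sorted, 0 = presented orientation
    values: np.ndarray               # (n_offsets,) or (n_offsets, n_times)

    def __post_init__(self):
        self.offsets_deg = np.asarray(self.offsets_deg, dtype=float)
        self.values = np.asarray(self.values, dtype=float)


def recenter_average(C2: np.ndarray, presented_deg, centers_deg) -> TuningCurve:
    """Circularly recenter per-trial channel profiles and average.

    ``C2`` is channels x trials; each trial's profile is rolled so the
    channel nearest the presented orientation lands on offset 0, and the
    average is returned on a sorted offset axis (spanning (-90, +90]).
    """
    centers = np.asarray(centers_deg, dtype=float)
    n = len(centers)
    if C2.shape[0] != n:
        raise ValueError("channel count does not match the orientation grid")
    presented = np.asarray(presented_deg, dtype=float)
    idx = np.argmin(np.abs(signed_diff(presented[:, None], centers[None, :])),
                    axis=1)
    # vectorized circular shift: row r of trial k reads channel (r + idx_k) % n
    rows = (np.arange(n)[:, None] + idx[None, :]) % n
    shifted = C2[rows, np.arange(C2.shape[1])[None, :], ...]
    spacing = 180.0 / n
    offsets = signed_diff(spacing * np.arange(n), 0.0)
    order = np.argsort(offsets)
    return TuningCurve(offsets_deg=offsets[order],
                       values=shifted.mean(axis=1)[order])


def interpolate_template_channels(values: np.ndarray, angles_deg: np.ndarray,
                                  target_angles_deg: np.ndarray) -> np.ndarray:
    """Circular linear interpolation of channel values onto new angles.

    Used to resample the 8 template-channel tuning values onto the 16-point
    orientation grid (inserting the 8 intermediate orientations).  Duplicate
    source angles are rejected.
    """
    ang = wrap_orientation(angles_deg)
    if len(np.unique(ang)) != len(ang):
        raise ValueError("duplicate angles")
    order = np.argsort(ang)
    ang, val = ang[order], np.asarray(values, dtype=float)[order]
    # extend periodically on both sides for wraparound segments
    ang_ext = np.concatenate([ang - 180.0, ang, ang + 180.0])
    val_ext = np.concatenate([val, val, val])
    return np.interp(wrap_orientation(target_angles_deg), ang_ext, val_ext)


def interpolation_matrix(angles_deg: np.ndarray,
                         target_angles_deg: np.ndarray) -> np.ndarray:
    """Linear map performing the circular interpolation of channel values.

    Returns M (n_target x n_source) with
    M @ values == interpolate_template_channels(values, angles, targets);
    interpolation is a fixed linear operation, so precomputing the matrix
    lets many profiles be resampled with one matrix product.
    """
    src = np.asarray(angles_deg, dtype=float)
    M = np.empty((len(np.atleast_1d(target_angles_deg)), len(src)))
    eye = np.eye(len(src))
    for k in range(len(src)):
        M[:, k] = interpolate_template_channels(eye[k], src, target_angles_deg)
    return M


def fold_sign(curve: TuningCurve) -> tuple[np.ndarray, np.ndarray]:
    """Average channels equidistant from 0 deg; returns (|tilt| grid, values)."""
    mags = np.unique(np.abs(curve.offsets_deg))
    vals = np.stack(
        [curve.values[np.abs(curve.offsets_deg) == m].mean(axis=0) for m in mags]
    )
    return mags, vals


def tuning_slope(curve: TuningCurve, dt_ms: float | None = None,
                 smooth_ms: float = 16.0) -> np.ndarray:
    """Linear slope of the tuning curve from -90 deg to 0.

    Sign-equidistant channels are averaged first; with a time axis present,
    each folded channel timecourse is smoothed with a Gaussian kernel
    (``smooth_ms`` = SD) before a least-squares line is fit across channels
    (abscissa -|tilt|, so positive slope = orientation information).
    Returns the slope per time point (scalar for a single profile), in
    channel units per degree.
    """
    mags, vals = fold_sign(curve)
    if vals.ndim == 2 and smooth_ms and dt_ms:
        vals = gaussian_filter1d(vals, sigma=smooth_ms / dt_ms, axis=1)
    x = -mags
    xc = x - x.mean()
    y = vals - vals.mean(axis=0, keepdims=True)
    slope = np.tensordot(xc, y, axes=(0, 0)) / (xc @ xc)
    return slope


# ---------------------------------------------------------------------------
# decoding schemes


@dataclass(frozen=True)
class SchemeConfig:
    """Windowing and preprocessing parameters of one decoding scheme."""

    label_column: str
    window_ms: float
    baseline_ms: tuple
    presmooth_ms: float
    n_channels: int


SCHEMES = {
    "stimulus": SchemeConfig("stimulus_deg", 20.0, (-150.0, -50.0), 0.0, 16),
    "template": SchemeConfig("template_deg", 32.0, (-200.0, -150.0), 32.0, 8),
    "distance": SchemeConfig("signed_distance_deg", 20.0, (-150.0, -50.0), 0.0, 16),
}


@dataclass
class SlopeTimecourse:
    """Tuning-curve slope per time point for one decoding scheme."""

    times_ms: np.ndarray
    slope: np.ndarray
    scheme: str
    tuning: TuningCurve | None = None
    n_folds: int = 0


def _scheme_labels(epochs: SensorEpochs, scheme: str) -> np.ndarray:
    cfg = SCHEMES[scheme]
    lab = epochs.trials[cfg.label_column].to_numpy(dtype=float)
    return wrap_orientation(lab)


def preprocess(epochs: SensorEpochs, scheme: str) -> np.ndarray:
    """Baseline-correct (and for the template scheme smooth) the data."""
    cfg = SCHEMES[scheme]
    data = epochs.data
    t = epochs.times_ms
    bl = (t >= cfg.baseline_ms[0]) & (t <= cfg.baseline_ms[1])
    if bl.any():
        data = data - data[:, :, bl].mean(axis=2, keepdims=True)
    if cfg.presmooth_ms:
        data = gaussian_filter1d(data, sigma=cfg.presmooth_ms / epochs.dt_ms,
                                 axis=2)
    return data


def window_average(data: np.ndarray, dt_ms: float, window_ms: float
                   ) -> np.ndarray:
    """Boxcar-average each timecourse over a centered sliding window."""
    size = max(int(round(window_ms / dt_ms)), 1)
    return uniform_filter1d(data, size=size, axis=2, mode="nearest")


def _template_design_info(labels: np.ndarray, n_channels: int):
    """Map irregular template angles to equally spaced pseudo-centers."""
    uniq = np.sort(np.unique(labels))
    if len(uniq) != n_channels:
        raise ValueError(
            f"expected {n_channels} distinct template angles, got {len(uniq)}")
    spacing = 180.0 / n_channels
    pseudo = spacing / 2.0 + spacing * np.arange(n_channels)
    mapping = {a: p for a, p in zip(uniq, pseudo)}
    return uniq, pseudo, mapping


def decode_timecourse(
    epochs: SensorEpochs,
    scheme: str = "stimulus",
    times_ms: np.ndarray | None = None,
    slope_smooth_ms: float = 16.0,
    add_constant: bool = True,
    basis_power: int = 15,
    labels: np.ndarray | None = None,
    recenter_labels: np.ndarray | None = None,
) -> SlopeTimecourse:
    """Within-time decoding under leave-one-block-out cross-validation.

    For each fold, encoder weights are estimated per time point on the
    training blocks (data boxcar-averaged over the scheme's sliding window)
    and inverted on the left-out block at the same time point; per-trial
    channel profiles are recentered on the scheme's label and averaged.
    ``labels``/``recenter_labels`` override the scheme's label column (used
    by the template-to-stimulus cross-generalization).
    """
    cfg = SCHEMES[scheme]
    if labels is None:
        labels = _scheme_labels(epochs, scheme)
    if recenter_labels is None:
        recenter_labels = labels
    data = preprocess(epochs, scheme)
    data = window_average(data, epochs.dt_ms, cfg.window_ms)
    t_all = epochs.times_ms
    if times_ms is None:
        times_ms = t_all
    t_idx = np.array([epochs.time_index(t) for t in times_ms])

    n_ch = cfg.n_channels
    if scheme == "template":
        # one equally spaced pseudo-channel per distinct template angle
        n_ch = len(np.unique(labels))
        uniq, pseudo, mapping = _template_design_info(labels, n_ch)
        design_labels = np.array([mapping[v] for v in labels])
        recenter_mapped = np.array([mapping[v] for v in recenter_labels]) \
            if set(np.unique(recenter_labels)) <= set(uniq) else None
    else:
        design_labels = labels
        pseudo = None

    basis = build_basis(n_ch, basis_power)
    blocks = _fold_ids(epochs)
    fold_curves = []
    for b in np.unique(blocks):
        train, test = blocks != b, blocks == b
        if len(np.unique(design_labels[train])) < 2:
            warnings.warn(f"fold {b} lacks label variation; skipped")
            continue
        try:
            C1 = build_design(design_labels[train], basis, add_constant)
        except ValueError:
            warnings.warn(f"fold {b} has invalid labels; skipped")
            continue
        curves = np.empty((n_ch, len(t_idx)))
        for j, ti in enumerate(t_idx):
            W = estimate_weights(data[train][:, :, ti].T, C1)
            C2 = invert_channels(W, data[test][:, :, ti].T)
            if add_constant:
                C2 = C2[:-1]
            if scheme == "template":
                if recenter_mapped is None:
                    raise ValueError("recenter labels must be template angles")
                tc = recenter_average(C2, recenter_mapped[test], basis.centers_deg)
            else:
                tc = recenter_average(C2, recenter_labels[test], basis.centers_deg)
            curves[:, j] = tc.values
        offsets = tc.offsets_deg
        if scheme == "template":
            # resample the estimated tuning values onto the doubled grid
            # (inserting the intermediate orientations)
            grid2 = build_basis(2 * n_ch).centers_deg
            target = np.sort(signed_diff(grid2 - grid2[0] + offsets[0], 0.0))
            curves = np.stack(
                [interpolate_template_channels(curves[:, j], offsets, target)
                 for j in range(curves.shape[1])], axis=1)
            offsets = target
        fold_curves.append(TuningCurve(offsets, curves))

    if not fold_curves:
        raise ValueError("no usable folds")
    mean_vals = np.mean([c.values for c in fold_curves], axis=0)
    mean_curve = TuningCurve(fold_curves[0].offsets_deg, mean_vals)
    slope = tuning_slope(mean_curve, dt_ms=_grid_step(times_ms),
                         smooth_ms=slope_smooth_ms)
    return SlopeTimecourse(times_ms=np.asarray(times_ms, dtype=float),
                           slope=slope, scheme=scheme, tuning=mean_curve,
                           n_folds=len(fold_curves))


def _fold_ids(epochs: SensorEpochs) -> np.ndarray:
    tr = epochs.trials
    return (tr["session"].to_numpy() * (tr["block"].max() + 1)
            + tr["block"].to_numpy())


def _grid_step(times_ms) -> float:
    times_ms = np.asarray(times_ms, dtype=float)
    return float(times_ms[1] - times_ms[0]) if len(times_ms) > 1 else 1.0
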