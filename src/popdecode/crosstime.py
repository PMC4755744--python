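"""Cross-temporal generalization, dynamic-coding statistics and latencies.

Training the encoder at one time point and testing at every other yields a
train-time x test-time matrix of tuning-curve slopes.  A code is *dynamic*
where within-time decoding beats cross-time generalization: for every
off-diagonal pair (i, j) the slope at (i, j) is tested (paired t across
subjects) against both within-time slopes (i, i) and (j, j), and the
conjunction is corrected by 2D cluster-extent permutation.

Onset latencies of two decoding timecourses are compared with a jack-knife:
leave-one-subject-out onsets give a variance estimate which is inflated by
(n - 1) to undo the jack-knife's variance reduction, and the full-sample
latency difference divided by that corrected SE is referred to t(n-1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from . import encoder
from .encoder import SCHEMES, TuningCurve
from .stats import (ClusterTestResult, cluster_permutation,
                    conjunction_cluster_permutation)
from .taskgen import SensorEpochs


@dataclass
class CrossTemporalMatrix:
    """Slopes over (train time x test time), averaged across folds."""

    train_times_ms: np.ndarray
    test_times_ms: np.ndarray
    slopes: np.ndarray
    scheme: str


def cross_temporal_matrix(
    epochs: SensorEpochs,
    scheme: str = "stimulus",
    step_ms: float = 12.0,
    labels: np.ndarray | None = None,
    recenter_labels: np.ndarray | None = None,
    train_scheme: str | None = None,
    smooth_result_ms: float = 0.0,
) -> CrossTemporalMatrix:
    """Train per time point, test on all time points (leave-one-block-out).

    The scheme's sliding window is applied on both the training and the test
    side; training times move on a ``step_ms`` grid; no extra smoothing is
    applied unless ``smooth_result_ms`` is set (used by the template-to-
    stimulus cross-generalization).  ``train_scheme`` lets the training side
    use different windowing/baselining than the test side.
    """
    train_scheme = train_scheme or scheme
    tcfg = SCHEMES[train_scheme]
    ecfg = SCHEMES[scheme if train_scheme == scheme else "stimulus"]
    if labels is None:
        labels = encoder._scheme_labels(epochs, train_scheme)
    if recenter_labels is None:
        recenter_labels = labels

    data_train = encoder.window_average(
        encoder.preprocess(epochs, train_scheme), epochs.dt_ms, tcfg.window_ms)
    if train_scheme == scheme:
        data_test = data_train
        test_cfg = tcfg
    else:
        test_cfg = ecfg
        data_test = encoder.window_average(
            encoder.preprocess(epochs, scheme if scheme in SCHEMES else "stimulus"),
            epochs.dt_ms, tcfg.window_ms)

    t_all = epochs.times_ms
    stride = max(int(round(step_ms / epochs.dt_ms)), 1)
    grid_idx = np.arange(0, len(t_all), stride)
    grid = t_all[grid_idx]

    n_ch = tcfg.n_channels
    if train_scheme == "template":
        n_ch = len(np.unique(labels))
        uniq, pseudo, mapping = encoder._template_design_info(labels, n_ch)
        design_labels = np.array([mapping[v] for v in labels])
    else:
        design_labels = labels
    basis = encoder.build_basis(n_ch)
    recenter_for_avg = recenter_labels
    if train_scheme == "template" and set(np.unique(recenter_labels)) <= set(uniq):
        recenter_for_avg = np.array([mapping[v] for v in recenter_labels])
        recenter_centers = basis.centers_deg
    elif train_scheme == "template":
        # recentering by a different (e.g. stimulus) 16-level label
        recenter_centers = None
    else:
        recenter_centers = basis.centers_deg

    blocks = encoder._fold_ids(epochs)
    n_grid = len(grid_idx)
    acc = None
    n_folds = 0
    for b in np.unique(blocks):
        train, test = blocks != b, blocks == b
        if len(np.unique(design_labels[train])) < 2:
            warnings.warn(f"fold {b} lacks label variation; skipped")
            continue
        C1 = encoder.build_design(design_labels[train], basis, add_constant=True)
        Btr = data_train[train]
        Bte = data_test[test]
        fold = np.empty((n_grid, n_grid))
        grid16 = encoder.build_basis(16).centers_deg
        interp16 = (encoder.interpolation_matrix(basis.centers_deg, grid16)
                    if recenter_centers is None else None)
        for i, ti in enumerate(grid_idx):
            W = encoder.estimate_weights(Btr[:, :, ti].T, C1)
            # invert on every test time at once
            C2 = encoder.invert_channels(W, Bte[:, :, grid_idx].transpose(1, 0, 2)
                                         .reshape(Bte.shape[1], -1))
            C2 = C2[:-1].reshape(n_ch, test.sum(), n_grid)
            if recenter_centers is not None:
                tc = encoder.recenter_average(C2, recenter_for_avg[test],
                                              recenter_centers)
            else:
                # 8-channel template profile -> 16-point grid, then recenter
                # by the 16-level stimulus label
                prof16 = np.einsum("ts,snj->tnj", interp16, C2)
                tc = encoder.recenter_average(prof16, recenter_labels[test],
                                              grid16)
            fold[i] = encoder.tuning_slope(tc, smooth_ms=0.0)
        acc = fold if acc is None else acc + fold
        n_folds += 1
    if n_folds == 0:
        raise ValueError("no usable folds")
    slopes = acc / n_folds
    if smooth_result_ms:
        slopes = gaussian_filter(slopes, sigma=smooth_result_ms / step_ms)
    return CrossTemporalMatrix(train_times_ms=grid, test_times_ms=grid,
                               slopes=slopes, scheme=scheme)


def _recenter_16(C2_8: np.ndarray, labels16: np.ndarray, basis8) -> TuningCurve:
    """Recenter an 8-channel profile by a 16-level label via interpolation."""
    grid16 = encoder.build_basis(16).centers_deg
    prof16 = encoder.interpolation_matrix(basis8.centers_deg, grid16) @ C2_8
    return encoder.recenter_average(prof16, labels16, grid16)


@dataclass
class DynamicCodingResult:
    """Masks and cluster p-values of the dynamic-coding conjunction test."""

    decoding: ClusterTestResult
    dynamic: ClusterTestResult

    @property
    def decoding_mask(self) -> np.ndarray:
        return self.decoding.significant_mask

    @property
    def dynamic_mask(self) -> np.ndarray:
        return self.dynamic.significant_mask


def dynamic_coding_test(
    matrices: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    seed: int | None = None,
) -> DynamicCodingResult:
    """Conjunction test for dynamic coding on per-subject slope matrices.

    ``matrices`` is subjects x T x T.  Significant decoding is assessed by a
    one-sided 2D cluster test of slope > 0.  For dynamic coding, each
    off-diagonal cell (i, j) must show slope(i,i) > slope(i,j) AND
    slope(j,j) > slope(i,j); both paired t maps are combined by elementwise
    minimum and cluster-corrected (diagonal cells are excluded by
    construction since their differences are zero).
    """
    M = np.asarray(matrices, dtype=float)
    if M.ndim != 3 or M.shape[1] != M.shape[2]:
        raise ValueError("matrices must be subjects x T x T")
    decoding = cluster_permutation(M, alpha_cluster=alpha_cluster,
                                   n_perm=n_perm, tail="greater", seed=seed)
    diag = np.einsum("sii->si", M)
    d_train = diag[:, :, None] - M   # slope(i,i) - slope(i,j)
    d_test = diag[:, None, :] - M    # slope(j,j) - slope(i,j)
    dynamic = conjunction_cluster_permutation(
        d_train, d_test, alpha_cluster=alpha_cluster, n_perm=n_perm, seed=seed)
    return DynamicCodingResult(decoding=decoding, dynamic=dynamic)


def cross_generalize_template_to_stimulus(
    epochs: SensorEpochs,
    step_ms: float = 12.0,
    smooth_result_ms: float = 20.0,
) -> CrossTemporalMatrix:
    """Train on template orientations, recenter test trials by stimulus.

    The training side is treated exactly as in template decoding (baseline
    -200..-150 ms, 32-ms smoothing and window); the test side as in
    stimulus decoding (baseline -150..-50 ms, no smoothing); the resulting
    slope matrix is smoothed with a 20-ms Gaussian kernel.  A positive
    slope at (i, j) means the template-discriminative pattern at train time
    i carries stimulus information at test time j.
    """
    labels = encoder._scheme_labels(epochs, "template")
    stim = encoder._scheme_labels(epochs, "stimulus")
    return cross_temporal_matrix(
        epochs, scheme="stimulus", step_ms=step_ms, labels=labels,
        recenter_labels=stim, train_scheme="template",
        smooth_result_ms=smooth_result_ms)


def prestimulus_template_tuning(
    epochs: SensorEpochs,
    train_window_ms: tuple = (-150.0, 0.0),
    test_window_ms: tuple = (50.0, 150.0),
) -> TuningCurve:
    """Train template weights on the pre-stimulus window only.

    Weights are estimated from the time-averaged pre-stimulus data (with
    template-scheme preprocessing) and applied to the time-averaged early
    post-stimulus test data, recentered on the *stimulus* orientation.  A
    peak at 0 deg indicates that the pre-activated template pattern carries
    stimulus information.
    """
    labels = encoder._scheme_labels(epochs, "template")
    stim = encoder._scheme_labels(epochs, "stimulus")
    data = encoder.preprocess(epochs, "template")
    t = epochs.times_ms
    tr_mask = (t >= train_window_ms[0]) & (t <= train_window_ms[1])
    te_mask = (t >= test_window_ms[0]) & (t <= test_window_ms[1])

    n_ch = len(np.unique(labels))
    uniq, pseudo, mapping = encoder._template_design_info(labels, n_ch)
    design_labels = np.array([mapping[v] for v in labels])
    basis = encoder.build_basis(n_ch)
    blocks = encoder._fold_ids(epochs)
    curves = []
    for b in np.unique(blocks):
        train, test = blocks != b, blocks == b
        C1 = encoder.build_design(design_labels[train], basis, add_constant=True)
        B1 = data[train][:, :, tr_mask].mean(axis=2).T
        B2 = data[test][:, :, te_mask].mean(axis=2).T
        W = encoder.estimate_weights(B1, C1)
        C2 = encoder.invert_channels(W, B2)[:-1]
        curves.append(_recenter_16(C2, stim[test], basis))
    values = np.mean([c.values for c in curves], axis=0)
    return TuningCurve(curves[0].offsets_deg, values)


@dataclass
class JackknifeLatencyResult:
    """Jack-knife comparison of two decoding onset latencies."""

    latency_a_ms: float
    latency_b_ms: float
    difference_ms: float
    se_ms: float
    t: float
    df: int
    p: float


def _default_onset(maps: np.ndarray, times: np.ndarray, n_perm: int,
                   seed: int | None, rule: str = "cluster") -> float:
    """Onset = first significant time point.

    ``rule='cluster'`` uses the cluster-corrected significant window (the
    default); ``rule='threshold'`` uses the uncorrected supra-threshold t
    map, which remains usable at very small subject counts where a
    sign-flip permutation cannot reach p < 0.05.
    """
    if rule == "cluster":
        res = cluster_permutation(maps, n_perm=n_perm, tail="greater",
                                  seed=seed)
        mask = res.significant_mask
    else:
        from .stats import cluster_threshold, group_t
        t = group_t(maps)
        mask = np.nan_to_num(t) > cluster_threshold(maps.shape[0])
    if not mask.any():
        return np.nan
    return float(times[np.flatnonzero(mask)[0]])


def jackknife_latency_compare(
    maps_a: np.ndarray,
    maps_b: np.ndarray,
    times_ms: np.ndarray,
    n_perm: int = 500,
    seed: int | None = 0,
    onset_rule: str = "cluster",
) -> JackknifeLatencyResult:
    """Compare onset latencies of two per-subject decoding timecourses.

    The onset is the first time point of the cluster-corrected significant
    window (p < 0.05, one-sided).  Leave-one-subject-out onsets provide the
    jack-knife variance, inflated by (n - 1) to correct for the reduced
    variability of leave-one-out estimates; t = full-sample difference /
    corrected SE on t(n-1).
    """
    a = np.asarray(maps_a, dtype=float)
    b = np.asarray(maps_b, dtype=float)
    times = np.asarray(times_ms, dtype=float)
    n = a.shape[0]
    lat_a = _default_onset(a, times, n_perm, seed, onset_rule)
    lat_b = _default_onset(b, times, n_perm, seed, onset_rule)
    if np.isnan(lat_a) or np.isnan(lat_b):
        raise ValueError("no significant onset in the full sample")
    diffs = np.empty(n)
    for i in range(n):
        keep = np.arange(n) != i
        la = _default_onset(a[keep], times, n_perm, seed, onset_rule)
        lb = _default_onset(b[keep], times, n_perm, seed, onset_rule)
        if np.isnan(la) or np.isnan(lb):
            raise ValueError(
                f"no significant onset when leaving out subject {i}")
        diffs[i] = la - lb
    # jack-knife SE with the (n-1) variance inflation
    se = np.sqrt((n - 1) / n * np.sum((diffs - diffs.mean()) ** 2))
    full_diff = lat_a - lat_b
    if se == 0:
        t = 0.0 if full_diff == 0 else np.inf * np.sign(full_diff)
    else:
        t = full_diff / se
    from scipy import stats as sps
    p = float(2 * sps.t.sf(abs(t), df=n - 1)) if np.isfinite(t) else 0.0
    return JackknifeLatencyResult(latency_a_ms=lat_a, latency_b_ms=lat_b,
                                  difference_ms=full_diff, se_ms=float(se),
                                  t=float(t), df=n - 1, p=p)
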