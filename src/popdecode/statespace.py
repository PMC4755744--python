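"""Targeted dimensionality reduction onto task axes.

Sensor data are smoothed, reduced to 30 principal components (loadings
computed from the trial-averaged sensor timecourses), and regressed per
time point on six task regressors: sine and cosine of the doubled stimulus,
template, and stimulus-template angular-distance angles.  For the distance
pair the cosine is the task-relevant *magnitude* axis (1 at targets, -1 at
orthogonal non-targets, equal for +/- tilts) and the sine is the
task-irrelevant *sign* axis (0 at 0 and +/-90 deg, antisymmetric in the
tilt direction).  The 30 x 6 coefficient matrix is symmetrically
orthogonalized (polar factor of its SVD) per time point, and held-out
condition means are projected onto the resulting orthonormal axes, averaged
over leave-one-block-out folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .circular import cos2, sin2
from .encoder import _fold_ids
from .stats import ClusterTestResult, cluster_permutation
from .taskgen import SensorEpochs

AXIS_NAMES = ("stimulus_sin", "stimulus_cos", "template_sin", "template_cos",
              "distance_magnitude", "distance_sign")


def reduce_dimensionality(
    epochs: SensorEpochs,
    n_components: int = 30,
    smooth_ms: float = 20.0,
) -> dict:
    """PCA scores and loadings for the sensor data.

    Loadings are computed from the trial-averaged sensor x time matrix
    (time samples as observations); single trials are then projected onto
    those loadings.  Data are pre-smoothed with a Gaussian kernel.  If there
    are fewer sensors than requested components the count is reduced with a
    warning.
    """
    data = epochs.data
    if smooth_ms:
        data = gaussian_filter1d(data, sigma=smooth_ms / epochs.dt_ms, axis=2)
    n_sens = data.shape[1]
    cap = min(n_sens, data.shape[2])   # PCA rank limit of the averaged matrix
    if cap < n_components:
        warnings.warn(
            f"only {n_sens} sensors / {data.shape[2]} samples; "
            f"reducing components from {n_components} to {cap}")
        n_components = cap
    avg = data.mean(axis=0)                   # sensors x time
    pca = PCA(n_components=n_components)
    pca.fit(avg.T)                            # observations = time samples
    loadings = pca.components_.T              # sensors x components
    centered = data - pca.mean_[None, :, None]
    scores = np.einsum("tsk,sc->tck", centered, loadings)
    return {"scores": scores, "loadings": loadings,
            "explained_variance": pca.explained_variance_,
            "smoothed_data": data}


def build_task_regressors(trials: pd.DataFrame) -> tuple:
    """Six per-trial regressors: sin/cos of the doubled task angles.

    Returns (matrix trials x 6, axis names).  The distance-cosine column is
    the decision-value magnitude axis (cos(2*Delta): 0.92 at +/-11.25 deg),
    the distance-sine the task-irrelevant sign axis (sin(2*Delta): +0.38 at
    +11.25 deg, -0.38 at -11.25 deg, 0 at 0 and +/-90 deg).
    """
    stim = trials["stimulus_deg"].to_numpy(dtype=float)
    templ = trials["template_deg"].to_numpy(dtype=float)
    delta = trials["signed_distance_deg"].to_numpy(dtype=float)
    X = np.column_stack([sin2(stim), cos2(stim), sin2(templ), cos2(templ),
                         cos2(delta), sin2(delta)])
    names = ("stimulus_sin", "stimulus_cos", "template_sin", "template_cos",
             "distance_magnitude", "distance_sign")
    return X, names


def symmetric_orthogonalize(B: np.ndarray) -> np.ndarray:
    """Closest matrix with orthonormal columns (polar factor U V')."""
    U, s, Vt = np.linalg.svd(B, full_matrices=False)
    if np.any(s < 1e-12 * s.max() if s.size else True):
        raise np.linalg.LinAlgError("rank-deficient coefficient matrix")
    return U @ Vt


@dataclass
class TaskAxes:
    """Orthonormalized axes (time x components x regressors)."""

    axes: np.ndarray
    valid: np.ndarray
    axis_names: tuple = AXIS_NAMES


def fit_and_orthogonalize(scores: np.ndarray, regressors: np.ndarray,
                          norm_stats: tuple | None = None) -> TaskAxes:
    """Per-time GLM betas, symmetrically orthogonalized.

    ``scores`` is trials x components x time (training set), ``regressors``
    trials x 6.  Data are normalized per component and time point (mean and
    variance from ``norm_stats`` when given, else from these data).  Time
    points with a rank-deficient beta matrix are flagged invalid (NaN axes).
    """
    n_tr, n_comp, n_t = scores.shape
    if norm_stats is None:
        norm_stats = normalization_stats(scores)
    mu, sd = norm_stats
    Z = (scores - mu[None]) / sd[None]
    axes = np.full((n_t, n_comp, regressors.shape[1]), np.nan)
    valid = np.zeros(n_t, dtype=bool)
    XtX = regressors.T @ regressors
    for t in range(n_t):
        beta = np.linalg.solve(XtX, regressors.T @ Z[:, :, t]).T  # comp x 6
        try:
            axes[t] = symmetric_orthogonalize(beta)
            valid[t] = True
        except np.linalg.LinAlgError:
            pass
    return TaskAxes(axes=axes, valid=valid)


def normalization_stats(scores: np.ndarray) -> tuple:
    """Per-component, per-time mean and SD across trials (SD floored)."""
    mu = scores.mean(axis=0)
    sd = scores.std(axis=0)
    sd = np.where(sd < 1e-12, 1.0, sd)
    return mu, sd


def project_condition_means(test_means: np.ndarray, axes: TaskAxes) -> np.ndarray:
    """Project condition means onto the task axes, per time point.

    ``test_means`` is conditions x components x time (already normalized
    with the training statistics); returns conditions x 6 x time, NaN where
    the axes were invalid.
    """
    out = np.einsum("nct,tcr->nrt", test_means, axes.axes)
    out[:, :, ~axes.valid] = np.nan
    return out


@dataclass
class ProjectionResult:
    """Fold-averaged projections of the 16 angular-distance conditions."""

    projections: np.ndarray      # conditions x 6 x time
    condition_values: np.ndarray
    times_ms: np.ndarray
    axis_names: tuple = AXIS_NAMES
    n_folds: int = 0


def task_axis_projection(
    epochs: SensorEpochs,
    n_components: int = 30,
    smooth_ms: float = 20.0,
) -> ProjectionResult:
    """Full targeted-dimensionality-reduction pipeline, cross-validated.

    PCA loadings are computed once from the trial-averaged data; for each
    leave-one-block-out fold the GLM is fit on normalized training scores,
    the betas orthogonalized, and the left-out block's condition means
    (one per signed angular distance, normalized with training statistics)
    projected onto the axes.  Projections are averaged over folds.
    """
    red = reduce_dimensionality(epochs, n_components, smooth_ms)
    scores = red["scores"]
    X, _ = build_task_regressors(epochs.trials)
    delta = epochs.trials["signed_distance_deg"].to_numpy(dtype=float)
    conds = np.unique(delta)
    blocks = _fold_ids(epochs)
    acc = None
    n_folds = 0
    for b in np.unique(blocks):
        train, test = blocks != b, blocks == b
        stats = normalization_stats(scores[train])
        axes = fit_and_orthogonalize(scores[train], X[train], norm_stats=stats)
        mu, sd = stats
        Ztest = (scores[test] - mu[None]) / sd[None]
        dtest = delta[test]
        means = np.stack([Ztest[dtest == c].mean(axis=0) for c in conds])
        proj = project_condition_means(means, axes)
        acc = proj if acc is None else acc + proj
        n_folds += 1
    return ProjectionResult(projections=acc / n_folds, condition_values=conds,
                            times_ms=epochs.times_ms, n_folds=n_folds)


PAIR_TILTS = (11.25, 22.5, 33.75)


def sign_axis_divergence(
    projections: np.ndarray,
    condition_values: np.ndarray,
    pair_tilts=PAIR_TILTS,
    axis_index: int = 5,
) -> np.ndarray:
    """Clockwise-minus-counterclockwise difference on the sign axis.

    ``projections`` is (subjects x) conditions x 6 x time; for each tilt in
    ``pair_tilts`` the sign-axis projection of the -tilt condition is
    subtracted from that of the +tilt condition.  Returns
    (subjects x) pairs x time.
    """
    single = projections.ndim == 3
    P = projections[None] if single else projections
    cond = np.asarray(condition_values, dtype=float)
    rows = []
    for tilt in pair_tilts:
        ip = int(np.flatnonzero(np.isclose(cond, tilt))[0])
        im = int(np.flatnonzero(np.isclose(cond, -tilt))[0])
        rows.append(P[:, ip, axis_index, :] - P[:, im, axis_index, :])
    out = np.stack(rows, axis=1)
    return out[0] if single else out


def sign_axis_divergence_test(
    divergence: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> ClusterTestResult:
    """Group cluster test of the pair-averaged sign-axis divergence.

    ``divergence`` is subjects x pairs x time; the pair average is tested
    against zero (two-sided cluster-forming threshold) with cluster-extent
    permutation over time.
    """
    mean_div = divergence.mean(axis=1)
    return cluster_permutation(mean_div, n_perm=n_perm, tail="two-sided",
                               seed=seed)
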