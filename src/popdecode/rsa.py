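"""Representational similarity analysis with Mahalanobis distances.

Condition-wise evoked responses (split into odd/even trial halves) are
compared by their pairwise Mahalanobis distances, using the within-condition
sensor covariance pooled over all conditions and shrunk toward its diagonal
for invertibility.  The resulting representational dissimilarity matrices
(RDMs) support: cross-temporal RDM correlations (is the representational
geometry stable even when the patterns are not?), correlation between
template-sorted and stimulus-sorted RDMs, regression on an idealized
16-point circular simplex, classical MDS visualization, and a multiple
regression of the angular-distance RDM with decision-value and
response-frequency nuisance models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.ndimage import gaussian_filter1d

from .circular import circ_dist


# ---------------------------------------------------------------------------
# condition means and pooled covariance


@dataclass
class ConditionMeans:
    """Per-split condition-mean responses and pooled within-condition covariance."""

    means: np.ndarray        # splits x conditions x sensors x time
    covariance: np.ndarray   # time x sensors x sensors (shrunk)
    condition_values: np.ndarray
    shrinkage: float


def _shrink_to_diagonal(S: np.ndarray, residuals: np.ndarray) -> tuple:
    """Shrink a covariance toward its diagonal with an analytic intensity.

    The intensity follows the Schafer-Strimmer estimator for the diagonal
    target: lambda* = sum_{i!=j} Var(s_ij) / sum_{i!=j} s_ij^2, clipped to
    [0, 1], where Var(s_ij) is the sampling variance of each off-diagonal
    covariance entry across residual trials.
    """
    n = residuals.shape[0]
    if n < 2:
        return np.diag(np.diag(S)), 1.0
    w = residuals[:, :, None] * residuals[:, None, :]
    var_s = w.var(axis=0, ddof=1) * n / (n - 1) ** 2
    off = ~np.eye(S.shape[0], dtype=bool)
    denom = np.sum(S[off] ** 2)
    lam = 1.0 if denom == 0 else float(np.clip(np.sum(var_s[off]) / denom, 0, 1))
    return (1 - lam) * S + lam * np.diag(np.diag(S)), lam


def condition_mean_split(
    epochs_data: np.ndarray,
    condition_labels: np.ndarray,
    shrinkage: float | str = "auto",
) -> ConditionMeans:
    """Odd/even split condition means plus pooled, shrunk covariance.

    ``epochs_data`` is trials x sensors x time.  Trials are split by parity
    of their order within each condition; the within-condition covariance is
    pooled over all conditions and splits, per time point, and shrunk
    toward its diagonal (``shrinkage='auto'`` for the analytic intensity, or
    a float in [0, 1]).
    """
    labels = np.asarray(condition_labels)
    conds = np.unique(labels)
    n_tr, n_sens, n_t = epochs_data.shape
    means = np.full((2, len(conds), n_sens, n_t), np.nan)
    resid = []
    for ci, c in enumerate(conds):
        idx = np.flatnonzero(labels == c)
        for split in range(2):
            sel = idx[split::2]
            if len(sel) < 2:
                raise ValueError(
                    f"condition {c!r} has fewer than 2 trials in split {split}")
            means[split, ci] = epochs_data[sel].mean(axis=0)
            resid.append(epochs_data[sel] - means[split, ci])
    resid = np.concatenate(resid, axis=0)   # trials x sensors x time

    cov = np.empty((n_t, n_sens, n_sens))
    lam_used = 0.0
    for t in range(n_t):
        r = resid[:, :, t]
        S = r.T @ r / max(len(r) - 1, 1)
        if shrinkage == "auto":
            cov[t], lam = _shrink_to_diagonal(S, r)
        else:
            lam = float(shrinkage)
            cov[t] = (1 - lam) * S + lam * np.diag(np.diag(S))
        lam_used += lam
    return ConditionMeans(means=means, covariance=cov,
                          condition_values=conds, shrinkage=lam_used / n_t)


# ---------------------------------------------------------------------------
# RDMs


def _check_rdm(rdm: np.ndarray) -> None:
    if not np.allclose(rdm, rdm.T):
        raise ValueError("RDM must be symmetric")
    if not np.allclose(np.diag(rdm), 0):
        raise ValueError("RDM must have a zero diagonal")
    if np.any(rdm < -1e-10):
        raise ValueError("RDM must be nonnegative")


def mahalanobis_rdm(means: np.ndarray, covariance: np.ndarray) -> np.ndarray:
    """Pairwise Mahalanobis distances between condition means.

    ``means`` is conditions x sensors; distances are
    sqrt((m_a - m_b)' Sigma^-1 (m_a - m_b)).  With the identity covariance
    this reduces exactly to the Euclidean distance.
    """
    try:
        L = cholesky(covariance, lower=True)
    except np.linalg.LinAlgError as err:
        raise ValueError("covariance not positive-definite despite shrinkage") \
            from err
    white = solve_triangular(L, means.T, lower=True).T
    diff = white[:, None, :] - white[None, :, :]
    rdm = np.sqrt(np.einsum("abk,abk->ab", diff, diff))
    np.fill_diagonal(rdm, 0.0)
    return rdm


def rdm_timecourse(means_t: np.ndarray, covariance_t: np.ndarray) -> np.ndarray:
    """Mahalanobis RDM per time point (conditions x sensors x time input)."""
    n_t = means_t.shape[-1]
    return np.stack([mahalanobis_rdm(means_t[:, :, t], covariance_t[t])
                     for t in range(n_t)])


def lower_triangle(rdm: np.ndarray) -> np.ndarray:
    """Vectorize the strictly lower triangle (diagonal excluded)."""
    i, j = np.tril_indices(rdm.shape[-1], k=-1)
    return rdm[..., i, j]


def rdm_crosstemporal_correlation(rdms_a: np.ndarray,
                                  rdms_b: np.ndarray) -> np.ndarray:
    """Pearson correlation of RDM lower triangles over all time pairs.

    ``rdms_a``/``rdms_b`` are time x conditions x conditions (e.g. the two
    trial splits); entry (i, j) correlates split-A geometry at time i with
    split-B geometry at time j.  Zero-variance RDMs give NaN.
    """
    va = lower_triangle(rdms_a)
    vb = lower_triangle(rdms_b)
    va = va - va.mean(axis=1, keepdims=True)
    vb = vb - vb.mean(axis=1, keepdims=True)
    na = np.linalg.norm(va, axis=1)
    nb = np.linalg.norm(vb, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (va @ vb.T) / np.outer(na, nb)
    return corr


def fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


# ---------------------------------------------------------------------------
# model RDMs and fits


def circular_simplex(angles_deg: np.ndarray) -> np.ndarray:
    """Idealized RDM of pairwise circular orientation distances (period 180)."""
    a = np.asarray(angles_deg, dtype=float)
    return circ_dist(a[:, None], a[None, :])


def unsigned_value_distance(signed_deg: np.ndarray) -> np.ndarray:
    """Nuisance model: distance between *unsigned* angular distances.

    d(a, b) = | |a| - |b| |, so d(0, -22.5) = 22.5 but d(-22.5, +22.5) = 0.
    """
    m = np.abs(np.asarray(signed_deg, dtype=float))
    return np.abs(m[:, None] - m[None, :])


def response_frequency_distance(freq: np.ndarray) -> np.ndarray:
    """Nuisance model: absolute difference in response frequency."""
    f = np.asarray(freq, dtype=float)
    return np.abs(f[:, None] - f[None, :])


def simplex_fit(rdms: np.ndarray, model_rdm: np.ndarray) -> np.ndarray:
    """Per-time regression coefficient of the data RDM on one model RDM.

    A linear fit with intercept on the vectorized lower triangles; returns
    one coefficient per time point (scalar for a single RDM).
    """
    single = rdms.ndim == 2
    if single:
        rdms = rdms[None]
    y = lower_triangle(rdms)
    x = lower_triangle(model_rdm)
    X = np.column_stack([x, np.ones_like(x)])
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    return float(beta[0, 0]) if single else beta[0]


def distance_rdm_regression(
    rdms: np.ndarray,
    signed_distances_deg: np.ndarray,
    response_freq: np.ndarray | None = None,
) -> dict:
    """Multiple regression of the angular-distance RDM on model components.

    Regressors: the circular simplex over the signed distances, the
    unsigned-decision-value nuisance, optionally the response-frequency
    nuisance, plus an intercept.  Returns per-time coefficients keyed by
    regressor name; warns on ill-conditioned model matrices.
    """
    single = rdms.ndim == 2
    if single:
        rdms = rdms[None]
    models = {
        "simplex": circular_simplex(signed_distances_deg),
        "unsigned_value": unsigned_value_distance(signed_distances_deg),
    }
    if response_freq is not None:
        models["response_frequency"] = response_frequency_distance(response_freq)
    X = np.column_stack([lower_triangle(m) for m in models.values()]
                        + [np.ones(lower_triangle(rdms[0]).shape[0])])
    cond = np.linalg.cond(X)
    if cond > 1e8:
        import warnings
        warnings.warn(f"model RDMs nearly collinear (condition number {cond:.2g})")
    y = lower_triangle(rdms)
    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    out = {name: (float(beta[k, 0]) if single else beta[k])
           for k, name in enumerate(models)}
    out["condition_number"] = cond
    return out


# ---------------------------------------------------------------------------
# MDS and template-stimulus comparison


def mds_embed(rdm: np.ndarray, n_dims: int = 2) -> np.ndarray:
    """Classical (double-centering) MDS embedding.

    Deterministic up to rotation/reflection: B = -0.5 J D^2 J is
    eigendecomposed and the top ``n_dims`` dimensions returned (zero for
    non-positive eigenvalues).
    """
    _check_rdm(rdm)
    n = rdm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (rdm ** 2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1][:n_dims]
    coords = vecs[:, order] * np.sqrt(np.clip(vals[order], 0, None))
    return coords


def template_stimulus_rdm_correlation(
    template_rdms: np.ndarray,
    stimulus_rdms: np.ndarray,
    template_angles_deg: np.ndarray,
    stimulus_angles_deg: np.ndarray,
    diag_smooth_ms: float = 20.0,
    dt_ms: float | None = None,
) -> dict:
    """Correlate template-sorted with stimulus-sorted RDMs over time pairs.

    Both RDM stacks must be built over the same eight angles (the session's
    template set); entry (i, j) of the map correlates the template geometry
    at time i with the stimulus geometry at time j.  The within-time
    diagonal is additionally smoothed with a Gaussian kernel.
    """
    ta = np.sort(np.asarray(template_angles_deg, dtype=float))
    sa = np.sort(np.asarray(stimulus_angles_deg, dtype=float))
    if not np.array_equal(ta, sa):
        raise ValueError("template and stimulus angle sets must match")
    corr = rdm_crosstemporal_correlation(template_rdms, stimulus_rdms)
    diag = np.diag(corr).copy()
    if diag_smooth_ms and dt_ms:
        diag = gaussian_filter1d(diag, sigma=diag_smooth_ms / dt_ms)
    return {"map": corr, "diagonal": diag}
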