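"""Group-level inference: one-sample t maps and cluster-based permutation.

Family-wise error over time (1D) or time-by-time (2D) maps is controlled by
cluster-based permutation testing: a one-sample t statistic is computed per
point, contiguous supra-threshold points are grouped into clusters scored by
their extent, and the null distribution of the maximum cluster extent is
built by randomly sign-flipping the subject maps.  A conjunction variant
(elementwise minimum of two paired t maps, sign-flipped jointly) supports
the dynamic-coding test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats as sps


@dataclass
class ClusterTestResult:
    """Clusters, their extents and permutation p-values for one map."""

    t_map: np.ndarray
    threshold: float
    cluster_labels: np.ndarray
    cluster_extents: np.ndarray
    p_values: np.ndarray
    n_perm: int
    seed: int | None = None
    alpha: float = 0.05

    @property
    def significant_mask(self) -> np.ndarray:
        mask = np.zeros_like(self.cluster_labels, dtype=bool)
        for k, p in enumerate(self.p_values, start=1):
            if p <= self.alpha:
                mask |= self.cluster_labels == k
        return mask

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_extents)


def group_t(maps: np.ndarray, popmean: float = 0.0) -> np.ndarray:
    """One-sample t against ``popmean`` per point; zero-variance points -> NaN.

    ``maps`` is subjects x (map shape).  Paired designs pass the difference
    maps.
    """
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 2:
        raise ValueError("need at least 2 subjects")
    n = maps.shape[0]
    mean = maps.mean(axis=0) - popmean
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    return t


def _t_from_signs(maps_flat: np.ndarray, signs: np.ndarray) -> np.ndarray:
    """t maps for many sign-flip permutations at once.

    Sign flips leave the per-point sum of squares unchanged, so only the
    permuted means need recomputation: t = m / sqrt((ss - n m^2)/(n-1)/n).
    """
    n = maps_flat.shape[0]
    ss = np.einsum("sp,sp->p", maps_flat, maps_flat)
    means = signs @ maps_flat / n
    var = (ss[None, :] - n * means**2) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return means / np.sqrt(var / n)


def _label_clusters(supra: np.ndarray, connectivity: int) -> tuple:
    if supra.ndim == 2 and connectivity == 8:
        structure = np.ones((3, 3), dtype=bool)
    else:
        structure = None  # scipy default: 1D adjacency / 4-connectivity
    labels, n = ndimage.label(supra, structure=structure)
    if n == 0:
        return labels, np.array([], dtype=int)
    extents = ndimage.sum_labels(np.ones_like(labels), labels,
                                 index=np.arange(1, n + 1)).astype(int)
    return labels, extents


def _max_extent(t_maps: np.ndarray, threshold: float, tail: str,
                connectivity: int) -> np.ndarray:
    out = np.zeros(t_maps.shape[0], dtype=int)
    for i, tm in enumerate(t_maps):
        supra = _supra(tm, threshold, tail)
        _, ext = _label_clusters(supra, connectivity)
        out[i] = ext.max() if len(ext) else 0
    return out


def _supra(t_map: np.ndarray, threshold: float, tail: str) -> np.ndarray:
    t_map = np.nan_to_num(t_map)
    if tail == "greater":
        return t_map > threshold
    if tail == "less":
        return t_map < -threshold
    return np.abs(t_map) > threshold


def cluster_threshold(n_subjects: int, alpha: float = 0.05,
                      tail: str = "greater") -> float:
    """Cluster-forming t threshold from the alpha quantile of t(n-1)."""
    q = alpha if tail in ("greater", "less") else alpha / 2.0
    return float(sps.t.isf(q, df=n_subjects - 1))


def cluster_permutation(
    subject_maps: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    tail: str = "greater",
    connectivity: int = 8,
    seed: int | None = None,
    t_maps_override: tuple | None = None,
) -> ClusterTestResult:
    """Cluster-extent permutation test on subject maps (1D or 2D).

    ``subject_maps`` is subjects x map; the null is built from ``n_perm``
    random sign-flips of the subject maps.  Cluster p-values are rank-based,
    (1 + #null >= observed) / (n_perm + 1), so the smallest attainable p is
    1/(n_perm+1).  ``t_maps_override`` is used internally by the conjunction
    test.
    """
    maps = np.asarray(subject_maps, dtype=float)
    n = maps.shape[0]
    shape = maps.shape[1:]
    thr = cluster_threshold(n, alpha_cluster, tail)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))

    flat = maps.reshape(n, -1)
    if t_maps_override is None:
        t_obs = group_t(maps)
        t_null = _t_from_signs(flat, signs).reshape(n_perm, *shape)
    else:
        t_obs, t_null = t_maps_override

    supra = _supra(t_obs, thr, tail)
    labels, extents = _label_clusters(supra, connectivity)
    null_max = _max_extent(t_null, thr, tail, connectivity)
    p = np.array([(1 + np.sum(null_max >= e)) / (n_perm + 1) for e in extents])
    return ClusterTestResult(t_map=t_obs, threshold=thr, cluster_labels=labels,
                             cluster_extents=extents, p_values=p,
                             n_perm=n_perm, seed=seed)


def conjunction_cluster_permutation(
    diff_a: np.ndarray,
    diff_b: np.ndarray,
    alpha_cluster: float = 0.05,
    n_perm: int = 1000,
    connectivity: int = 8,
    seed: int | None = None,
) -> ClusterTestResult:
    """Cluster test on the conjunction (elementwise min) of two paired t maps.

    A point is supra-threshold only if *both* paired comparisons exceed the
    one-sided cluster-forming threshold; the same per-subject sign flip is
    applied to both difference maps, preserving their coupling under the
    null.
    """
    a = np.asarray(diff_a, dtype=float)
    b = np.asarray(diff_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("difference maps must share a shape")
    n = a.shape[0]
    shape = a.shape[1:]
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    t_obs = np.fmin(group_t(a), group_t(b))
    t_null = np.minimum(
        _t_from_signs(a.reshape(n, -1), signs),
        _t_from_signs(b.reshape(n, -1), signs),
    ).reshape(n_perm, *shape)
    return cluster_permutation(
        a, alpha_cluster=alpha_cluster, n_perm=n_perm, tail="greater",
        connectivity=connectivity, seed=seed,
        t_maps_override=(t_obs, t_null))
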