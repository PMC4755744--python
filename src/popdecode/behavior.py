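"""Behavioral analysis: response assignment and von Mises tilt tuning.

In a rapid serial stream every button press has several candidate causes.
Responses are therefore attributed probabilistically: RT-resolved response
tuning (probability of responding as a function of the stimulus tilt from
the template) is estimated first, and each response is then assigned to the
candidate stimulus that maximizes the modeled probability of a response at
the observed RT given the candidate's tilt.

Tilt tuning is summarized by a von Mises curve centered on the target:

    p(tilt) = P_MAX * exp(kappa * cos(2*tilt)) / exp(kappa)

with a signed concentration: kappa = 0 means no tuning, kappa > 0 tuning
toward the target, kappa < 0 toward the orthogonal orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .circular import cos2


@dataclass
class TiltTuningFit:
    """Fitted von Mises response-tuning parameters."""

    p_max: float
    kappa: float
    n_obs: int = 0

    def predict(self, tilt_deg) -> np.ndarray:
        return von_mises_tuning(tilt_deg, self.p_max, self.kappa)


def von_mises_tuning(tilt_deg, p_max, kappa):
    """Von Mises response probability, peak-normalized at tilt 0."""
    return p_max * np.exp(kappa * (cos2(tilt_deg) - 1.0))


def fit_response_tuning(
    tilt_deg: np.ndarray,
    frequency: np.ndarray,
    weights: np.ndarray | None = None,
) -> TiltTuningFit:
    """Least-squares fit of the von Mises tuning curve to binned frequencies.

    The curve is constrained to be centered at tilt 0 (the target); only the
    peak ``p_max`` and the signed concentration ``kappa`` are free.
    """
    tilt = np.asarray(tilt_deg, dtype=float)
    freq = np.asarray(frequency, dtype=float)
    if len(tilt) != len(freq):
        raise ValueError("tilt and frequency must have equal length")
    if np.all(freq == 0):
        warnings.warn("all response frequencies are zero; kappa undefined, returning 0")
        return TiltTuningFit(p_max=0.0, kappa=0.0, n_obs=len(freq))
    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        sigma = 1.0 / np.sqrt(np.maximum(w, 1e-12))
    try:
        popt, _ = curve_fit(
            von_mises_tuning,
            tilt,
            freq,
            p0=(min(max(freq.max(), 1e-3), 1.0), 1.0),
            bounds=([0.0, -50.0], [1.0, 50.0]),
            sigma=sigma,
            maxfev=10000,
        )
    except RuntimeError:
        warnings.warn("tuning fit did not converge; returning kappa = 0")
        return TiltTuningFit(p_max=float(freq.max()), kappa=0.0, n_obs=len(freq))
    return TiltTuningFit(p_max=float(popt[0]), kappa=float(popt[1]), n_obs=len(freq))


@dataclass
class RTResolvedTuning:
    """Per-RT-bin von Mises tuning fits over the response window."""

    rt_edges_ms: np.ndarray
    fits: list = field(default_factory=list)
    rt_density: np.ndarray | None = None

    @property
    def window_ms(self) -> tuple:
        return float(self.rt_edges_ms[0]), float(self.rt_edges_ms[-1])

    def probability(self, rt_ms: float, tilt_deg: float) -> float:
        """Modeled probability of a response at this RT for this tilt."""
        lo, hi = self.window_ms
        if not lo <= rt_ms <= hi:
            return 0.0
        k = min(
            int(np.searchsorted(self.rt_edges_ms, rt_ms, side="right") - 1),
            len(self.fits) - 1,
        )
        dens = 1.0 if self.rt_density is None else float(self.rt_density[k])
        return dens * float(self.fits[k].predict(tilt_deg))


def estimate_rt_tuning(
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    window_ms: tuple = (200.0, 1000.0),
    rt_bin_ms: float = 100.0,
) -> RTResolvedTuning:
    """Estimate RT-resolved response tuning from unassigned responses.

    Every (response, candidate stimulus) pair inside the RT window
    contributes its (RT, tilt) combination; per RT bin, response counts are
    normalized by the number of presented stimuli of each tilt and fitted
    with the von Mises tuning curve.
    """
    edges = np.arange(window_ms[0], window_ms[1] + 0.5 * rt_bin_ms, rt_bin_ms)
    tilts = np.sort(np.unique(np.abs(trials["signed_distance_deg"].to_numpy())))
    counts = np.zeros((len(edges) - 1, len(tilts)))
    tilt_index = {t: i for i, t in enumerate(tilts)}

    trial_tilt = np.abs(trials["signed_distance_deg"].to_numpy())
    n_per_tilt = np.array([(trial_tilt == t).sum() for t in tilts], dtype=float)

    for _, resp in responses.iterrows():
        cands = _candidate_indices(resp, trials, window_ms)
        for idx in cands:
            rt = resp["response_time_ms"] - trials["onset_ms"].iloc[idx]
            b = min(int(np.searchsorted(edges, rt, side="right") - 1), len(edges) - 2)
            counts[b, tilt_index[trial_tilt[idx]]] += 1.0

    fits = []
    for b in range(len(edges) - 1):
        rate = counts[b] / np.maximum(n_per_tilt, 1.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits.append(fit_response_tuning(tilts, np.clip(rate, 0, 1)))
    total = counts.sum()
    density = counts.sum(axis=1) / total if total > 0 else np.ones(len(edges) - 1)
    return RTResolvedTuning(rt_edges_ms=edges, fits=fits, rt_density=density)


def _candidate_indices(resp, trials: pd.DataFrame, window_ms: tuple) -> np.ndarray:
    same = (trials["session"] == resp["session"]) & (trials["block"] == resp["block"])
    rt = resp["response_time_ms"] - trials["onset_ms"]
    ok = same & (rt >= window_ms[0]) & (rt <= window_ms[1])
    return np.flatnonzero(ok.to_numpy())


def assign_responses(
    responses: pd.DataFrame,
    trials: pd.DataFrame,
    tuning: RTResolvedTuning | None = None,
    window_ms: tuple = (200.0, 1000.0),
) -> pd.DataFrame:
    """Attribute each response to a single candidate stimulus.

    Candidates are stimuli in the same block whose onset precedes the
    response by an RT inside ``window_ms``.  Among candidates the stimulus
    maximizing the modeled response probability at that RT wins; ties go to
    the later (closer) stimulus.  Responses with no candidate are flagged
    ``assigned = False`` rather than dropped.
    """
    if tuning is None:
        tuning = estimate_rt_tuning(responses, trials, window_ms=window_ms)
    onsets = trials["onset_ms"].to_numpy()
    tilt = np.abs(trials["signed_distance_deg"].to_numpy())

    out = responses.copy()
    assigned_idx = np.full(len(responses), -1, dtype=int)
    assigned_rt = np.full(len(responses), np.nan)
    for i, (_, resp) in enumerate(responses.iterrows()):
        cands = _candidate_indices(resp, trials, window_ms)
        if len(cands) == 0:
            continue
        scores = np.array(
            [
                tuning.probability(resp["response_time_ms"] - onsets[c], tilt[c])
                for c in cands
            ]
        )
        # ties broken in favor of the later (most recent) stimulus
        best = cands[np.flatnonzero(scores == scores.max())[-1]]
        assigned_idx[i] = best
        assigned_rt[i] = resp["response_time_ms"] - onsets[best]
    out["assigned_stimulus_index"] = assigned_idx
    out["assigned_rt_ms"] = assigned_rt
    out["assigned"] = assigned_idx >= 0
    return out


def response_frequency_curve(
    assigned: pd.DataFrame, trials: pd.DataFrame
) -> pd.DataFrame:
    """Per-tilt response rate with binomial standard errors.

    Rate = number of responses assigned to stimuli of a given tilt divided
    by the number of presented stimuli of that tilt.
    """
    tilts = np.sort(np.unique(np.abs(trials["signed_distance_deg"].to_numpy())))
    trial_tilt = np.abs(trials["signed_distance_deg"].to_numpy())
    n = np.array([(trial_tilt == t).sum() for t in tilts], dtype=float)
    k = np.zeros(len(tilts))
    if len(assigned):
        ok = assigned[assigned.get("assigned", True) == True]  # noqa: E712
        for idx in ok["assigned_stimulus_index"].to_numpy():
            k[np.searchsorted(tilts, trial_tilt[int(idx)])] += 1.0
    rate = np.divide(k, n, out=np.zeros_like(k), where=n > 0)
    se = np.sqrt(np.clip(rate * (1 - rate), 0, None) / np.maximum(n, 1.0))
    return pd.DataFrame(
        {"tilt_deg": tilts, "n_stimuli": n.astype(int), "n_responses": k.astype(int),
         "rate": rate, "se": se}
    )
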