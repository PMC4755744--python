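"""Synthetic serial match-to-template task: sequences, sensor epochs, behavior.

The generator emulates a target-detection experiment in which an observer
holds one *template* orientation per block and watches a rapid stream of
oriented gratings, responding whenever the stimulus matches the template.
Stimuli are drawn in shuffled full cycles of 16 equally spaced orientations,
so exactly 1/16 of stimuli are targets.

Sensor epochs are built as correlated Gaussian noise plus up to three
orientation codes:

* a stimulus code: sensor patterns for cos(2*theta), sin(2*theta) of the
  stimulus orientation, active in a post-onset window, optionally rotating
  through sensor space over time (dynamic coding);
* a template code: patterns for the block's template orientation, active
  transiently around stimulus onset (optionally sharing the stimulus
  patterns, which makes the two codes cross-generalize);
* an angular-distance code: patterns for cos(2*delta) (decision magnitude)
  and sin(2*delta) (task-irrelevant sign), active from a late onset.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .circular import cos2, signed_diff, sin2

DEFAULT_ORIENTATIONS = tuple(5.625 + 11.25 * k for k in range(16))

TRIAL_COLUMNS = [
    "session",
    "block",
    "index_in_block",
    "onset_ms",
    "stimulus_deg",
    "template_deg",
    "is_target",
    "signed_distance_deg",
]


@dataclass(frozen=True)
class TaskConfig:
    """Parameters of the serial match-to-template task."""

    n_sessions: int = 1
    n_blocks_per_session: int = 8
    n_stimuli_per_block: int = 480
    orientation_set: tuple = DEFAULT_ORIENTATIONS
    stim_duration_ms: float = 100.0
    isi_range_ms: tuple = (516.0, 783.0)
    segments_per_block: int = 3
    templates_unique_across_sessions: bool = False
    seed: int = 0

    def __post_init__(self):
        oris = np.asarray(self.orientation_set, dtype=float)
        if len(np.unique(oris)) != len(oris):
            raise ValueError("orientation_set must contain distinct values")
        if np.any(oris < 0) or np.any(oris >= 180):
            raise ValueError("orientations must lie in [0, 180)")
        if self.n_stimuli_per_block % len(oris) != 0:
            raise ValueError(
                "n_stimuli_per_block must be a multiple of the orientation-set "
                "size (stimuli are drawn in shuffled full cycles)"
            )
        if self.isi_range_ms[0] > self.isi_range_ms[1]:
            raise ValueError("isi_range_ms must be (low, high)")


def generate_task_sequence(config: TaskConfig) -> pd.DataFrame:
    """Generate the full trial table for one experiment.

    Stimuli are drawn in successive shuffled cycles of the 16 orientations
    (each consecutive run of 16 covers the full set exactly once), which
    yields an exact 1/16 target rate.  Each session receives
    ``n_blocks_per_session`` templates drawn without replacement from the
    orientation set.  Onsets accumulate stimulus duration plus uniform ISI
    draws, per block.
    """
    rng = np.random.default_rng(config.seed)
    oris = np.asarray(config.orientation_set, dtype=float)
    n_ori = len(oris)
    n_cycles = config.n_stimuli_per_block // n_ori

    used_templates: set = set()
    rows = []
    for session in range(config.n_sessions):
        if config.templates_unique_across_sessions:
            pool = np.array([o for o in oris if o not in used_templates])
        else:
            pool = oris
        if len(pool) < config.n_blocks_per_session:
            raise ValueError("not enough unused template orientations left")
        templates = rng.permutation(pool)[: config.n_blocks_per_session]
        used_templates.update(templates.tolist())

        for block, template in enumerate(templates):
            stims = np.concatenate(
                [rng.permutation(oris) for _ in range(n_cycles)]
            )
            isis = rng.uniform(*config.isi_range_ms, size=config.n_stimuli_per_block)
            onsets = np.concatenate(
                [[0.0], np.cumsum(config.stim_duration_ms + isis[:-1])]
            )
            delta = signed_diff(stims, template)
            rows.append(
                pd.DataFrame(
                    {
                        "session": session,
                        "block": block,
                        "index_in_block": np.arange(config.n_stimuli_per_block),
                        "onset_ms": onsets,
                        "stimulus_deg": stims,
                        "template_deg": template,
                        "is_target": delta == 0.0,
                        "signed_distance_deg": delta,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)[TRIAL_COLUMNS]


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic sensor-epoch generator.

    Gains are in noise-SD units per unit regressor; windows in ms relative to
    stimulus onset.  ``stim_dynamics='rotating'`` makes the stimulus-code
    sensor patterns rotate through a second orthogonal pattern pair with the
    given period, producing dynamic (time-specific) coding while the
    representational geometry stays fixed.
    """

    n_sensors: int = 32
    tmin_ms: float = -1000.0
    tmax_ms: float = 1000.0
    dt_ms: float = 4.0
    noise_scale: float = 1.0
    noise_corr_length: float = 5.0
    stim_gain: float = 1.0
    stim_window_ms: tuple = (50.0, 500.0)
    stim_dynamics: Literal["static", "rotating"] = "static"
    stim_rotation_period_ms: float = 400.0
    template_gain: float = 0.0
    template_window_ms: tuple = (-100.0, 300.0)
    template_pattern: Literal["independent", "shared"] = "independent"
    distance_gain: float = 0.0
    distance_onset_ms: float = 350.0
    distance_components: tuple = ("magnitude", "sign")
    seed: int = 0

    def __post_init__(self):
        for g in (self.stim_gain, self.template_gain, self.distance_gain):
            if g < 0:
                raise ValueError("gains must be >= 0")
        # windows are only constrained for codes that are switched on
        for gain, w in ((self.stim_gain, self.stim_window_ms),
                        (self.template_gain, self.template_window_ms)):
            if w[0] >= w[1]:
                raise ValueError("windows must be (start, stop) with start < stop")
            if gain > 0 and (w[0] < self.tmin_ms or w[1] > self.tmax_ms):
                raise ValueError("signal window lies outside the epoch")
        if self.distance_gain > 0 and not (
                self.tmin_ms <= self.distance_onset_ms <= self.tmax_ms):
            raise ValueError("distance onset lies outside the epoch")
        unknown = set(self.distance_components) - {"magnitude", "sign"}
        if unknown:
            raise ValueError(f"unknown distance components: {unknown}")


@dataclass
class SensorEpochs:
    """Trials x sensors x time array with its time axis and trial table.

    ``times_ms`` is strictly increasing with uniform step; ``data`` has one
    row per row of ``trials``.  ``sensor_locations`` groups sensors into
    triplet locations (as on a 306-channel system with two gradiometers and
    one magnetometer per location) when the sensor count is divisible by 3.
    """

    data: np.ndarray
    times_ms: np.ndarray
    trials: pd.DataFrame
    sensor_labels: list = field(default_factory=list)
    sensor_locations: np.ndarray | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x sensors x time")
        if self.data.shape[0] != len(self.trials):
            raise ValueError("first axis must match the trial table length")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("last axis must match the time axis")
        steps = np.diff(self.times_ms)
        if len(steps) and (np.any(steps <= 0) or not np.allclose(steps, steps[0])):
            raise ValueError("time axis must be strictly increasing and uniform")
        if not self.sensor_labels:
            self.sensor_labels = [f"S{i:03d}" for i in range(self.data.shape[1])]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def dt_ms(self) -> float:
        return float(self.times_ms[1] - self.times_ms[0])

    def time_index(self, t_ms: float) -> int:
        return int(np.argmin(np.abs(self.times_ms - t_ms)))

    def copy_with(self, data: np.ndarray) -> "SensorEpochs":
        return SensorEpochs(
            data=data,
            times_ms=self.times_ms,
            trials=self.trials,
            sensor_labels=list(self.sensor_labels),
            sensor_locations=self.sensor_locations,
            ground_truth=dict(self.ground_truth),
        )


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _orthonormal_pair(rng, n):
    a = _unit(rng.standard_normal(n))
    b = rng.standard_normal(n)
    b = _unit(b - a * (a @ b))
    return a, b


def generate_sensor_epochs(trials: pd.DataFrame, sim: SimConfig) -> SensorEpochs:
    """Simulate sensor epochs for every stimulus in ``trials``."""
    if len(trials) == 0:
        raise ValueError("trial table is empty")
    rng = np.random.default_rng(sim.seed)
    n_trials = len(trials)
    times = np.arange(sim.tmin_ms, sim.tmax_ms + 0.5 * sim.dt_ms, sim.dt_ms)
    n_t = len(times)
    ns = sim.n_sensors

    # spatially correlated Gaussian noise, white in time
    idx = np.arange(ns)
    cov = np.exp(-np.abs(idx[:, None] - idx[None, :]) / sim.noise_corr_length)
    chol = np.linalg.cholesky(cov)
    noise = rng.standard_normal((n_trials, ns, n_t))
    data = sim.noise_scale * np.einsum("ij,tjk->tik", chol, noise)

    gt = {}
    stim = trials["stimulus_deg"].to_numpy()
    templ = trials["template_deg"].to_numpy()
    delta = trials["signed_distance_deg"].to_numpy()

    # stimulus code
    p_cos, p_sin = _orthonormal_pair(rng, ns)
    p2_cos, p2_sin = _orthonormal_pair(rng, ns)
    gt["stim_pattern"] = np.stack([p_cos, p_sin])
    if sim.stim_gain > 0:
        in_win = (times >= sim.stim_window_ms[0]) & (times <= sim.stim_window_ms[1])
        c, s = cos2(stim), sin2(stim)
        if sim.stim_dynamics == "static":
            pat = np.outer(p_cos, in_win.astype(float)), np.outer(
                p_sin, in_win.astype(float)
            )
        else:
            phase = (
                2.0
                * np.pi
                * (times - sim.stim_window_ms[0])
                / sim.stim_rotation_period_ms
            )
            mix_a = np.where(in_win, np.cos(phase), 0.0)
            mix_b = np.where(in_win, np.sin(phase), 0.0)
            pat = (
                np.outer(p_cos, mix_a) + np.outer(p2_cos, mix_b),
                np.outer(p_sin, mix_a) + np.outer(p2_sin, mix_b),
            )
        data += sim.stim_gain * (
            c[:, None, None] * pat[0][None] + s[:, None, None] * pat[1][None]
        )

    # template code
    if sim.template_pattern == "shared":
        q_cos, q_sin = p_cos, p_sin
    else:
        q_cos, q_sin = _orthonormal_pair(rng, ns)
    gt["template_pattern"] = np.stack([q_cos, q_sin])
    if sim.template_gain > 0:
        in_win = (
            (times >= sim.template_window_ms[0])
            & (times <= sim.template_window_ms[1])
        ).astype(float)
        c, s = cos2(templ), sin2(templ)
        data += sim.template_gain * (
            c[:, None, None] * np.outer(q_cos, in_win)[None]
            + s[:, None, None] * np.outer(q_sin, in_win)[None]
        )

    # angular-distance code (magnitude = cos(2*delta), sign = sin(2*delta))
    d_cos, d_sin = _orthonormal_pair(rng, ns)
    gt["distance_pattern"] = np.stack([d_cos, d_sin])
    if sim.distance_gain > 0:
        env = (times >= sim.distance_onset_ms).astype(float)
        if "magnitude" in sim.distance_components:
            data += sim.distance_gain * cos2(delta)[:, None, None] * np.outer(
                d_cos, env
            )[None]
        if "sign" in sim.distance_components:
            data += sim.distance_gain * sin2(delta)[:, None, None] * np.outer(
                d_sin, env
            )[None]

    locations = None
    if ns % 3 == 0:
        locations = np.repeat(np.arange(ns // 3), 3)
    return SensorEpochs(
        data=data,
        times_ms=times,
        trials=trials.reset_index(drop=True),
        sensor_locations=locations,
        ground_truth=gt,
    )


@dataclass(frozen=True)
class RTDistribution:
    """Gamma-shaped RT distribution truncated to a response window.

    Defaults put the window at 200-1000 ms post-onset with the mode near
    550 ms (shape-4 gamma shifted by the window start).
    """

    min_ms: float = 200.0
    max_ms: float = 1000.0
    shape: float = 4.0
    scale_ms: float = 116.7

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        filled = 0
        while filled < size:
            draw = self.min_ms + rng.gamma(self.shape, self.scale_ms, size=size)
            ok = draw[draw <= self.max_ms]
            take = min(len(ok), size - filled)
            out[filled : filled + take] = ok[:take]
            filled += take
        return out


RESPONSE_COLUMNS = [
    "session",
    "block",
    "response_time_ms",
    "true_stimulus_index",
    "true_rt_ms",
]


def generate_behavior(
    trials: pd.DataFrame,
    p_max: float = 0.7,
    kappa: float = 4.5,
    rt_dist: RTDistribution | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate button presses with von Mises tilt tuning.

    Each stimulus elicits a response with probability
    ``p_max * exp(kappa * (cos(2*tilt) - 1))`` (peak ``p_max`` at tilt 0);
    response times are drawn from ``rt_dist`` relative to the causal
    stimulus onset.  The causal stimulus index is recorded as ground truth.
    """
    if not 0.0 <= p_max <= 1.0:
        raise ValueError("p_max must lie in [0, 1]")
    rt_dist = rt_dist or RTDistribution()
    rng = np.random.default_rng(seed)
    tilt = np.abs(trials["signed_distance_deg"].to_numpy())
    p = p_max * np.exp(kappa * (cos2(tilt) - 1.0))
    responded = rng.random(len(trials)) < p
    idx = np.flatnonzero(responded)
    rts = rt_dist.sample(rng, len(idx))
    resp = pd.DataFrame(
        {
            "session": trials["session"].to_numpy()[idx],
            "block": trials["block"].to_numpy()[idx],
            "response_time_ms": trials["onset_ms"].to_numpy()[idx] + rts,
            "true_stimulus_index": idx,
            "true_rt_ms": rts,
        }
    )
    return resp.sort_values("response_time_ms", kind="stable").reset_index(drop=True)[
        RESPONSE_COLUMNS
    ]


def write_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_to_dict(cfg) -> dict:
    return dataclasses.asdict(cfg)
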