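"""Three-layer probabilistic population-code model of template matching.

A stimulus layer (von Mises tuning, kappa = 5), a template layer (broader
tuning, kappa = 2, mnemonic precision is lower) and a decision layer whose
units are tuned to *relative* orientation: the template-tuned unit connects
most strongly to the 0-degree decision unit, so decision activity is
invariant to rotating stimulus and template together.  A trial initializes
the stimulus and template layers, updates the template layer as the
element-wise product of the two (a Bayesian-style multiplication of
evidence and prior), and maps the result through all-to-all von Mises
connection weights (kappa = 5) into decision space.  The read-out can use
the decision population's peak location or its peak height.

The single-node accumulator comparator replaces the decision population by
one matched-filter unit (inner product of the stimulus response with the
template tuning profile): it carries the magnitude but not the sign of the
stimulus-template angular distance, which is the model contrast behind the
sign-separability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import signed_diff


@dataclass(frozen=True)
class LayerConfig:
    """One layer: unit count, preferred-orientation grid, concentration."""

    n_units: int = 100
    kappa: float = 5.0

    def __post_init__(self):
        if self.n_units < 2:
            raise ValueError("n_units must be >= 2")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")

    @property
    def preferred_deg(self) -> np.ndarray:
        return 180.0 * np.arange(self.n_units) / self.n_units


def von_mises_response(theta_deg, centers_deg, kappa) -> np.ndarray:
    """Peak-normalized von Mises activation in 180-deg orientation space.

    R_i(theta) = exp(kappa * cos(2*(theta - theta_i)*pi/180)) / exp(kappa),
    so the response is 1 at the preferred orientation, exp(-kappa) at 45 deg
    tilt and exp(-2*kappa) at the orthogonal orientation.
    """
    d = np.deg2rad(2.0 * (np.asarray(theta_deg, dtype=float)
                          - np.asarray(centers_deg, dtype=float)))
    return np.exp(kappa * (np.cos(d) - 1.0))


def normalize_activation(r: np.ndarray) -> np.ndarray:
    """Scale a nonzero activation vector to peak 1 (range [0, 1])."""
    peak = r.max()
    return r / peak if peak > 0 else r


@dataclass
class DecisionReadout:
    """Peak location (decision-space degrees, (-90, 90]) and peak height."""

    peak_location_deg: float
    peak_height: float


@dataclass
class PopulationModel:
    """The three-layer template-matching circuit."""

    stimulus: LayerConfig = field(default_factory=lambda: LayerConfig(100, 5.0))
    template: LayerConfig = field(default_factory=lambda: LayerConfig(100, 2.0))
    decision: LayerConfig = field(default_factory=lambda: LayerConfig(100, 5.0))

    def decision_preferred_deg(self) -> np.ndarray:
        """Decision-unit preferred relative orientations in (-90, 90]."""
        return signed_diff(self.decision.preferred_deg, 0.0)

    def run_trial(self, stimulus_deg: float, template_deg: float) -> dict:
        """Simulate one trial; returns all layer responses and the read-out.

        The element-wise product is propagated *unnormalized* so that the
        decision-layer peak height decreases with the stimulus-template
        distance (peak-1 normalized copies are provided under ``*_norm``
        for display).
        """
        s_pref = self.stimulus.preferred_deg
        t_pref = self.template.preferred_deg
        r_s = von_mises_response(stimulus_deg, s_pref, self.stimulus.kappa)
        r_t0 = von_mises_response(template_deg, t_pref, self.template.kappa)
        r_t = r_s * r_t0 if self.stimulus.n_units == self.template.n_units \
            else None
        if r_t is None:
            raise ValueError("stimulus and template layers must have equal "
                             "unit counts for the one-to-one mapping")
        # all-to-all template->decision weights: the unit preferring the
        # template orientation drives the 0-deg decision unit
        d_pref = self.decision_preferred_deg()
        rel = signed_diff(t_pref, template_deg)
        W = von_mises_response(d_pref[:, None], rel[None, :],
                               self.decision.kappa)
        r_d = W @ r_t
        r_d = r_d / W.sum(axis=1).max()   # fixed normalization of the mapping
        peak = int(np.argmax(r_d))
        readout = DecisionReadout(peak_location_deg=float(d_pref[peak]),
                                  peak_height=float(r_d[peak]))
        return {
            "stimulus_layer": r_s,
            "template_layer_initial": r_t0,
            "template_layer": r_t,
            "decision_layer": r_d,
            "stimulus_layer_norm": normalize_activation(r_s),
            "template_layer_norm": normalize_activation(r_t),
            "decision_layer_norm": normalize_activation(r_d),
            "readout": readout,
        }

    def accumulator_trial(self, stimulus_deg: float,
                          template_deg: float) -> float:
        """Single-node matched-filter decision value.

        The scalar inner product of the stimulus-layer response with the
        template tuning profile; symmetric in the sign of the angular
        distance by construction.
        """
        s_pref = self.stimulus.preferred_deg
        r_s = von_mises_response(stimulus_deg, s_pref, self.stimulus.kappa)
        filt = von_mises_response(template_deg, s_pref, self.template.kappa)
        return float(r_s @ filt) / self.stimulus.n_units


DELTA_GRID_16 = tuple(signed_diff(11.25 * np.arange(16), 0.0)[
    np.argsort(signed_diff(11.25 * np.arange(16), 0.0))])


def model_rdms(model: PopulationModel,
               delta_grid=DELTA_GRID_16,
               template_deg: float = 90.0,
               accumulator: bool = False) -> dict:
    """Layer-wise Euclidean RDMs over a grid of angular distances.

    Stimuli are presented at ``template + delta`` for each delta on the
    grid against a fixed template.  Returns one conditions x conditions RDM
    per layer; with ``accumulator=True`` the decision layer is replaced by
    the single matched-filter node (whose RDM cannot separate +delta from
    -delta).
    """
    deltas = np.asarray(delta_grid, dtype=float)
    layers = {"stimulus_layer": [], "template_layer": [], "decision_layer": []}
    for d in deltas:
        out = model.run_trial((template_deg + d) % 180.0, template_deg)
        for k in layers:
            layers[k].append(out[k])
    if accumulator:
        vals = np.array([[model.accumulator_trial((template_deg + d) % 180.0,
                                                  template_deg)]
                         for d in deltas])
        layers["decision_layer"] = list(vals)
    rdms = {}
    for k, resp in layers.items():
        R = np.asarray(resp)
        diff = R[:, None, :] - R[None, :, :]
        rdms[k] = np.sqrt(np.einsum("abk,abk->ab", diff, diff))
    rdms["delta_grid"] = deltas
    return rdms
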