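"""Circular arithmetic for orientation (180-degree periodic) variables.

Orientations live on a half-circle: theta and theta + 180 deg describe the
same grating.  All trigonometric transforms therefore use the doubled angle
2*theta, and differences are wrapped to the signed interval (-90, +90].
"""

from __future__ import annotations

import numpy as np

ORI_PERIOD = 180.0


def wrap_orientation(theta):
    """Wrap orientation(s) in degrees into [0, 180)."""
    return np.asarray(theta, dtype=float) % ORI_PERIOD


def signed_diff(a, b):
    """Signed circular orientation difference a - b in degrees, in (-90, +90].

    The difference is computed modulo 180 deg and mapped so that +90 (not -90)
    represents the orthogonal case.
    """
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % ORI_PERIOD
    d = np.where(d > 90.0, d - ORI_PERIOD, d)
    return d


def circ_dist(a, b):
    """Absolute circular orientation distance in degrees, in [0, 90]."""
    return np.abs(signed_diff(a, b))


def cos2(theta_deg):
    """cos of the doubled orientation angle (degrees in, dimensionless out)."""
    return np.cos(np.deg2rad(2.0 * np.asarray(theta_deg, dtype=float)))


def sin2(theta_deg):
    """sin of the doubled orientation angle."""
    return np.sin(np.deg2rad(2.0 * np.asarray(theta_deg, dtype=float)))
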