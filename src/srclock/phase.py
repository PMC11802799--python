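"""Phase conventions and unit conversions.

The canonical internal unit is radians on [0, 2*pi). Phase *shifts* are
signed and live on (-pi, pi], so a shift of exactly half a cycle is
reported as an advance of +pi (the largest advance and the largest delay
coincide on the circle). Circadian time (CT) uses a standardized 24-h
cycle: CT = phase * 24 / (2*pi).
"""

from __future__ import annotations

import numpy as np

TWO_PI = 2.0 * np.pi
#: Circadian period used for all hour<->radian conversions (hours).
CIRCADIAN_PERIOD_H = 24.0


def wrap_phase(x):
    """Wrap angle(s) to the canonical interval [0, 2*pi)."""
    return np.mod(x, TWO_PI)


def wrap_shift(x):
    """Wrap signed difference(s) to (-pi, pi]."""
    w = np.mod(np.asarray(x, dtype=float), TWO_PI)
    w = np.where(w > np.pi, w - TWO_PI, w)
    if np.ndim(x) == 0:
        return float(w)
    return w


def hours_to_rad(h):
    """Circadian hours -> radians (24 h == one full cycle)."""
    return np.asarray(h, dtype=float) * TWO_PI / CIRCADIAN_PERIOD_H


def rad_to_hours(r):
    """Radians -> circadian hours."""
    return np.asarray(r, dtype=float) * CIRCADIAN_PERIOD_H / TWO_PI


def fraction_to_rad(f):
    """Cycle fraction (rad / 2*pi) -> radians."""
    return np.asarray(f, dtype=float) * TWO_PI


def rad_to_fraction(r):
    """Radians -> cycle fraction."""
    return np.asarray(r, dtype=float) / TWO_PI


def circular_mean(angles, weights=None):
    """Mean direction of a set of angles, in [0, 2*pi).

    Returns ``nan`` when the resultant vector has (near-)zero length.
    """
    angles = np.asarray(angles, dtype=float)
    z = np.exp(1j * angles)
    if weights is not None:
        z = z * np.asarray(weights, dtype=float)
    m = z.mean()
    if abs(m) < 1e-12:
        return float("nan")
    return float(wrap_phase(np.angle(m)))
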