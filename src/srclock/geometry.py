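"""Circular limit-cycle phase-resetting model.

A circadian clock is idealized as a point moving on the unit circle. A
stimulus displaces the state by a fixed vector ``F * exp(i*Phi)``; after
instantaneous relaxation back to the cycle, the new phase is the argument
of the displaced state:

    theta2 = arg( exp(i*theta1) + F * exp(i*Phi) )

The phase response curve (PRC) is g(theta1) = theta2 - theta1 wrapped to
(-pi, pi]. For F < 1 the map theta1 -> theta2 winds once around the
circle and the PRC is continuous (type 1); for F > 1 the displaced circle
no longer encloses the origin, the winding number drops to zero and the
PRC is discontinuous (type 0). At F = 1 the displaced circle passes
through the origin: the state antipodal to the stimulus direction lands
exactly on the amplitude-zero singular point, where phase is undefined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import AmbiguousPrcError, SingularityError
from .phase import TWO_PI, wrap_phase, wrap_shift

#: Default distance (in limit-cycle radii) below which a post-stimulus
#: state is treated as the singular point.
TOL_SINGULAR = 1e-9


@dataclass(frozen=True)
class StimulusVector:
    """Displacement applied to on-cycle states.

    Parameters
    ----------
    F : float
        Stimulus strength, in units of limit-cycle radii; must be >= 0.
    phi : float
        Direction of the displacement, radians (wrapped to [0, 2*pi)).
    """

    F: float
    phi: float = 0.0

    def __post_init__(self):
        if self.F < 0:
            raise ValueError(f"stimulus strength F must be >= 0, got {self.F}")
        object.__setattr__(self, "phi", float(wrap_phase(self.phi)))

    @property
    def as_complex(self) -> complex:
        return self.F * np.exp(1j * self.phi)


class PrcType(enum.Enum):
    """Topological class of a phase response curve."""

    TYPE1 = "type1"  # continuous PRC; post-stimulus map winds once
    TYPE0 = "type0"  # discontinuous PRC; winding number zero
    SINGULAR = "singular"  # a sampled point sits on the singularity


@dataclass
class PhaseResponseCurve:
    """Sampled map from pre-stimulus phase to phase shift.

    ``theta1`` is strictly increasing within [0, 2*pi); every ``shift``
    lies in (-pi, pi].
    """

    theta1: np.ndarray
    shift: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.theta1 = np.asarray(self.theta1, dtype=float)
        self.shift = np.asarray(self.shift, dtype=float)
        if self.theta1.shape != self.shift.shape:
            raise ValueError("theta1 and shift must have equal length")
        if len(self.theta1) < 3:
            raise ValueError("a PRC needs at least 3 sampled phases")
        if np.any(self.theta1 < 0) or np.any(self.theta1 >= TWO_PI):
            raise ValueError("theta1 must lie in [0, 2*pi)")
        if np.any(np.diff(self.theta1) <= 0):
            raise ValueError("theta1 must be strictly increasing")
        if np.any(self.shift <= -np.pi) or np.any(self.shift > np.pi):
            raise ValueError("shifts must lie in (-pi, pi]")

    def __len__(self) -> int:
        return len(self.theta1)

    @property
    def theta2(self) -> np.ndarray:
        """Post-stimulus phases, canonicalized to [0, 2*pi)."""
        return wrap_phase(self.theta1 + self.shift)


def apply_stimulus(theta1, stim: StimulusVector, tol_singular: float = TOL_SINGULAR):
    """Post-stimulus phase of an on-cycle state (scalar or array).

    Raises
    ------
    SingularityError
        If any displaced state has magnitude below ``tol_singular``.
    """
    theta1 = np.asarray(theta1, dtype=float)
    z = np.exp(1j * theta1) + stim.as_complex
    mag = np.abs(z)
    if np.any(mag < tol_singular):
        raise SingularityError(
            f"stimulus (F={stim.F}, phi={stim.phi:.6g}) maps a state to the "
            f"singular point (|z| = {mag.min():.3g} < {tol_singular:g})"
        )
    out = wrap_phase(np.angle(z))
    if theta1.ndim == 0:
        return float(out)
    return out


def phase_shift(theta1, stim: StimulusVector, tol_singular: float = TOL_SINGULAR):
    """Phase shift g(theta1) = theta2 - theta1, wrapped to (-pi, pi]."""
    theta2 = apply_stimulus(theta1, stim, tol_singular=tol_singular)
    return wrap_shift(np.asarray(theta2) - np.asarray(theta1, dtype=float))


def generate_prc(
    stim: StimulusVector,
    n_phases: int = 100,
    tol_singular: float = TOL_SINGULAR,
) -> PhaseResponseCurve:
    """Sample the model PRC on a uniform phase grid.

    If a grid point lands on the singular point (possible only at F = 1),
    the grid is shifted by half a step; the transition is measure-zero and
    the perturbed curve represents the same stimulus.
    """
    if n_phases < 3:
        raise ValueError("n_phases must be >= 3")
    grid = TWO_PI * np.arange(n_phases) / n_phases
    try:
        shifts = phase_shift(grid, stim, tol_singular=tol_singular)
    except SingularityError:
        grid = wrap_phase(grid + np.pi / n_phases)
        grid = np.sort(grid)
        shifts = phase_shift(grid, stim, tol_singular=tol_singular)
    return PhaseResponseCurve(
        theta1=grid,
        shift=shifts,
        provenance={"model": "circular", "F": stim.F, "phi": stim.phi},
    )


def classify_prc(prc: PhaseResponseCurve, ambiguity_tol: float = 0.25) -> PrcType:
    """Classify a PRC by the winding number of theta1 -> theta2.

    The winding number is the sum of wrapped successive differences of the
    post-stimulus phases around the closed phase circle, divided by 2*pi.
    Winding 1 means the continuous (type-1) regime; winding 0 the
    discontinuous (type-0) regime.

    Raises
    ------
    AmbiguousPrcError
        If the winding sum is farther than ``ambiguity_tol`` from every
        integer (undersampled or inconsistent curve).
    """
    if len(prc) < 16:
        raise ValueError("classification needs >= 16 sampled phases")
    theta2 = prc.theta2
    closed_diffs = wrap_shift(np.diff(np.append(theta2, theta2[0])))
    winding = float(np.sum(closed_diffs)) / TWO_PI
    nearest = round(winding)
    if abs(winding - nearest) > ambiguity_tol:
        raise AmbiguousPrcError(
            f"winding sum {winding:.3f} is not close to an integer; "
            "the PRC appears undersampled"
        )
    if nearest == 1:
        return PrcType.TYPE1
    if nearest == 0:
        return PrcType.TYPE0
    raise AmbiguousPrcError(f"unexpected winding number {nearest}")
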