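"""Prediction models for combined stimuli, background (pre-treatment)
effects, and receptor antagonists.

Two combination rules, chosen by whether the stimuli share a signaling
pathway:

* different pathways -- the SRs add as vectors,
  R_{A+B} e^{i Theta_{A+B}} = R_A e^{i Theta_A} + R_B e^{i Theta_B},
  with the reported amplitude capped at 1 (the phase always comes from
  the uncapped sum);
* same pathway -- each amplitude is converted to its equivalent
  concentration through the inverse Hill function,
  x_eq = EC50 * (R / (1 - R))^(1/n), the equivalent doses add, and the
  combined amplitude is H(x_eq,A + x_eq,B). Saturation of H makes this
  strictly subadditive, unlike the vector sum.

A background (pre-treatment) dose of the same stimulus attenuates the
response to an added dose: R_ADD = H(x_BK + x_ADD) - H(x_BK), optionally
with the background concentration decayed by a multiplicative factor
before the second stimulus. A background of a *different* pathway leaves
the added stimulus's own SR unchanged (vector subtraction recovers it
exactly). A competitive antagonist drives the final response below the
background; its SR amplitude is |R_ADD| and its phase is opposite the
reset phase of the inhibited target.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dose import HillFit, PhaseAmplitudeLine, hill
from .errors import CapBiasWarning, NotInhibitoryError, SaturatedError
from .estimation import SRParams, THETA_REPORT_FLOOR
from .phase import wrap_phase

#: Amplitudes within this distance of 1 (normalized scale) are treated as
#: saturated: the equivalent concentration diverges.
EPS_SATURATION = 1e-6


class CombinationRule(enum.Enum):
    VECTOR_SUM = "vector_sum"
    EQUIVALENT_CONC = "equivalent_conc"
    BACKGROUND = "background"
    INHIBITOR = "inhibitor"


@dataclass
class CombinationResult:
    """Predicted SR for a stimulus combination.

    ``raw`` retains the uncapped complex sum: the phase and any subsequent
    subtraction are computed from it, while ``R_pred`` is capped at 1.
    """

    R_pred: float
    theta_pred: float | None
    rule: CombinationRule
    cap_applied: bool = False
    raw: complex = 0j
    inputs: dict = field(default_factory=dict)

    def as_sr(self) -> SRParams:
        return SRParams(
            R=self.R_pred,
            theta=self.theta_pred,
            diagnostics={"rule": self.rule.value, "cap_applied": self.cap_applied},
        )


def _result_from_complex(
    z: complex,
    rule: CombinationRule,
    inputs: dict,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> CombinationResult:
    R_raw = abs(z)
    cap = R_raw > 1.0
    theta = float(wrap_phase(np.angle(z))) if R_raw >= theta_report_floor else None
    return CombinationResult(
        R_pred=min(R_raw, 1.0),
        theta_pred=theta,
        rule=rule,
        cap_applied=cap,
        raw=z,
        inputs=inputs,
    )


def combine_vector_sum(sr_a: SRParams, sr_b: SRParams) -> CombinationResult:
    """Different-pathway combination: complex sum of the two SRs.

    The reported amplitude is capped at 1 (flagged); the phase is the
    argument of the uncapped sum.
    """
    z = sr_a.as_complex + sr_b.as_complex
    return _result_from_complex(
        z,
        CombinationRule.VECTOR_SUM,
        inputs={"R_a": sr_a.R, "theta_a": sr_a.theta, "R_b": sr_b.R, "theta_b": sr_b.theta},
    )


def equivalent_concentration(
    R: float, hill_fit: HillFit, eps_sat: float = EPS_SATURATION
) -> float:
    """Dose producing SR amplitude ``R`` under the fitted Hill curve:
    the closed-form inverse x_eq = EC50 * (R / (1 - R))^(1/n).

    ``R`` is taken on the same (raw) scale as the fitted table and divided
    by the fit's ceiling ``r_max`` internally.
    """
    if R < 0:
        raise ValueError("amplitude must be >= 0")
    r = R / hill_fit.r_max
    if r >= 1.0 - eps_sat:
        raise SaturatedError(
            f"normalized amplitude {r:.6g} is saturated; equivalent "
            "concentration is unbounded"
        )
    if r == 0.0:
        return 0.0
    return float(hill_fit.ec50 * (r / (1.0 - r)) ** (1.0 / hill_fit.n_h))


def combine_same_pathway(
    R_a: float,
    R_b: float,
    hill_fit: HillFit,
    line: PhaseAmplitudeLine | None = None,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> CombinationResult:
    """Same-pathway combination via equivalent concentrations:
    R_{A+B} = H(x_eq,A + x_eq,B), on the raw scale of the fit.

    The phase, when a :class:`PhaseAmplitudeLine` for the shared pathway
    is supplied, comes from evaluating the line at the predicted
    amplitude. The line must be the one fitted for this stimulus/tissue;
    there is deliberately no default.
    """
    x_a = equivalent_concentration(R_a, hill_fit)
    x_b = equivalent_concentration(R_b, hill_fit)
    R_pred = hill_fit.r_max * hill(x_a + x_b, hill_fit.ec50, hill_fit.n_h)
    theta = None
    if line is not None and R_pred >= theta_report_floor:
        theta = line.predict(R_pred)
    return CombinationResult(
        R_pred=float(R_pred),
        theta_pred=theta,
        rule=CombinationRule.EQUIVALENT_CONC,
        raw=complex(R_pred),
        inputs={"R_a": R_a, "R_b": R_b, "x_eq_a": x_a, "x_eq_b": x_b},
    )


def background_response(
    x_bk: float,
    x_add: float,
    hill_fit: HillFit,
    decay: float = 1.0,
    line: PhaseAmplitudeLine | None = None,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> CombinationResult:
    """Response to an added dose of the *same* stimulus on top of a
    background dose: R_ADD = H(d*x_BK + x_ADD) - H(d*x_BK).

    ``decay`` (in (0, 1]) multiplies the background concentration to model
    its loss between the two treatments (named presets: 1.0 no decay, 0.5
    half, 1/3 one-third).
    """
    if x_bk < 0 or x_add < 0:
        raise ValueError("concentrations must be >= 0")
    if not (0.0 < decay <= 1.0):
        raise ValueError("decay must be in (0, 1]")
    eff_bk = decay * x_bk
    R_pred = hill_fit.r_max * (
        hill(eff_bk + x_add, hill_fit.ec50, hill_fit.n_h)
        - hill(eff_bk, hill_fit.ec50, hill_fit.n_h)
    )
    theta = None
    if line is not None and R_pred >= theta_report_floor:
        theta = line.predict(R_pred)
    return CombinationResult(
        R_pred=float(R_pred),
        theta_pred=theta,
        rule=CombinationRule.BACKGROUND,
        raw=complex(R_pred),
        inputs={"x_bk": x_bk, "x_add": x_add, "decay": decay},
    )


#: Named background-decay presets.
DECAY_PRESETS = {"none": 1.0, "half": 0.5, "third": 1.0 / 3.0}


def cross_background_response(
    sr_final: SRParams | CombinationResult,
    sr_bk: SRParams,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> CombinationResult:
    """SR of an added stimulus, recovered by subtracting the background SR
    from the final (combined) SR as vectors.

    For a background of a different pathway this returns the added
    stimulus's own SR unchanged. When the final result carries a capped
    amplitude, the subtraction uses the retained *uncapped* complex sum
    (the capped value would bias the difference) and a warning is emitted
    so the caller knows the reported final amplitude and the subtraction
    operand differ.
    """
    if isinstance(sr_final, CombinationResult):
        if sr_final.cap_applied:
            warnings.warn(
                "final amplitude was capped at 1; subtraction performed on "
                "the uncapped complex sum",
                CapBiasWarning,
                stacklevel=2,
            )
        z_final = sr_final.raw
    else:
        z_final = sr_final.as_complex
    z = z_final - sr_bk.as_complex
    return _result_from_complex(
        z,
        CombinationRule.BACKGROUND,
        inputs={"R_final": abs(z_final), "R_bk": sr_bk.R},
        theta_report_floor=theta_report_floor,
    )


def inhibitor_response(
    R_final: float, R_bk: float, target_theta: float
) -> SRParams:
    """SR of a competitive antagonist from the drop it causes.

    When the added stimulus inhibits the background pathway the final
    response falls below the background response (R_ADD < 0); the
    antagonist's SR amplitude is |R_ADD| = R_BK - R_final and its phase is
    opposite (+pi) the reset phase of the inhibited target.
    """
    if R_final < 0 or R_bk < 0:
        raise ValueError("amplitudes must be >= 0")
    if R_final >= R_bk:
        raise NotInhibitoryError(
            f"final response {R_final} is not below background {R_bk}"
        )
    return SRParams(
        R=R_bk - R_final,
        theta=float(wrap_phase(target_theta + np.pi)),
        diagnostics={"rule": CombinationRule.INHIBITOR.value},
    )
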