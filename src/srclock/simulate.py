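"""Stuart-Landau oscillator-ensemble simulator and synthetic plate
generator.

Each single-cell clock is a Stuart-Landau oscillator (normal form of a
Hopf bifurcation) with zero shear: in polar coordinates

    dR/dt = alpha * (A - R^2) * R,       dtheta/dt = sigma_i,

so the radial coordinate relaxes to the circular limit cycle of radius
sqrt(A) at rate alpha while the angle rotates uniformly (A = 1 and
sigma_i = 2*pi/24 rad/h by default, a 24-h clock on the unit cycle). A
stimulus displaces every oscillator's complex state by F * exp(i*Phi).
The population's bulk reporter signal (the in-silico analogue of plate
bioluminescence) is the collective output mean_j R_j cos(theta_j).

The radial equation is propagated by its closed-form solution (logistic
in u = R^2), so trajectories carry no integrator error. The plate
generator layers the experiment's nuisance structure on top: a
multiplicative exponentially-decaying baseline, per-oscillator period
heterogeneity that spontaneously desynchronizes each well before the
stimulus, and additive measurement noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .estimation import BioluminescenceSeries, SRParams, fit_cosine
from .geometry import StimulusVector
from .phase import TWO_PI, wrap_phase
from .reconstruct import forward_amplitude


@dataclass(frozen=True)
class SLParams:
    """Stuart-Landau dynamics parameters.

    alpha : radial relaxation rate toward the limit cycle, 1/h. The paper
        model leaves it free; 1/h makes relaxation fast relative to the
        24-h cycle without being instantaneous.
    A : squared limit-cycle radius (cycle radius sqrt(A)); 1 by default.
    sigma_i : angular frequency, rad/h; 2*pi/24 by default.
    """

    alpha: float = 1.0
    A: float = 1.0
    sigma_i: float = TWO_PI / 24.0

    def __post_init__(self):
        if self.alpha <= 0 or self.A <= 0:
            raise ValueError("alpha and A must be positive")


@dataclass
class OscillatorEnsemble:
    """States (R_j, theta_j) of a population of uncoupled oscillators.

    ``sigma`` may be a scalar (homogeneous population) or a per-oscillator
    array (heterogeneity drives spontaneous desynchronization).
    """

    r: np.ndarray
    theta: np.ndarray
    params: SLParams = field(default_factory=SLParams)
    sigma: np.ndarray | float | None = None

    def __post_init__(self):
        self.r = np.asarray(self.r, dtype=float)
        self.theta = wrap_phase(np.asarray(self.theta, dtype=float))
        if self.r.shape != self.theta.shape:
            raise ValueError("r and theta must have equal length")
        if np.any(self.r < 0):
            raise ValueError("radial coordinates must be >= 0")
        if self.sigma is None:
            self.sigma = self.params.sigma_i

    def __len__(self) -> int:
        return len(self.r)

    @classmethod
    def uniform_on_cycle(cls, n_osc: int, params: SLParams | None = None):
        """The canonical initial condition: n_osc on-cycle oscillators at
        phases theta_j = 2*pi*j/n_osc."""
        params = params or SLParams()
        theta = TWO_PI * np.arange(n_osc) / n_osc
        return cls(r=np.full(n_osc, np.sqrt(params.A)), theta=theta, params=params)


def _propagate_radius(r0: np.ndarray, alpha: float, A: float, t) -> np.ndarray:
    """Closed-form solution of dR/dt = alpha(A - R^2)R.

    u = R^2 obeys a logistic equation:
    u(t) = A u0 e^{2 alpha A t} / (A + u0 (e^{2 alpha A t} - 1)).
    R = 0 is the (unstable) fixed point and is propagated exactly.
    """
    u0 = np.asarray(r0, dtype=float) ** 2
    decay = np.exp(-2.0 * alpha * A * np.asarray(t, dtype=float))
    with np.errstate(divide="ignore"):
        u = np.where(u0 > 0, A / (1.0 + (A / np.where(u0 > 0, u0, 1.0) - 1.0) * decay), 0.0)
    return np.sqrt(u)


def evolve(ensemble: OscillatorEnsemble, t: float) -> OscillatorEnsemble:
    """Propagate the ensemble forward by ``t`` hours (exact solution)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    p = ensemble.params
    r = _propagate_radius(ensemble.r, p.alpha, p.A, t)
    theta = wrap_phase(ensemble.theta + np.asarray(ensemble.sigma) * t)
    return OscillatorEnsemble(r=r, theta=theta, params=p, sigma=ensemble.sigma)


def apply_ensemble_stimulus(
    ensemble: OscillatorEnsemble,
    stim: StimulusVector,
    rng: np.random.Generator | None = None,
) -> OscillatorEnsemble:
    """Displace every oscillator's complex state by F * exp(i*Phi).

    An oscillator landing exactly at the origin has no defined angle; it
    is flagged, given a random angle (at radius 0 the angle choice does
    not affect the dynamics until noise or another stimulus) and a
    warning is logged.
    """
    z = ensemble.r * np.exp(1j * ensemble.theta) + stim.as_complex
    r = np.abs(z)
    theta = wrap_phase(np.angle(z))
    at_origin = r < 1e-12
    if np.any(at_origin):
        warnings.warn(
            f"{int(at_origin.sum())} oscillator(s) mapped to the origin; "
            "angle re-randomized",
            stacklevel=2,
        )
        rng = rng or np.random.default_rng(0)
        theta = np.where(at_origin, rng.uniform(0, TWO_PI, size=r.shape), theta)
    return OscillatorEnsemble(
        r=r, theta=theta, params=ensemble.params, sigma=ensemble.sigma
    )


def collective_output(ensemble: OscillatorEnsemble) -> float:
    """Population output: mean over oscillators of R_j cos(theta_j)."""
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    return float(np.mean(ensemble.r * np.cos(ensemble.theta)))


def collective_trajectory(
    ensemble: OscillatorEnsemble, times_h: np.ndarray
) -> np.ndarray:
    """Collective output at each requested time (closed-form, vectorized:
    oscillators x times)."""
    times_h = np.asarray(times_h, dtype=float)
    p = ensemble.params
    r = _propagate_radius(ensemble.r[:, None], p.alpha, p.A, times_h[None, :])
    sigma = np.broadcast_to(np.asarray(ensemble.sigma, dtype=float), ensemble.r.shape)
    theta = ensemble.theta[:, None] + sigma[:, None] * times_h[None, :]
    return np.mean(r * np.cos(theta), axis=0)


def simulate_sr(
    params: SLParams | None = None,
    stim: StimulusVector = StimulusVector(F=0.0),
    n_osc: int = 100,
    dt_h: float = 1.0 / 6.0,
    fit_window_h: tuple[float, float] = (24.0, 48.0),
    period_mode: str = "fixed24",
) -> SRParams:
    """In-silico SR measurement on a uniformly phased on-cycle ensemble.

    The stimulus is applied at t = 0; the collective output is sampled at
    ``dt_h`` over the fit window and cosine-fitted (window 24-48 h after
    the stimulus) with the acrophase referenced to the stimulus time.
    In the fast-relaxation limit (alpha large) this reproduces the
    quadrature SR of the circular model; slow relaxation biases the
    measured amplitude, which is the key caveat of the instantaneous
    phase-only model.
    """
    params = params or SLParams()
    ens = OscillatorEnsemble.uniform_on_cycle(n_osc, params)
    ens = apply_ensemble_stimulus(ens, stim)
    times = np.arange(0.0, fit_window_h[1] + dt_h / 2, dt_h)
    signal = collective_trajectory(ens, times)
    if np.std(signal[times >= fit_window_h[0]]) < 1e-9:
        # no collective rhythm (e.g. F = 0 on a uniform ensemble)
        return SRParams(R=0.0, theta=None, n_support=n_osc,
                        diagnostics={"source": "stuart_landau"})
    series = BioluminescenceSeries(
        time_h=times, values=signal, stim_time_h=0.0, well="sim", detrended=True
    )
    fit = fit_cosine(
        series,
        t_start_h=fit_window_h[0],
        t_end_h=fit_window_h[1],
        period_mode=period_mode,
        t_ref_h=0.0,
    )
    return SRParams(
        R=fit.amplitude,
        theta=fit.acrophase,
        n_support=n_osc,
        diagnostics={"source": "stuart_landau", "period_h": fit.period_h},
    )


# ---------------------------------------------------------------------------
# Synthetic plate generator


class WellStimulus(BaseModel):
    """Stimulus programmed for one well."""

    model_config = ConfigDict(extra="forbid")

    F: float = Field(ge=0)
    phi_rad: float = 0.0


class PlateProtocol(BaseModel):
    """Protocol for a synthetic bioluminescence plate.

    Defaults emulate a one-week fibroblast reporter recording: 10-min
    sampling, stimulation 96 h after the start, wells that desynchronize
    spontaneously through per-oscillator period heterogeneity
    (SD 2 h around 24 h), an exponentially decaying multiplicative
    baseline, and additive counting noise.
    """

    model_config = ConfigDict(extra="forbid")

    stimuli: list[WellStimulus]
    n_oscillators: int = Field(default=200, gt=0)
    period_h: float = Field(default=24.0, gt=0)
    period_sd_h: float = Field(default=2.0, ge=0)
    alpha: float = Field(default=1.0, gt=0)
    stim_time_h: float = Field(default=96.0, ge=0)
    duration_h: float = Field(default=168.0, gt=0)
    dt_h: float = Field(default=1.0 / 6.0, gt=0)
    baseline_initial: float = Field(default=1000.0, gt=0)
    baseline_decay_per_h: float = Field(default=0.005, ge=0)
    rel_amplitude: float = Field(default=0.5, gt=0)
    noise_sd: float = Field(default=5.0, ge=0)
    seed: int = 0

    def model_post_init(self, __context):
        if self.duration_h < self.stim_time_h + 48.0:
            raise ValueError("duration must cover stim_time + 48 h")


def generate_plate(protocol: PlateProtocol) -> tuple[pd.DataFrame, dict]:
    """Simulate a plate and return (long-format data frame, ground truth).

    Each well starts fully synchronized on the limit cycle and dephases
    through its oscillators' heterogeneous periods; the programmed
    stimulus displaces all oscillator states at ``stim_time_h``.
    Luminescence is

        l(t) = baseline(t) * (1 + c * mean_j R_j cos(theta_j)) + noise,

    with baseline(t) = b0 * exp(-k t). Nonpositive values are clipped at
    zero with a warning. All randomness derives from ``protocol.seed``;
    identical protocols produce identical output. The ground-truth dict
    records, per well, the programmed stimulus and the SR amplitude
    predicted by the forward quadrature map.
    """
    p = protocol
    n_steps = int(np.floor(p.duration_h / p.dt_h)) + 1
    times = np.arange(n_steps) * p.dt_h
    pre = times < p.stim_time_h
    params = SLParams(alpha=p.alpha, A=1.0, sigma_i=TWO_PI / p.period_h)

    frames = []
    truth_wells = []
    clipped = 0
    for w, stim_spec in enumerate(p.stimuli):
        rng = np.random.default_rng([p.seed, w])
        periods = rng.normal(p.period_h, p.period_sd_h, size=p.n_oscillators)
        periods = np.clip(periods, 12.0, 48.0)  # guard absurd tails
        sigma = TWO_PI / periods
        ens0 = OscillatorEnsemble(
            r=np.ones(p.n_oscillators),
            theta=np.zeros(p.n_oscillators),
            params=params,
            sigma=sigma,
        )
        x = np.empty(n_steps)
        x[pre] = collective_trajectory(ens0, times[pre])
        at_stim = evolve(ens0, p.stim_time_h)
        stim = StimulusVector(F=stim_spec.F, phi=stim_spec.phi_rad)
        post_ens = apply_ensemble_stimulus(at_stim, stim, rng=rng)
        x[~pre] = collective_trajectory(post_ens, times[~pre] - p.stim_time_h)

        baseline = p.baseline_initial * np.exp(-p.baseline_decay_per_h * times)
        lum = baseline * (1.0 + p.rel_amplitude * x)
        if p.noise_sd > 0:
            lum = lum + rng.normal(0.0, p.noise_sd, size=n_steps)
        neg = lum < 0
        clipped += int(neg.sum())
        lum[neg] = 0.0

        well = f"W{w:02d}"
        frames.append(
            pd.DataFrame({"time_h": times, "well": well, "luminescence": lum})
        )
        truth_wells.append(
            {
                "well": well,
                "F": stim_spec.F,
                "phi_rad": float(wrap_phase(stim_spec.phi_rad)),
                "predicted_R": forward_amplitude(stim_spec.F) if stim_spec.F > 0 else 0.0,
                "stim_time_h": p.stim_time_h,
            }
        )
    if clipped:
        warnings.warn(f"{clipped} nonpositive luminescence values clipped at 0",
                      stacklevel=2)
    data = pd.concat(frames, ignore_index=True)
    truth = {"seed": p.seed, "protocol": p.model_dump(), "wells": truth_wells}
    return data, truth
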