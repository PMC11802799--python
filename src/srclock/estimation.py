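"""Singularity-response (SR) estimation.

The SR is the complex order parameter acquired by a desynchronized
oscillator population after a stimulus:

    R * exp(i*Theta) = <exp(i * (theta + g(theta)))>

with the average taken over a uniform distribution of pre-stimulus phases
theta. R in [0, 1] measures how strongly the stimulus synchronizes the
population; Theta is the phase toward which the clock is reset. Three
estimators are provided:

* :func:`sr_from_prc` -- equal-weight quadrature of the integral over a
  model or sampled PRC;
* :func:`sr_from_cells` -- the discrete complex mean over single-cell
  (pre-phase, shift) records;
* :func:`measure_sr` -- the bulk-bioluminescence pipeline: detrend a
  plate trace against its 24-h moving average, cosine-fit the
  post-stimulus window, and read R and Theta off the fitted cosine.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import (
    DegenerateSignalError,
    DetrendError,
    EmptyRecordsError,
    NonConvergenceError,
    UndersampledWarning,
)
from .geometry import PhaseResponseCurve, StimulusVector, apply_stimulus
from .phase import TWO_PI, rad_to_hours, wrap_phase, wrap_shift

#: Below this resultant length the SR phase is reported as undefined:
#: the argument of a near-zero complex mean is dominated by noise.
THETA_REPORT_FLOOR = 0.02

#: Default sampling interval of plate recordings (hours): 10-min bins.
DEFAULT_DT_H = 1.0 / 6.0


@dataclass
class SRParams:
    """SR amplitude and phase.

    ``theta`` is ``None`` when the resultant length is below the
    reporting floor (phase of a near-zero vector is meaningless).
    """

    R: float
    theta: float | None = None
    n_support: int | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.isfinite(self.R) or self.R < 0:
            raise ValueError(f"SR amplitude must be finite and >= 0, got {self.R}")
        if self.theta is not None:
            self.theta = float(wrap_phase(self.theta))

    @property
    def theta_ct_h(self) -> float | None:
        """SR phase expressed in circadian hours (CT)."""
        if self.theta is None:
            return None
        return float(rad_to_hours(self.theta))

    @property
    def as_complex(self) -> complex:
        if self.theta is None:
            return complex(0.0)
        return self.R * np.exp(1j * self.theta)


@dataclass
class BioluminescenceSeries:
    """Uniformly sampled luminescence of one well.

    ``stim_time_h`` is hours from the start of the recording.
    """

    time_h: np.ndarray
    values: np.ndarray
    stim_time_h: float | None = None
    well: str = ""
    condition: str = ""
    concentration: float | None = None
    detrended: bool = False

    def __post_init__(self):
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time_h.shape != self.values.shape:
            raise ValueError("time_h and values must have equal length")
        if len(self.time_h) < 2:
            raise ValueError("a series needs at least 2 samples")
        steps = np.diff(self.time_h)
        dt = np.median(steps)
        if dt <= 0 or np.any(np.abs(steps - dt) > 0.01 * dt):
            raise ValueError(
                f"series {self.well!r} is not uniformly sampled "
                f"(median step {dt:.4g} h)"
            )

    @property
    def dt_h(self) -> float:
        return float(np.median(np.diff(self.time_h)))


@dataclass
class CosineFit:
    """Result of a least-squares cosine fit.

    ``acrophase`` is the phase of the cosine at the reference time
    ``t_ref_h`` (the fitted model is
    ``baseline + amplitude * cos(2*pi*(t - t_ref)/period + acrophase)``);
    amplitude is always nonnegative, with sign folded into the phase.
    """

    amplitude: float
    acrophase: float
    period_h: float
    baseline: float
    rss: float
    t_ref_h: float
    n_obs: int


def _complex_mean_to_sr(
    vectors: np.ndarray,
    theta_report_floor: float,
    n_support: int | None = None,
    diagnostics: dict | None = None,
) -> SRParams:
    m = vectors.mean()
    R = float(abs(m))
    assert R <= 1.0 + 1e-12, "mean of unit vectors cannot exceed 1"
    R = min(R, 1.0)
    theta = float(wrap_phase(np.angle(m))) if R >= theta_report_floor else None
    return SRParams(
        R=R, theta=theta, n_support=n_support, diagnostics=diagnostics or {}
    )


def sr_from_prc(
    prc: StimulusVector | PhaseResponseCurve,
    n_quad: int = 100,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> SRParams:
    """SR parameters from a PRC by equal-weight quadrature.

    When a :class:`StimulusVector` is given, the model PRC is evaluated at
    ``n_quad`` uniform phase nodes ``theta_j = 2*pi*j/n_quad``. When a
    sampled PRC is given, its own (approximately uniform) phases serve as
    the quadrature nodes and ``n_quad`` is ignored.
    """
    if isinstance(prc, StimulusVector):
        nodes = TWO_PI * np.arange(n_quad) / n_quad
        theta2 = apply_stimulus(nodes, prc)
    else:
        nodes = prc.theta1
        theta2 = wrap_phase(prc.theta1 + prc.shift)
    if len(nodes) < 16:
        warnings.warn(
            f"only {len(nodes)} quadrature nodes; SR estimate may be biased",
            UndersampledWarning,
            stacklevel=2,
        )
    return _complex_mean_to_sr(
        np.exp(1j * theta2),
        theta_report_floor,
        n_support=len(nodes),
        diagnostics={"source": "prc", "n_quad": len(nodes)},
    )


def sr_from_cells(
    theta: np.ndarray,
    shift: np.ndarray,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> SRParams:
    """SR parameters from per-cell (pre-stimulus phase, shift) records.

    Valid as an estimator of the SR integral when the pre-stimulus phases
    are approximately uniformly distributed over the cycle.
    """
    theta = np.asarray(theta, dtype=float)
    shift = np.asarray(shift, dtype=float)
    if theta.shape != shift.shape:
        raise ValueError("theta and shift must have equal length")
    if len(theta) == 0:
        raise EmptyRecordsError("no cell records supplied")
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(shift))):
        raise ValueError("cell records must be finite")
    post = wrap_phase(theta + wrap_shift(shift))
    return _complex_mean_to_sr(
        np.exp(1j * post),
        theta_report_floor,
        n_support=len(theta),
        diagnostics={"source": "cells"},
    )


def detrend(
    series: BioluminescenceSeries,
    window_h: float = 24.0,
    max_flagged_fraction: float = 0.05,
) -> BioluminescenceSeries:
    """Normalize luminescence against its centered moving average.

    Each point becomes ``L_j = (l_j - lbar_j) / lbar_j`` where ``lbar`` is
    the boxcar mean over a centered window of ``2n + 1`` samples, with
    ``n`` the number of samples in half the window (n = 72 at 10-min
    sampling and a 24-h window). The first and last ``n`` points have no
    complete window and are dropped rather than computed from shrunken
    windows, which would bias the ends.
    """
    n = half_window_samples(series.dt_h, window_h)
    if len(series.values) <= 2 * n + 1:
        raise DetrendError(
            f"series of {len(series.values)} points is too short for a "
            f"{window_h}-h window ({2 * n + 1} samples)"
        )
    kernel = np.full(2 * n + 1, 1.0 / (2 * n + 1))
    lbar = np.convolve(series.values, kernel, mode="valid")
    interior = series.values[n:-n]
    bad = lbar <= 0
    if bad.mean() > max_flagged_fraction:
        raise DetrendError(
            f"{bad.sum()} of {bad.size} moving-average points are "
            "nonpositive; series rejected"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        L = np.where(bad, np.nan, (interior - lbar) / lbar)
    return BioluminescenceSeries(
        time_h=series.time_h[n:-n],
        values=L,
        stim_time_h=series.stim_time_h,
        well=series.well,
        condition=series.condition,
        concentration=series.concentration,
        detrended=True,
    )


def half_window_samples(dt_h: float, window_h: float = 24.0) -> int:
    """Number of samples in half the detrending window (72 at 10-min
    sampling with the default 24-h window)."""
    return int(round((window_h / 2.0) / dt_h))


def _cosine(t, baseline, amplitude, phase, period):
    return baseline + amplitude * np.cos(TWO_PI * t / period + phase)


def fit_cosine(
    series: BioluminescenceSeries,
    t_start_h: float,
    t_end_h: float,
    period_mode: str = "fixed24",
    t_ref_h: float | None = None,
    period_bounds_h: tuple[float, float] = (20.0, 28.0),
    noise_floor: float = 1e-8,
) -> CosineFit:
    """Least-squares cosine fit over a time window.

    ``period_mode`` is ``"fixed24"`` (linear least squares on a cos/sin
    basis at a 24-h period; exact, no iteration) or ``"free"`` (period
    floats within ``period_bounds_h``; nonlinear fit initialized from the
    fixed-period solution). The acrophase is referenced to ``t_ref_h``
    (default: the stimulus time, else the window start).
    """
    if period_mode not in ("fixed24", "free"):
        raise ValueError(f"unknown period_mode {period_mode!r}")
    if t_ref_h is None:
        t_ref_h = series.stim_time_h if series.stim_time_h is not None else t_start_h
    mask = (series.time_h >= t_start_h) & (series.time_h <= t_end_h)
    mask &= np.isfinite(series.values)
    t = series.time_h[mask]
    y = series.values[mask]
    if len(t) < 4 or t[-1] - t[0] < 24.0 - 1e-9:
        raise ValueError(
            f"fit window [{t_start_h}, {t_end_h}] h holds "
            f"{t[-1] - t[0] if len(t) else 0:.1f} h of data; need >= 24 h"
        )
    if np.std(y) < noise_floor:
        raise DegenerateSignalError(
            f"window variance {np.var(y):.3g} is below the noise floor"
        )
    tau = t - t_ref_h

    def _linear_fit(period):
        w = TWO_PI / period
        X = np.column_stack([np.ones_like(tau), np.cos(w * tau), np.sin(w * tau)])
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ coef
        return coef, float(resid @ resid)

    coef, rss = _linear_fit(24.0)
    baseline, c, s = coef
    amplitude = float(np.hypot(c, s))
    acrophase = float(np.arctan2(-s, c))
    period = 24.0

    if period_mode == "free":
        model = lmfit.Model(_cosine, independent_vars=["t"])
        params = model.make_params(
            baseline=baseline,
            amplitude=max(amplitude, noise_floor),
            phase=acrophase,
            period=24.0,
        )
        params["amplitude"].set(min=0.0)
        params["period"].set(min=period_bounds_h[0], max=period_bounds_h[1])
        result = model.fit(y, params, t=tau)
        if not result.success:
            raise NonConvergenceError("free-period cosine fit did not converge")
        baseline = float(result.params["baseline"].value)
        amplitude = float(result.params["amplitude"].value)
        acrophase = float(result.params["phase"].value)
        period = float(result.params["period"].value)
        rss = float(np.sum(result.residual**2))

    if amplitude < 0:  # fold negative amplitude into the phase
        amplitude = -amplitude
        acrophase += np.pi
    return CosineFit(
        amplitude=amplitude,
        acrophase=float(wrap_phase(acrophase)),
        period_h=period,
        baseline=float(baseline),
        rss=rss,
        t_ref_h=float(t_ref_h),
        n_obs=len(t),
    )


def measure_sr(
    series: BioluminescenceSeries,
    fit_offsets_h: tuple[float, float] = (24.0, 48.0),
    period_mode: str = "fixed24",
    window_h: float = 24.0,
    theta_report_floor: float = THETA_REPORT_FLOOR,
    reference_amplitude: float | None = None,
    control: SRParams | None = None,
) -> SRParams:
    """Direct SR measurement from a bulk bioluminescence trace.

    Pipeline: detrend against the 24-h moving average, then cosine-fit the
    window ``stim_time + fit_offsets_h`` (default 24-48 h post-stimulus;
    tissues with slower dynamics may use (24, 96)). R is the fitted
    amplitude on the detrended scale; Theta is the acrophase
    back-extrapolated to the stimulus time at the fitted period.

    Two same-plate corrections are available, both standard practice for
    bulk recordings:

    * ``control`` -- the SR measured on a vehicle-control well (measure
      it with ``theta_report_floor=0`` so its phase is retained). Its
      complex amplitude is subtracted vectorially; this removes the
      residual collective rhythm a not-yet-fully-desynchronized plate
      carries through the stimulus, which otherwise contaminates weak
      responses.
    * ``reference_amplitude`` -- the (control-corrected) amplitude of a
      maximal-response well; dividing by it places R on the [0, 1] SR
      scale. The raw amplitude, the control difference and the reference
      ratio are all reported in the diagnostics.
    """
    if series.stim_time_h is None:
        raise ValueError("series has no recorded stimulus time")
    det = series if series.detrended else detrend(series, window_h=window_h)
    fit = fit_cosine(
        det,
        t_start_h=series.stim_time_h + fit_offsets_h[0],
        t_end_h=series.stim_time_h + fit_offsets_h[1],
        period_mode=period_mode,
        t_ref_h=series.stim_time_h,
    )
    z = fit.amplitude * np.exp(1j * fit.acrophase)
    if control is not None:
        z = z - control.as_complex
    R = abs(z)
    theta_raw = float(wrap_phase(np.angle(z)))
    if reference_amplitude is not None:
        if reference_amplitude <= 0:
            raise ValueError("reference_amplitude must be positive")
        R = R / reference_amplitude
    theta = theta_raw if R >= theta_report_floor else None
    return SRParams(
        R=R,
        theta=theta,
        n_support=fit.n_obs,
        diagnostics={
            "source": "timeseries",
            "window_h": [series.stim_time_h + fit_offsets_h[0],
                         series.stim_time_h + fit_offsets_h[1]],
            "period_h": fit.period_h,
            "rss": fit.rss,
            "raw_amplitude": fit.amplitude,
            "control_R": None if control is None else control.R,
            "control_difference": None if control is None else float(abs(z)),
            "reference_amplitude": reference_amplitude,
        },
    )


def measure_plate_sr(
    series_list: list[BioluminescenceSeries],
    control_well: str | None = None,
    reference_well: str | None = None,
    reference_true_R: float = 1.0,
    **measure_kwargs,
) -> dict[str, SRParams]:
    """SR measurement across a plate with same-plate corrections.

    If ``control_well`` names a vehicle-control series, its complex SR is
    subtracted from every other well (removes residual pre-stimulus
    synchrony). If ``reference_well`` names a maximal-response well, every
    amplitude is divided by the reference's (control-corrected) amplitude
    scaled to ``reference_true_R`` (the SR amplitude the reference is
    known or designed to produce, e.g. from the forward map for a
    saturating stimulus), placing results on the [0, 1] SR scale.
    Remaining keyword arguments pass through to :func:`measure_sr`.
    """
    by_well = {s.well: s for s in series_list}
    control = None
    if control_well is not None:
        control = measure_sr(
            by_well[control_well], theta_report_floor=0.0, **measure_kwargs
        )
    scale = None
    if reference_well is not None:
        ref = measure_sr(
            by_well[reference_well],
            control=control,
            theta_report_floor=0.0,
            **measure_kwargs,
        )
        scale = ref.R / reference_true_R
    out: dict[str, SRParams] = {}
    for well, series in by_well.items():
        if well == control_well:
            out[well] = measure_sr(by_well[well], theta_report_floor=0.0,
                                   **measure_kwargs)
            continue
        out[well] = measure_sr(
            series, control=control, reference_amplitude=scale, **measure_kwargs
        )
    return out
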