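"""Hill-equation dose-response parameterization of SR amplitude and the
linear SR-phase-vs-amplitude relationship.

The amplitude dose response of a resetting stimulus follows the Hill
equation H(x) = x^n / (x^n + EC50^n): exponential rise at low dose,
near-linear midrange, saturation toward 1. Because bulk SR amplitudes are
measured on an arbitrary (reporter-dependent) scale, tables are first
normalized by the maximum per-concentration mean response; the recorded
ceiling ``r_max`` maps fits back to the raw scale. The SR phase varies
approximately linearly with the SR amplitude, so two curves -- a Hill fit
and a straight phase line, four parameters in all -- predict the complete
phase response at any dose.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import (
    AllZeroError,
    ExtrapolationWarning,
    NonConvergenceError,
    NonMonotoneWarning,
    WrapAmbiguousError,
    ZeroVarianceError,
)
from .estimation import SRParams, THETA_REPORT_FLOOR
from .phase import circular_mean, wrap_phase, wrap_shift

#: Columns of a dose-response table.
DOSE_COLUMNS = ["concentration", "R", "theta_rad", "replicate", "condition", "exclude"]


def hill(x, ec50: float, n_h: float):
    """Hill function H(x) = x^n / (x^n + EC50^n) for x >= 0."""
    scalar = np.ndim(x) == 0
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    pos = x > 0
    # compute in log space to avoid overflow at extreme doses
    ratio = np.exp(n_h * (np.log(x[pos]) - np.log(ec50)))
    out[pos] = ratio / (1.0 + ratio)
    if scalar:
        return float(out[0])
    return out


@dataclass
class HillFit:
    """Fitted dose-response parameters.

    ``r_max`` is the response ceiling the data were normalized by (1 when
    the table was already on the [0, 1] scale); predictions on the raw
    scale are ``r_max * H(x)``.
    """

    ec50: float
    n_h: float
    r_max: float
    r_squared: float
    conc_range: tuple[float, float]
    extrapolated: bool = False
    non_monotone: bool = False
    n_points: int = 0

    def predict(self, x, raw_scale: bool = True):
        """Predicted response at concentration(s) x."""
        h = hill(x, self.ec50, self.n_h)
        return self.r_max * h if raw_scale else h


@dataclass
class PhaseAmplitudeLine:
    """Straight-line model Theta = a + b * R on unwrapped phases."""

    intercept: float  # radians
    slope: float  # radians per unit amplitude
    r_range: tuple[float, float]
    rss: float = 0.0
    n_points: int = 0

    def predict(self, R) -> float:
        """Predicted (wrapped) SR phase at amplitude R."""
        return float(wrap_phase(self.intercept + self.slope * np.asarray(R, float)))


def _per_concentration_means(df: pd.DataFrame) -> pd.Series:
    return df.groupby("concentration")["R"].mean()


def normalize_by_max(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Divide all responses by the maximum per-concentration mean.

    The ceiling is taken over per-concentration means, not raw replicate
    points, so a single noisy replicate cannot set the scale. Returns the
    normalized table and the ceiling ``r_max``.
    """
    if not (table["R"] > 0).any():
        raise AllZeroError("no positive response in the table")
    r_max = float(_per_concentration_means(table).max())
    out = table.copy()
    out["R"] = out["R"] / r_max
    return out, r_max


def r_squared(y, f) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot (can be < 0)."""
    y = np.asarray(y, dtype=float)
    f = np.asarray(f, dtype=float)
    if y.shape != f.shape or len(y) < 2:
        raise ValueError("y and f must have equal length >= 2")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ZeroVarianceError("all observed values are equal")
    ss_res = float(np.sum((y - f) ** 2))
    return 1.0 - ss_res / ss_tot


def _check_monotone(df: pd.DataFrame) -> bool:
    """True if the mean response drops by > 20% of its running maximum at
    any higher dose (cytotoxicity-like shape)."""
    means = _per_concentration_means(df).sort_index()
    running_max = means.cummax()
    return bool(((running_max - means) > 0.2 * running_max).any())


def fit_hill(
    table: pd.DataFrame,
    normalize: bool = False,
    use_means: bool = False,
    n_h_max: float = 10.0,
) -> HillFit:
    """Least-squares Hill fit of SR amplitude vs. concentration.

    Zero-dose rows are excluded from the least squares (H(0) = 0 by
    construction; vehicle controls serve comparison, not fitting), as are
    rows with ``exclude = 1``. EC50 is fitted in log10 space with bounds
    [min dose / 100, max dose * 100] and a multi-start over a coarse
    (log10 EC50, n) grid; the Hill slope is bounded to (0, ``n_h_max``].

    With ``normalize=True`` the table is first normalized by the maximum
    per-concentration mean and the ceiling recorded as ``r_max``.
    ``use_means=True`` fits per-concentration means instead of raw
    replicate points.
    """
    df = table.copy()
    if "exclude" in df.columns:
        df = df[df["exclude"].fillna(0).astype(int) == 0]
    r_max = 1.0
    if normalize:
        df, r_max = normalize_by_max(df)
    df = df[df["concentration"] > 0]
    if df["concentration"].nunique() < 3:
        raise ValueError("need >= 3 distinct nonzero concentrations")

    non_monotone = _check_monotone(df)
    if non_monotone:
        warnings.warn(
            "mean response decreases > 20% at high dose; Hill model may be "
            "inappropriate",
            NonMonotoneWarning,
            stacklevel=2,
        )

    if use_means:
        means = _per_concentration_means(df)
        x = means.index.to_numpy(dtype=float)
        y = means.to_numpy(dtype=float)
    else:
        x = df["concentration"].to_numpy(dtype=float)
        y = df["R"].to_numpy(dtype=float)

    log_lo = np.log10(x.min()) - 2.0
    log_hi = np.log10(x.max()) + 2.0

    def residuals(p):
        log_ec50, n_h = p
        return hill(x, 10.0**log_ec50, n_h) - y

    best = None
    starts = [
        (lg, n0)
        for lg in np.linspace(np.log10(x.min()), np.log10(x.max()), 5)
        for n0 in (0.5, 1.0, 2.0, 4.0)
    ]
    for p0 in starts:
        try:
            sol = least_squares(
                residuals,
                p0,
                bounds=([log_lo, 1e-6], [log_hi, n_h_max]),
                method="trf",
            )
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise NonConvergenceError("Hill fit failed from every start")

    ec50 = float(10.0 ** best.x[0])
    n_h = float(best.x[1])
    r2 = r_squared(y, hill(x, ec50, n_h))
    conc_range = (float(x.min()), float(x.max()))
    extrapolated = not (conc_range[0] * 1e-2 <= ec50 <= conc_range[1] * 1e2)
    return HillFit(
        ec50=ec50,
        n_h=n_h,
        r_max=r_max,
        r_squared=r2,
        conc_range=conc_range,
        extrapolated=extrapolated,
        non_monotone=non_monotone,
        n_points=len(x),
    )


def fit_phase_line(
    R: np.ndarray,
    theta: np.ndarray,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> PhaseAmplitudeLine:
    """Ordinary least squares of SR phase against SR amplitude.

    Phases are first unwrapped around their circular mean (so a cluster
    straddling 0/2*pi fits a finite-slope line with no artificial 2*pi
    jump), then regressed linearly on amplitude. Pairs with amplitude
    below the reporting floor are dropped.

    Raises
    ------
    WrapAmbiguousError
        If the unwrapped phase spread exceeds pi: the points do not sit on
        one coherent arc and a line through them is meaningless.
    """
    R = np.asarray(R, dtype=float)
    theta = np.asarray(theta, dtype=float)
    keep = np.isfinite(R) & np.isfinite(theta) & (R >= theta_report_floor)
    R, theta = R[keep], theta[keep]
    if len(R) < 3:
        raise ValueError("need >= 3 pairs with amplitude above the floor")
    center = circular_mean(theta)
    if not np.isfinite(center):
        raise WrapAmbiguousError(
            "phases have a near-zero resultant; no coherent arc to unwrap"
        )
    dev = wrap_shift(theta - center)
    if dev.max() - dev.min() > np.pi:
        raise WrapAmbiguousError(
            f"phase spread {dev.max() - dev.min():.3f} rad exceeds pi after "
            "unwrapping"
        )
    unwrapped = center + dev
    slope, intercept = np.polyfit(R, unwrapped, 1)
    resid = unwrapped - (intercept + slope * R)
    return PhaseAmplitudeLine(
        intercept=float(intercept),
        slope=float(slope),
        r_range=(float(R.min()), float(R.max())),
        rss=float(resid @ resid),
        n_points=len(R),
    )


def fit_phase_line_from_table(table: pd.DataFrame, **kw) -> PhaseAmplitudeLine:
    df = table
    if "exclude" in df.columns:
        df = df[df["exclude"].fillna(0).astype(int) == 0]
    return fit_phase_line(df["R"].to_numpy(), df["theta_rad"].to_numpy(), **kw)


def predict_sr_at_dose(
    x: float,
    hill_fit: HillFit,
    line: PhaseAmplitudeLine | None = None,
    theta_report_floor: float = THETA_REPORT_FLOOR,
) -> SRParams:
    """Predicted SR parameters at concentration ``x``.

    R = r_max * H(x); Theta from the phase-amplitude line evaluated at the
    predicted amplitude (undefined when no line is supplied or the
    amplitude is below the reporting floor). Composable with PRC
    reconstruction to emit a predicted PRC at any dose.
    """
    if x < 0:
        raise ValueError("concentration must be >= 0")
    if x > 0 and not (hill_fit.conc_range[0] <= x <= hill_fit.conc_range[1]):
        warnings.warn(
            f"concentration {x} outside fitted range {hill_fit.conc_range}",
            ExtrapolationWarning,
            stacklevel=2,
        )
    R = float(hill_fit.predict(x))
    theta = None
    if line is not None and R >= theta_report_floor:
        theta = line.predict(R)
    return SRParams(R=R, theta=theta, diagnostics={"source": "dose_prediction", "x": x})
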