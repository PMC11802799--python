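"""Readers and writers for the plain-text interchange formats.

Three table dialects, all CSV with a header:

* PRC tables: ``phase_rad, shift_rad`` (or ``phase_h, shift_h`` in
  circadian hours; the unit is inferred from the header and recorded);
* plate recordings: long format ``time_h, well, luminescence`` with a
  JSON sidecar mapping each well to ``{stim_time_h, condition,
  concentration, unit}``;
* dose-response tables: ``concentration, unit, R, theta_rad, replicate,
  condition, exclude``.

Field names always carry their unit (``theta_rad``, ``stim_time_h``) —
the literature mixes radians, cycle fractions and circadian hours for the
same quantities, and implicit units are how those get confused.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import MissingSidecarError, NonuniformSamplingError, ParseError
from .estimation import BioluminescenceSeries
from .geometry import PhaseResponseCurve
from .phase import hours_to_rad, rad_to_hours, wrap_phase

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# PRC tables


def read_prc_csv(path) -> PhaseResponseCurve:
    """Read a PRC table; phases are canonicalized, shifts validated.

    Accepts ``phase_rad``/``shift_rad`` or ``phase_h``/``shift_h``
    columns; hour-valued tables are converted to radians and the
    conversion noted in provenance.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if {"phase_rad", "shift_rad"} <= set(df.columns):
        phase, shift, unit = df["phase_rad"], df["shift_rad"], "rad"
    elif {"phase_h", "shift_h"} <= set(df.columns):
        phase = hours_to_rad(df["phase_h"])
        shift = hours_to_rad(df["shift_h"])
        unit = "hours"
    else:
        raise ParseError(
            f"{path}: need columns phase_rad/shift_rad or phase_h/shift_h, "
            f"got {list(df.columns)}"
        )
    phase = np.asarray(phase, dtype=float)
    shift = np.asarray(shift, dtype=float)
    for i, s in enumerate(shift):
        if not (-np.pi < s <= np.pi + 1e-12):
            raise ParseError(
                f"{path}, line {i + 2}: shift {s:.6g} rad outside (-pi, pi]"
            )
    phase = wrap_phase(phase)
    order = np.argsort(phase)
    phase, shift = phase[order], shift[order]
    if np.any(np.diff(phase) == 0):
        dup = phase[np.where(np.diff(phase) == 0)[0][0]]
        raise ParseError(f"{path}: duplicate phase {dup:.6g} rad")
    return PhaseResponseCurve(
        theta1=phase,
        shift=np.minimum(shift, np.pi),
        provenance={"path": str(path), "unit": unit},
    )


def write_prc_csv(prc: PhaseResponseCurve, path, unit: str = "rad") -> None:
    path = Path(path)
    if unit == "rad":
        df = pd.DataFrame({"phase_rad": prc.theta1, "shift_rad": prc.shift})
    elif unit == "hours":
        df = pd.DataFrame(
            {"phase_h": rad_to_hours(prc.theta1), "shift_h": rad_to_hours(prc.shift)}
        )
    else:
        raise ValueError(f"unknown unit {unit!r}")
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# Plate recordings


def read_plate_csv(path, sidecar) -> list[BioluminescenceSeries]:
    """Read a long-format plate CSV plus its per-well metadata sidecar.

    Row order is irrelevant; each well is validated for uniform sampling
    (steps within 1% of the median interval).
    """
    path = Path(path)
    if sidecar is None or not Path(sidecar).exists():
        raise MissingSidecarError(f"no metadata sidecar for {path}")
    meta = json.loads(Path(sidecar).read_text())
    df = pd.read_csv(path)
    required = {"time_h", "well", "luminescence"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    out = []
    for well, g in df.groupby("well", sort=True):
        g = g.sort_values("time_h")
        t = g["time_h"].to_numpy(dtype=float)
        steps = np.diff(t)
        dt = np.median(steps)
        if np.any(np.abs(steps - dt) > 0.01 * dt):
            raise NonuniformSamplingError(
                f"well {well!r}: sampling step deviates from {dt:.4g} h"
            )
        m = meta.get(str(well), {})
        out.append(
            BioluminescenceSeries(
                time_h=t,
                values=g["luminescence"].to_numpy(dtype=float),
                stim_time_h=m.get("stim_time_h"),
                well=str(well),
                condition=m.get("condition", ""),
                concentration=m.get("concentration"),
            )
        )
    return out


def write_plate_csv(data: pd.DataFrame, path, sidecar=None, meta: dict | None = None):
    path = Path(path)
    data.to_csv(path, index=False, float_format=_FLOAT_FMT)
    if sidecar is not None:
        Path(sidecar).write_text(json.dumps(meta or {}, indent=2) + "\n")


def wide_to_long(df: pd.DataFrame, time_column: str = "time_h") -> pd.DataFrame:
    """Convert a device-style wide export (one column per well) to the
    long dialect."""
    return df.melt(
        id_vars=[time_column], var_name="well", value_name="luminescence"
    ).rename(columns={time_column: "time_h"})


# ---------------------------------------------------------------------------
# Dose-response tables


def read_dose_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if not {"concentration", "R"} <= set(df.columns):
        raise ParseError(f"{path}: need at least columns concentration, R")
    if "unit" in df.columns and df["unit"].nunique() > 1:
        raise ParseError(f"{path}: more than one concentration unit in table")
    if "exclude" not in df.columns:
        df["exclude"] = 0
    if (df["concentration"] < 0).any():
        bad = int(np.argmax(df["concentration"].to_numpy() < 0))
        raise ParseError(f"{path}, line {bad + 2}: negative concentration")
    return df


def write_dose_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)
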