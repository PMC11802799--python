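"""Analysis configuration and run provenance records."""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, ConfigDict, Field

from . import __version__


class AnalysisConfig(BaseModel):
    """Validated knobs of the estimation pipeline.

    Unknown keys are rejected so a typo in a config file fails loudly
    instead of silently running defaults.
    """

    model_config = ConfigDict(extra="forbid")

    phase_unit: Literal["rad", "hours", "fraction"] = "rad"
    detrend_window_h: float = Field(default=24.0, gt=0)
    fit_offset_start_h: float = Field(default=24.0, gt=0)
    fit_offset_end_h: float = Field(default=48.0, gt=0)
    period_mode: Literal["fixed24", "free"] = "fixed24"
    n_quad: int = Field(default=10_000, gt=0)
    inversion_tol: float = Field(default=1e-6, gt=0)
    F_max: float = Field(default=1e3, gt=0)
    decay: float = Field(default=1.0, gt=0, le=1.0)
    seed: int = 0

    @property
    def fit_offsets_h(self) -> tuple[float, float]:
        return (self.fit_offset_start_h, self.fit_offset_end_h)


def _digest(paths) -> dict[str, str]:
    out = {}
    for p in paths:
        p = Path(p)
        if p.exists():
            out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    return out


def make_run_record(inputs, config: dict | None = None, warnings_emitted=()) -> dict:
    """Provenance record written next to every CLI result."""
    return {
        "tool": "srclock",
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "inputs_sha256": _digest(inputs),
        "config": config or {},
        "warnings": list(warnings_emitted),
    }


def write_run_record(path, record: dict) -> None:
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
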