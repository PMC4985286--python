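"""Current-trace container and its on-disk CSV format.

Traces are CSV with ``#``-prefixed metadata header lines followed by columns
``time_s, voltage_mV, current_pA`` and optionally ``po``. Metadata keys are
free-form strings; the writers record ligand, concentration, conductance and
seed so synthetic recordings are self-describing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("time_s", "voltage_mV", "current_pA")


class TraceFormatError(ValueError):
    """Malformed trace file (header, columns, or time base)."""


@dataclass
class CurrentTrace:
    """One sweep of (time, command voltage, current) with metadata."""

    time_s: np.ndarray
    voltage_mV: np.ndarray
    current_pA: np.ndarray
    po: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.voltage_mV = np.asarray(self.voltage_mV, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        n = len(self.time_s)
        if len(self.voltage_mV) != n or len(self.current_pA) != n:
            raise TraceFormatError("column lengths differ")
        if n > 1 and not np.all(np.diff(self.time_s) > 0):
            raise TraceFormatError("time base must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.time_s[1] - self.time_s[0])

    def segment(self, t_start: float, t_stop: float) -> "CurrentTrace":
        """Sub-trace on the half-open window [t_start, t_stop)."""
        m = (self.time_s >= t_start - 1e-12) & (self.time_s < t_stop - 1e-12)
        return CurrentTrace(
            time_s=self.time_s[m], voltage_mV=self.voltage_mV[m],
            current_pA=self.current_pA[m],
            po=self.po[m] if self.po is not None else None,
            meta=dict(self.meta),
        )


def write_trace(path: str | Path, trace: CurrentTrace) -> None:
    buf = io.StringIO()
    for key, val in trace.meta.items():
        buf.write(f"# {key}={val}\n")
    cols = {"time_s": trace.time_s, "voltage_mV": trace.voltage_mV,
            "current_pA": trace.current_pA}
    if trace.po is not None:
        cols["po"] = trace.po
    pd.DataFrame(cols).to_csv(buf, index=False, float_format="%.9g")
    Path(path).write_text(buf.getvalue())


def read_trace(path: str | Path) -> CurrentTrace:
    meta: dict = {}
    lines = Path(path).read_text().splitlines()
    body_start = 0
    for k, line in enumerate(lines):
        if line.startswith("#"):
            stripped = line.lstrip("# ").rstrip()
            if "=" not in stripped:
                raise TraceFormatError(f"malformed metadata line: {line!r}")
            key, _, val = stripped.partition("=")
            meta[key.strip()] = val.strip()
            body_start = k + 1
        else:
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])))
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"missing required columns: {missing}")
    return CurrentTrace(
        time_s=df["time_s"].to_numpy(),
        voltage_mV=df["voltage_mV"].to_numpy(),
        current_pA=df["current_pA"].to_numpy(),
        po=df["po"].to_numpy() if "po" in df.columns else None,
        meta=meta,
    )
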