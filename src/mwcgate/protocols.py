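"""Voltage-clamp protocol builders.

Two protocol flavours cover everything used here: piecewise-constant
segment lists (step families, two-step relaxation protocols) and sampled
arbitrary waveforms (action potentials and AP trains). All voltages are
volts internally; the constructors below take millivolts because that is
how protocols are specified at the rig.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

DEFAULT_DT = 5e-5  # 50 us sampling (20 kHz)


@dataclass
class VoltageProtocol:
    """A single sweep: either piecewise-constant segments or a sampled waveform.

    ``segments`` is a list of (duration_s, voltage_V) pairs; ``waveform`` is
    (dt_s, samples_V). Exactly one of the two is set.
    """

    segments: list[tuple[float, float]] | None = None
    waveform: tuple[float, np.ndarray] | None = None
    holding_V: float = -0.060
    name: str = ""

    def __post_init__(self) -> None:
        if (self.segments is None) == (self.waveform is None):
            raise ValueError("exactly one of segments/waveform must be given")
        if self.segments is not None:
            for dur, _v in self.segments:
                if dur < 0:
                    raise ValueError(f"segment durations must be non-negative, got {dur}")
        else:
            dt, v = self.waveform
            if dt <= 0:
                raise ValueError(f"waveform dt must be positive, got {dt}")
            v = np.asarray(v, dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError("waveform samples must be finite")
            self.waveform = (float(dt), v)

    @property
    def is_piecewise(self) -> bool:
        return self.segments is not None

    @property
    def duration(self) -> float:
        if self.segments is not None:
            return float(sum(d for d, _ in self.segments))
        dt, v = self.waveform
        return dt * len(v)

    def sample(self, dt: float = DEFAULT_DT) -> tuple[np.ndarray, np.ndarray]:
        """Render the sweep on a regular time grid; returns (t, V).

        Piecewise protocols hold each segment's voltage over its interior;
        samples at a boundary take the incoming segment's voltage.
        """
        if self.waveform is not None:
            wdt, v = self.waveform
            t = np.arange(len(v)) * wdt
            if abs(dt - wdt) < 1e-15:
                return t, v.copy()
            tq = np.arange(0.0, self.duration, dt)
            return tq, np.interp(tq, t, v)
        t = np.arange(0.0, self.duration - 1e-12, dt)
        v = np.empty_like(t)
        edges = np.cumsum([0.0] + [d for d, _ in self.segments])
        for k, (_d, volt) in enumerate(self.segments):
            v[(t >= edges[k] - 1e-12) & (t < edges[k + 1] - 1e-12)] = volt
        return t, v

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {"holding_mV": self.holding_V * 1e3, "name": self.name}
        if self.segments is not None:
            doc["segments"] = [
                {"duration_s": d, "voltage_mV": v * 1e3} for d, v in self.segments
            ]
        else:
            dt, v = self.waveform
            doc["waveform"] = {"dt_s": dt, "voltage_mV": (v * 1e3).tolist()}
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "VoltageProtocol":
        hold = doc.get("holding_mV", -60.0) / 1e3
        name = doc.get("name", "")
        if "segments" in doc:
            segs = [(s["duration_s"], s["voltage_mV"] / 1e3) for s in doc["segments"]]
            return cls(segments=segs, holding_V=hold, name=name)
        w = doc["waveform"]
        return cls(
            waveform=(w["dt_s"], np.asarray(w["voltage_mV"], dtype=float) / 1e3),
            holding_V=hold, name=name,
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "VoltageProtocol":
        return cls.from_dict(json.loads(Path(path).read_text()))


def step_family(V_hold_mV: float = -60.0, V_min_mV: float = -140.0,
                V_max_mV: float = 220.0, increment_mV: float = 20.0,
                step_duration_s: float = 0.1, tail_voltage_mV: float = -60.0,
                hold_duration_s: float = 0.02,
                tail_duration_s: float = 0.05) -> list[VoltageProtocol]:
    """Activation step family: hold -> test step -> tail, one sweep per voltage.

    Defaults reproduce a -140..+220 mV family in 20 mV increments.
    """
    if V_min_mV > V_max_mV:
        raise ValueError("V_min must not exceed V_max")
    if increment_mV <= 0:
        raise ValueError("increment must be positive")
    n = int(round((V_max_mV - V_min_mV) / increment_mV))
    if abs(V_min_mV + n * increment_mV - V_max_mV) > 1e-9:
        warnings.warn("increment does not divide the voltage range; last step clipped")
        n = int(np.floor((V_max_mV - V_min_mV) / increment_mV))
    voltages = [V_min_mV + k * increment_mV for k in range(n + 1)]
    sweeps = []
    for v in voltages:
        sweeps.append(VoltageProtocol(
            segments=[
                (hold_duration_s, V_hold_mV / 1e3),
                (step_duration_s, v / 1e3),
                (tail_duration_s, tail_voltage_mV / 1e3),
            ],
            holding_V=V_hold_mV / 1e3,
            name=f"step_{v:+.0f}mV",
        ))
    return sweeps


def relaxation_protocol(V_hold_mV: float = -60.0, V_act_mV: float = 120.0,
                        V_deact_mV: float = -80.0,
                        durations_s: tuple[float, float] = (0.1, 0.1),
                        hold_duration_s: float = 0.02) -> VoltageProtocol:
    """Two-step relaxation sweep: activate at +120 mV, deactivate at -80 mV."""
    return VoltageProtocol(
        segments=[
            (hold_duration_s, V_hold_mV / 1e3),
            (durations_s[0], V_act_mV / 1e3),
            (durations_s[1], V_deact_mV / 1e3),
        ],
        holding_V=V_hold_mV / 1e3,
        name=f"relax_{V_act_mV:+.0f}_{V_deact_mV:+.0f}mV",
    )


def ap_waveform(V_rest_mV: float = -60.0, V_peak_mV: float = 40.0,
                upstroke_ms: float = 1.0, repol_ms: float = 2.0,
                ahp_mV: float = 10.0, ahp_ms: float = 15.0,
                pre_ms: float = 5.0, post_ms: float = 20.0,
                dt: float = DEFAULT_DT) -> VoltageProtocol:
    """Stylized sensory-neuron action potential command waveform.

    Linear upstroke to ``V_peak``, linear repolarization overshooting to an
    after-hyperpolarization ``ahp_mV`` below rest, then exponential recovery
    back to rest with time constant ``ahp_ms``. The template is a command
    voltage for voltage clamp, not a membrane model.
    """
    if V_peak_mV <= V_rest_mV:
        raise ValueError("AP peak must exceed the resting potential")
    if V_peak_mV > 80.0:
        raise ValueError(f"non-physiological AP peak {V_peak_mV} mV (> +80 mV)")
    if ahp_mV < 0:
        raise ValueError("AHP depth must be non-negative")
    ms = 1e-3
    t_total = (pre_ms + upstroke_ms + repol_ms + 6 * ahp_ms + post_ms) * ms
    t = np.arange(0.0, t_total, dt)
    v = np.full_like(t, V_rest_mV)
    t0 = pre_ms * ms
    t1 = t0 + upstroke_ms * ms
    t2 = t1 + repol_ms * ms
    v_trough = V_rest_mV - ahp_mV
    up = (t >= t0) & (t < t1)
    v[up] = V_rest_mV + (V_peak_mV - V_rest_mV) * (t[up] - t0) / (upstroke_ms * ms)
    rp = (t >= t1) & (t < t2)
    v[rp] = V_peak_mV + (v_trough - V_peak_mV) * (t[rp] - t1) / (repol_ms * ms)
    rec = t >= t2
    v[rec] = V_rest_mV + (v_trough - V_rest_mV) * np.exp(-(t[rec] - t2) / (ahp_ms * ms))
    # pin the final samples to rest so trains concatenate cleanly
    v[-1] = V_rest_mV
    return VoltageProtocol(
        waveform=(dt, v * 1e-3), holding_V=V_rest_mV * 1e-3, name="ap",
    )


def ap_train(waveform: VoltageProtocol, rate_Hz: float = 8.0,
             duration_s: float = 1.0, pre_s: float = 0.1) -> VoltageProtocol:
    """Train of identical AP waveforms at fixed onsets, rest in between.

    ``pre_s`` of resting baseline precedes the train (used for holding-current
    estimation in charge analysis).
    """
    if waveform.waveform is None:
        raise ValueError("ap_train requires a sampled AP waveform")
    dt, v_ap = waveform.waveform
    period = 1.0 / rate_Hz
    if waveform.duration > period:
        raise ValueError(
            f"AP width {waveform.duration:.3f} s exceeds inter-AP period {period:.3f} s"
        )
    n_ap = int(np.floor(rate_Hz * duration_s + 1e-9))
    v_rest = waveform.holding_V
    n_total = int(round((pre_s + duration_s) / dt))
    v = np.full(n_total, v_rest)
    for k in range(n_ap):
        start = int(round((pre_s + k * period) / dt))
        v[start:start + len(v_ap)] = v_ap[:max(0, min(len(v_ap), n_total - start))]
    return VoltageProtocol(
        waveform=(dt, v), holding_V=v_rest,
        name=f"train_{rate_Hz:g}Hz_{duration_s:g}s",
    )


PRESETS = {
    "steps": lambda: step_family(),
    "relax": lambda: relaxation_protocol(),
    "ap": lambda: ap_waveform(),
    "ap-train": lambda: ap_train(ap_waveform()),
}
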