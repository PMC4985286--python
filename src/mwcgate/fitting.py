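"""Ligand-parameter estimation.

Two stages, mirroring how such recordings are analysed in practice:

1. Steady state: the concentration dependence of the activation-midpoint
   shift dV1/2(L) determines the open-state affinity Kd and the per-ligand
   energetic effect ddG (gating charge z held fixed).
2. Kinetics: with (Kd, ddG, z) pinned, a global least-squares fit of the
   full 10-state model to relaxation time courses across concentrations and
   voltages determines alpha0(0), beta0(0) and kon — three free parameters.
   koff follows from Kd*kon and the closed-state unbinding rate from
   detailed balance at every evaluation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .gating import build_generator, delta_v_half, steady_state
from .params import GateParams, LigandSpec, Mechanism, T_DEFAULT
from .simulate import _segment_propagate
from .traces import CurrentTrace


class IdentifiabilityWarning(UserWarning):
    """Data do not constrain a parameter (e.g. no saturation of the shift)."""


@dataclass
class SteadyStateFit:
    """Result of the dV1/2-vs-concentration fit."""

    Kd: float
    ddG: float
    Kd_stderr: float | None
    ddG_stderr: float | None
    z: float
    temperature: float
    residual_mV: np.ndarray
    flagged: bool = False


def fit_eq9(conc_M: np.ndarray, dV_half_mV: np.ndarray, z: float = 0.82,
            T: float = T_DEFAULT, name: str = "ligand",
            mechanism: Mechanism = Mechanism.TYPE_I) -> SteadyStateFit:
    """Least-squares fit of the activation-shift equation to a dV1/2 series.

    dV1/2 = -(RT/zF) ln[(1+L/Kd)^4 / (1+(L/Kd) e^{ddG/RT})^4], with Kd and
    ddG free and z, T fixed. Kd is searched on a log scale. A warning is
    issued when the highest concentration is below ~5x the fitted Kd: the
    shift has then not begun to saturate and (Kd, ddG) are only jointly
    constrained (their estimates should be considered approximative).
    """
    conc = np.asarray(conc_M, dtype=float)
    dv = np.asarray(dV_half_mV, dtype=float)
    if len(conc) < 4:
        raise ValueError("need >= 4 concentrations to constrain (Kd, ddG)")
    if np.allclose(dv, 0.0, atol=1e-9):
        warnings.warn("all shifts are zero: ddG = 0 and Kd is unidentifiable",
                      IdentifiabilityWarning)
        return SteadyStateFit(Kd=np.nan, ddG=0.0, Kd_stderr=None,
                              ddG_stderr=None, z=z, temperature=T,
                              residual_mV=dv.copy(), flagged=True)

    nonzero = conc[conc > 0]
    params = lmfit.Parameters()
    params.add("log10_Kd", value=float(np.log10(np.median(nonzero))),
               min=-12, max=2)
    params.add("ddG", value=-3000.0, min=-60000.0, max=60000.0)

    def resid(p):
        lig = LigandSpec(name=name, mechanism=mechanism,
                         Kd=10.0 ** p["log10_Kd"].value, ddG=p["ddG"].value,
                         kon=1.0, temperature=T)
        model = np.array([delta_v_half(lig, L, z, T) * 1e3 for L in conc])
        return model - dv

    res = lmfit.minimize(resid, params, method="leastsq")
    p = res.params
    Kd = 10.0 ** p["log10_Kd"].value
    kd_err = None
    if p["log10_Kd"].stderr:
        kd_err = Kd * np.log(10) * p["log10_Kd"].stderr
    flagged = False
    if conc.max() < 5.0 * Kd:
        warnings.warn(
            f"highest concentration ({conc.max():.3g} M) is below 5x the "
            f"fitted Kd ({Kd:.3g} M): shift not near saturation, estimates "
            "are approximative", IdentifiabilityWarning,
        )
        flagged = True
    return SteadyStateFit(
        Kd=Kd, ddG=float(p["ddG"].value), Kd_stderr=kd_err,
        ddG_stderr=p["ddG"].stderr if p["ddG"].stderr else None,
        z=z, temperature=T, residual_mV=np.asarray(res.residual),
        flagged=flagged,
    )


@dataclass
class GlobalFitResult:
    """Result of the three-parameter global kinetic fit."""

    alpha0: float
    beta0: float
    kon: float
    stderr: dict = field(default_factory=dict)
    objective: float = np.nan
    success: bool = True
    n_traces: int = 0
    n_starts: int = 0
    at_bounds: list = field(default_factory=list)
    message: str = ""


def _segments_from_trace(trace: CurrentTrace) -> list[tuple[np.ndarray, float]]:
    """Split a trace's sample times into constant-voltage runs.

    Returns (segment-local times, voltage in volts) per run; requires a
    piecewise-constant command voltage.
    """
    v = trace.voltage_mV
    edges = np.flatnonzero(np.abs(np.diff(v)) > 1e-9) + 1
    bounds = np.concatenate([[0], edges, [len(v)]])
    out = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        t_local = trace.time_s[a:b] - trace.time_s[a]
        out.append((t_local, float(v[a]) * 1e-3))
    return out


def _predict_po(gate: GateParams, ligand: LigandSpec, L: float,
                segments: list[tuple[np.ndarray, float]],
                V_hold: float) -> np.ndarray:
    """Open probability at the trace's sample times, from rest at V_hold."""
    p = steady_state(build_generator(gate, ligand, L, V_hold))
    pos = []
    for t_local, V in segments:
        Q = build_generator(gate, ligand, L, V)
        seg = _segment_propagate(Q, p, t_local)
        pos.append(seg[:, 5:].sum(axis=1))
        dur = t_local[-1] + (t_local[1] - t_local[0] if len(t_local) > 1 else 0.0)
        p = _segment_propagate(Q, p, np.array([dur]))[0]
        p = np.clip(p, 0.0, None)
        p /= p.sum()
    return np.concatenate(pos)


def global_kinetic_fit(traces: list[CurrentTrace], ligand: LigandSpec,
                       z: float = 0.82, T: float = T_DEFAULT,
                       Erev_mV: float = 0.0,
                       alpha0_seed: float = 50.0, beta0_seed: float = 500.0,
                       kon_seeds: tuple[float, ...] = (1e3, 1e4, 1e5, 1e6, 1e7),
                       ) -> GlobalFitResult:
    """Global fit of alpha0(0), beta0(0), kon to relaxation traces.

    Each trace must carry ``conc_M`` in its metadata and a
    piecewise-constant command voltage; the set should span at least three
    ligand concentrations (including control) and two voltages. Currents are
    normalized per sweep by peak |I| so a shared conductance is not a free
    parameter. Parameters are searched on a log scale; ``kon`` is
    multi-started across decades and the lowest-objective solution wins.
    """
    if len(traces) < 3:
        raise ValueError("global fit needs traces at >= 3 concentrations")
    concs = []
    prepped = []
    for tr in traces:
        if "conc_M" not in tr.meta:
            raise ValueError("each trace needs conc_M metadata")
        L = float(tr.meta["conc_M"])
        concs.append(L)
        segs = _segments_from_trace(tr)
        v_hold = segs[0][1]
        norm = np.abs(tr.current_pA).max()
        if norm == 0:
            raise ValueError("trace has zero current everywhere")
        v_volts = tr.voltage_mV * 1e-3
        prepped.append((L, segs, v_hold, tr.current_pA / norm, v_volts))
    if len(set(concs)) < 3:
        raise ValueError("global fit needs >= 3 distinct concentrations")
    voltages = {round(v * 1e3) for tr in traces for v in
                [seg[1] for seg in _segments_from_trace(tr)[1:]]}
    if len(voltages) < 2:
        warnings.warn("fewer than two test voltages: kinetics weakly constrained")

    def resid(p):
        gate = GateParams(alpha0=10.0 ** p["log10_alpha0"].value,
                          beta0=10.0 ** p["log10_beta0"].value,
                          z=z, temperature=T)
        lig = LigandSpec(name=ligand.name, mechanism=ligand.mechanism,
                         Kd=ligand.Kd, ddG=ligand.ddG,
                         kon=10.0 ** p["log10_kon"].value, temperature=T)
        out = []
        for L, segs, v_hold, i_norm, v_volts in prepped:
            po = _predict_po(gate, lig, L, segs, v_hold)
            i_model = po * (v_volts - Erev_mV * 1e-3)
            peak = np.abs(i_model).max()
            if peak == 0 or not np.isfinite(peak):
                out.append(np.full(len(i_norm), 1e3))
                continue
            out.append(i_model / peak - i_norm)
        return np.concatenate(out)

    best = None
    n_starts = 0
    for kon0 in kon_seeds:
        params = lmfit.Parameters()
        params.add("log10_alpha0", value=np.log10(alpha0_seed), min=-3, max=6)
        params.add("log10_beta0", value=np.log10(beta0_seed), min=-3, max=7)
        params.add("log10_kon", value=np.log10(kon0), min=0, max=10)
        try:
            res = lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            continue
        n_starts += 1
        obj = float(np.sum(res.residual ** 2))
        if best is None or obj < best[0]:
            best = (obj, res)
    if best is None:
        raise RuntimeError("global kinetic fit failed from every start")
    obj, res = best
    p = res.params
    alpha0 = 10.0 ** p["log10_alpha0"].value
    beta0 = 10.0 ** p["log10_beta0"].value
    kon = 10.0 ** p["log10_kon"].value
    at_bounds = [name for name in ("log10_alpha0", "log10_beta0", "log10_kon")
                 if (abs(p[name].value - p[name].min) < 1e-6
                     or abs(p[name].value - p[name].max) < 1e-6)]
    if at_bounds:
        warnings.warn(f"parameters at bounds: {at_bounds}")
    stderr = {}
    for name, val in (("alpha0", alpha0), ("beta0", beta0), ("kon", kon)):
        err = p[f"log10_{name}"].stderr
        stderr[name] = val * np.log(10) * err if err else None
    return GlobalFitResult(
        alpha0=alpha0, beta0=beta0, kon=kon, stderr=stderr, objective=obj,
        success=True, n_traces=len(traces), n_starts=n_starts,
        at_bounds=at_bounds, message=getattr(res, "message", ""),
    )
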