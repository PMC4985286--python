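"""Propagation of the 10-state model through voltage protocols.

Piecewise-constant protocols are solved exactly by spectral decomposition of
the generator within each segment (the matrix exponential as a sum of ten
exponential modes); arbitrary sampled waveforms go through a stiff ODE
integrator. A Gillespie single-channel simulator provides the stochastic
oracle against which both deterministic paths are validated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.integrate import solve_ivp

from .gating import (N_STATES, VoltageGenerator, build_generator,
                     steady_state)
from .params import N_SITES, GateParams, LigandSpec
from .protocols import DEFAULT_DT, VoltageProtocol

logger = logging.getLogger(__name__)


@dataclass
class SimResult:
    """Time course of the state distribution along one sweep.

    ``probabilities`` has shape (n_samples, 10); ``po`` is the open-tier
    mass at each sample; ``voltage`` is the command potential in volts.
    """

    time: np.ndarray
    voltage: np.ndarray
    probabilities: np.ndarray
    po: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.po is None:
            self.po = self.probabilities[:, N_SITES + 1:].sum(axis=1)


@dataclass(frozen=True)
class RecordingConfig:
    """Whole-cell current mapping: ohmic conductance, reversal at ``Erev``.

    Symmetric monovalent solutions put the reversal potential at 0 mV; all
    rectification in the current then comes from Po(V).
    """

    Gmax_nS: float = 10.0
    Erev_mV: float = 0.0

    def __post_init__(self) -> None:
        if self.Gmax_nS <= 0:
            raise ValueError(f"Gmax must be positive, got {self.Gmax_nS}")


def to_current(sim: SimResult, rec: RecordingConfig) -> np.ndarray:
    """Current in pA: I = Gmax * Po * (V - Erev) with G in nS, V in mV."""
    v_mV = sim.voltage * 1e3
    return rec.Gmax_nS * sim.po * (v_mV - rec.Erev_mV)


def _segment_propagate(Q: np.ndarray, p0: np.ndarray,
                       t: np.ndarray) -> np.ndarray:
    """Exact p(t) = p0 expm(Q t) at each requested time, via eigenmodes."""
    try:
        lam, U = np.linalg.eig(Q.T)
        Uinv = np.linalg.inv(U)
        cond = np.linalg.cond(U)
        if cond > 1e12:
            raise np.linalg.LinAlgError(f"ill-conditioned eigenbasis (cond={cond:.1e})")
        c = Uinv @ p0  # modal coordinates of the initial condition
        # p(t) = U diag(exp(lam t)) c ; lam may be complex-conjugate pairs
        et = np.exp(np.outer(t, lam))  # (n_t, 10)
        out = np.real(et * c[None, :] @ U.T)
        return out
    except np.linalg.LinAlgError as err:
        logger.warning("spectral propagation failed (%s); using dense expm", err)
        out = np.empty((len(t), N_STATES))
        for k, tk in enumerate(t):
            out[k] = p0 @ linalg.expm(Q * tk)
        return out


def propagate_piecewise(params: GateParams, ligand: LigandSpec, L: float,
                        protocol: VoltageProtocol,
                        p0: np.ndarray | None = None,
                        dt: float = DEFAULT_DT) -> SimResult:
    """Exact propagation through a piecewise-constant protocol.

    The initial condition defaults to the steady state at the holding
    potential (sweeps start from rest). Within each segment the solution is
    the matrix exponential evaluated by spectral decomposition; the state is
    continuous across segment boundaries.
    """
    if protocol.segments is None:
        raise ValueError("propagate_piecewise requires a piecewise protocol")
    if p0 is None:
        p0 = steady_state(build_generator(params, ligand, L, protocol.holding_V))
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (N_STATES,) or abs(p0.sum() - 1.0) > 1e-8 or p0.min() < -1e-12:
        raise ValueError("p0 must be a probability distribution over the 10 states")

    times, volts, probs = [], [], []
    t_offset = 0.0
    p = p0
    for dur, V in protocol.segments:
        if dur == 0:
            continue
        n = max(1, int(round(dur / dt)))
        t_local = np.arange(n) * dt
        t_local = t_local[t_local < dur - 1e-15]
        Q = build_generator(params, ligand, L, V)
        seg = _segment_propagate(Q, p, t_local)
        times.append(t_local + t_offset)
        volts.append(np.full(len(t_local), V))
        probs.append(seg)
        # advance the state to the end of the segment exactly
        p = _segment_propagate(Q, p, np.array([dur]))[0]
        p = np.clip(p, 0.0, None)
        p /= p.sum()
        t_offset += dur
    return SimResult(
        time=np.concatenate(times),
        voltage=np.concatenate(volts),
        probabilities=np.vstack(probs),
    )


def integrate_waveform(params: GateParams, ligand: LigandSpec, L: float,
                       protocol: VoltageProtocol,
                       p0: np.ndarray | None = None,
                       rtol: float = 1e-8, atol: float = 1e-10) -> SimResult:
    """ODE integration of the master equation along an arbitrary waveform.

    Sampled waveforms are linearly interpolated between samples (a
    continuous command); piecewise-constant protocols are integrated
    segment by segment with the exact discontinuity at each boundary, so
    the result agrees with :func:`propagate_piecewise` to better than 1e-6
    in open probability.
    """
    if p0 is None:
        p0 = steady_state(build_generator(params, ligand, L, protocol.holding_V))
    Q_of_V = VoltageGenerator(params, ligand, L)

    def _run(rhs, t_span, t_eval, p_init):
        sol = solve_ivp(rhs, t_span, p_init, t_eval=t_eval, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(
                f"master-equation integration failed near t={sol.t[-1]:.6f} s: "
                f"{sol.message}"
            )
        return sol

    if protocol.is_piecewise:
        dt = DEFAULT_DT
        times, volts, probs = [], [], []
        p = np.asarray(p0, dtype=float)
        t_offset = 0.0
        for dur, V in protocol.segments:
            if dur == 0:
                continue
            Q = Q_of_V(V)
            t_local = np.arange(0.0, dur - 1e-15, dt)
            sol = _run(lambda t, q: q @ Q, (0.0, dur),
                       np.append(t_local, dur), p)
            times.append(t_local + t_offset)
            volts.append(np.full(len(t_local), V))
            probs.append(sol.y.T[:-1])
            p = sol.y[:, -1]
            p = np.clip(p, 0.0, None)
            p /= p.sum()
            t_offset += dur
        t_grid = np.concatenate(times)
        v = np.concatenate(volts)
        out = np.vstack(probs)
    else:
        dt, v = protocol.waveform
        t_grid = np.arange(len(v)) * dt

        def rhs(t: float, q: np.ndarray) -> np.ndarray:
            return q @ Q_of_V(float(np.interp(t, t_grid, v)))

        sol = _run(rhs, (t_grid[0], t_grid[-1]), t_grid, p0)
        out = sol.y.T
    out = np.clip(out, 0.0, None)
    out /= out.sum(axis=1, keepdims=True)
    return SimResult(time=t_grid, voltage=np.asarray(v, dtype=float),
                     probabilities=out)


def simulate(params: GateParams, ligand: LigandSpec, L: float,
             protocol: VoltageProtocol, p0: np.ndarray | None = None,
             dt: float = DEFAULT_DT) -> SimResult:
    """Route to the exact spectral path for piecewise protocols, ODE otherwise."""
    if protocol.is_piecewise:
        return propagate_piecewise(params, ligand, L, protocol, p0, dt=dt)
    return integrate_waveform(params, ligand, L, protocol, p0)


def gillespie_single_channel(params: GateParams, ligand: LigandSpec, L: float,
                             protocol: VoltageProtocol, n_channels: int,
                             seed: int, dt: float = DEFAULT_DT,
                             return_dwells: bool = False):
    """Stochastic simulation of independent channels (piecewise protocols).

    Event-driven continuous-time Markov chain per channel; returns
    ``(t, open_counts)`` sampled on the regular grid, plus per-state dwell
    times when ``return_dwells`` is set. Serves as the brute-force oracle
    for the deterministic propagators.
    """
    if protocol.segments is None:
        raise ValueError("the stochastic oracle supports piecewise protocols only")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)

    p_hold = steady_state(build_generator(params, ligand, L, protocol.holding_V))
    segs = [(d, V) for d, V in protocol.segments if d > 0]
    Qs = [build_generator(params, ligand, L, V) for _, V in segs]
    # per-segment exit rates and jump distributions
    exits = [-np.diag(Q) for Q in Qs]
    jumps = []
    for Q, ex in zip(Qs, exits):
        P = Q.copy()
        np.fill_diagonal(P, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            P = np.where(ex[:, None] > 0, P / np.where(ex[:, None] > 0, ex[:, None], 1.0), 0.0)
        jumps.append(np.cumsum(P, axis=1))
    edges = np.cumsum([0.0] + [d for d, _ in segs])
    t_grid = np.arange(0.0, edges[-1] - 1e-15, dt)
    open_counts = np.zeros(len(t_grid), dtype=np.int64)
    dwells: dict[int, list[float]] = {s: [] for s in range(N_STATES)}

    init_states = rng.choice(N_STATES, size=n_channels, p=p_hold)
    for ch in range(n_channels):
        s = int(init_states[ch])
        t = 0.0
        grid_pos = 0
        for k, (dur, _V) in enumerate(segs):
            t_end = edges[k + 1]
            ex, Pc = exits[k], jumps[k]
            while t < t_end:
                rate = ex[s]
                t_next = t + rng.exponential(1.0 / rate) if rate > 0 else t_end
                t_leave = min(t_next, t_end)
                # record occupancy on grid samples falling in [t, t_leave)
                while grid_pos < len(t_grid) and t_grid[grid_pos] < t_leave - 1e-15:
                    if s > N_SITES:
                        open_counts[grid_pos] += 1
                    grid_pos += 1
                if t_next >= t_end:
                    t = t_end
                    break
                if return_dwells:
                    dwells[s].append(t_next - t)
                u = rng.random()
                s = int(np.searchsorted(Pc[s], u * Pc[s, -1], side="right"))
                t = t_next
    if return_dwells:
        return t_grid, open_counts, dwells
    return t_grid, open_counts
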