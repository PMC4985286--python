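"""Descriptive trace analysis: relaxation fits, G-V curves, Boltzmann fits.

These are the standard voltage-clamp summary statistics: current
relaxations after a voltage step are reduced to one or two exponential time
constants; steady-state currents from a step family become a
conductance-voltage curve whose midpoint shift under agonist quantifies the
energetic effect of binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy import stats

from .params import FARADAY, GAS_CONSTANT, T_DEFAULT
from .traces import CurrentTrace

#: dead time blanked after each voltage edge (settling; no capacitance model)
DEFAULT_BLANK_S = 2e-4


@dataclass
class ExpFit:
    """Sum-of-exponentials fit to one relaxation segment.

    ``tau_s`` sorted ascending for two components (tau_fast first).
    ``offset`` is the asymptotic current; amplitudes pair with ``tau_s``.
    """

    n_components: int
    amplitudes: np.ndarray
    tau_s: np.ndarray
    offset: float
    rss: float
    n_points: int
    success: bool = True

    def __post_init__(self) -> None:
        order = np.argsort(self.tau_s)
        self.tau_s = np.asarray(self.tau_s, dtype=float)[order]
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)[order]

    @property
    def n_params(self) -> int:
        return 1 + 2 * self.n_components

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        y = np.full_like(t, self.offset)
        for A, tau in zip(self.amplitudes, self.tau_s):
            y = y + A * np.exp(-t / tau)
        return y


@dataclass
class BoltzmannFit:
    """Two-state Boltzmann fit of a conductance-voltage curve."""

    Gmax: float
    V_half_mV: float
    z: float
    rss: float = 0.0
    stderr: dict = field(default_factory=dict)

    def predict(self, V_mV: np.ndarray) -> np.ndarray:
        V = np.asarray(V_mV, dtype=float) * 1e-3
        x = self.z * FARADAY * (V - self.V_half_mV * 1e-3) / (GAS_CONSTANT * T_DEFAULT)
        return self.Gmax / (1.0 + np.exp(-x))


@dataclass
class GVCurve:
    """Steady-state conductance per test voltage, G = I_ss / V."""

    voltage_mV: np.ndarray
    conductance_nS: np.ndarray
    normalized: np.ndarray | None = None


def _exp_model(t: np.ndarray, params: lmfit.Parameters, n: int) -> np.ndarray:
    y = np.full_like(t, params["offset"].value, dtype=float)
    for k in range(n):
        y = y + params[f"A{k}"] * np.exp(-t / params[f"tau{k}"])
    return y


def _seed_tau(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Log-linear initializer: offset from the tail, tau/A from a regression."""
    offset = float(np.mean(y[max(1, int(0.9 * len(y))):]))
    resid = y - offset
    sign = 1.0 if resid[0] >= 0 else -1.0
    mag = sign * resid
    mask = mag > max(1e-3 * np.abs(mag).max(), 1e-30)
    if mask.sum() < 3:
        return offset, float(resid[0]), (t[-1] - t[0]) / 3
    slope, intercept = np.polyfit(t[mask], np.log(mag[mask]), 1)
    tau = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3
    A = sign * np.exp(intercept)
    return offset, float(A), float(max(tau, (t[1] - t[0])))


def fit_exponentials(trace: CurrentTrace, n_components: int = 1,
                     blank_s: float = DEFAULT_BLANK_S,
                     use_po: bool = False) -> ExpFit:
    """Least-squares mono- or bi-exponential fit to a relaxation segment.

    The trace must start at the voltage-step edge; the first ``blank_s``
    seconds are excluded (settling). Deterministic: a log-linear initializer
    seeds tau, two fixed multiplicative spreads provide restarts, and the
    lowest-RSS solution wins.
    """
    if n_components not in (1, 2):
        raise ValueError("n_components must be 1 or 2")
    y_full = trace.po if use_po else trace.current_pA
    t0 = trace.time_s[0]
    m = trace.time_s - t0 >= blank_s - 1e-12
    t = trace.time_s[m] - t0
    y = np.asarray(y_full, dtype=float)[m]
    if len(t) < 10 * n_components:
        raise ValueError(
            f"need >= {10 * n_components} points for {n_components} components, "
            f"got {len(t)}"
        )
    offset0, A0, tau0 = _seed_tau(t, y)
    scale = max(np.abs(y).max(), 1e-30)

    best = None
    for spread in (1.0, 0.3, 3.0):  # fixed restarts, lowest RSS wins
        params = lmfit.Parameters()
        params.add("offset", value=offset0)
        if n_components == 1:
            params.add("A0", value=A0)
            params.add("tau0", value=tau0 * spread, min=1e-7)
        else:
            params.add("A0", value=A0 / 2)
            params.add("A1", value=A0 / 2)
            params.add("tau0", value=tau0 * spread / 3, min=1e-7)
            params.add("tau1", value=tau0 * spread * 3, min=1e-7)

        def resid(p):
            return (_exp_model(t, p, n_components) - y) / scale

        try:
            res = lmfit.minimize(resid, params, method="leastsq")
        except Exception:
            continue
        rss = float(np.sum((_exp_model(t, res.params, n_components) - y) ** 2))
        if best is None or rss < best[0]:
            best = (rss, res)
    if best is None:
        raise RuntimeError(
            "exponential fit failed to converge "
            f"(initializer: offset={offset0:.3g}, A={A0:.3g}, tau={tau0:.3g})"
        )
    rss, res = best
    p = res.params
    amps = np.array([p[f"A{k}"].value for k in range(n_components)])
    taus = np.array([p[f"tau{k}"].value for k in range(n_components)])
    return ExpFit(n_components=n_components, amplitudes=amps, tau_s=taus,
                  offset=float(p["offset"].value), rss=rss, n_points=len(t),
                  success=True)


def select_n_components(fit1: ExpFit, fit2: ExpFit, alpha: float = 0.01,
                        min_rel_amplitude: float = 0.02) -> int:
    """Choose 1 or 2 exponentials by an extra-sum-of-squares F-test.

    Returns 2 only if the bi-exponential fit is significantly better at
    ``alpha`` AND its minor amplitude exceeds ``min_rel_amplitude`` of the
    major one (guards against degenerate equal-tau solutions).
    """
    if fit1.n_components != 1 or fit2.n_components != 2:
        raise ValueError("expects a mono fit and a bi fit on the same data")
    if fit1.n_points != fit2.n_points:
        raise ValueError("fits must share the same data")
    n = fit1.n_points
    df1, df2 = n - fit1.n_params, n - fit2.n_params
    # essentially-perfect mono fit: nothing left for a second component
    scale = max(abs(fit1.offset), float(np.abs(fit1.amplitudes).max()), 1e-30)
    if fit1.rss <= (1e-8 * scale) ** 2 * n:
        return 1
    if fit2.rss >= fit1.rss:
        return 1
    F = ((fit1.rss - fit2.rss) / (df1 - df2)) / (fit2.rss / df2)
    p = stats.f.sf(F, df1 - df2, df2)
    a_minor = np.abs(fit2.amplitudes).min()
    a_major = np.abs(fit2.amplitudes).max()
    if p < alpha and a_minor > min_rel_amplitude * a_major:
        return 2
    return 1


def gv_from_steps(traces: list[CurrentTrace], test_window: tuple[float, float] | None = None,
                  v_exclude_mV: float = 10.0, ss_fraction: float = 0.1,
                  drift_tol: float = 0.05) -> GVCurve:
    """Conductance-voltage curve from a family of activation-step sweeps.

    The steady-state current is the mean over the last ``ss_fraction`` of the
    test step; G(V) = I_ss / V. Test voltages with |V| below
    ``v_exclude_mV`` are excluded (division blows up the noise). A relative
    drift above ``drift_tol`` across the averaging window flags a sweep as
    not at steady state.
    """
    volts, conds = [], []
    for tr in traces:
        if test_window is not None:
            seg = tr.segment(*test_window)
        else:
            seg = _test_segment(tr)
        V = float(np.median(seg.voltage_mV))
        if abs(V) < v_exclude_mV:
            continue
        n = len(seg.time_s)
        tail = seg.current_pA[int((1 - ss_fraction) * n):]
        i_ss = float(tail.mean())
        half = len(tail) // 2
        if half >= 2 and abs(i_ss) > 0:
            drift = abs(tail[half:].mean() - tail[:half].mean()) / max(abs(i_ss), 1e-30)
            if drift > drift_tol:
                warnings.warn(
                    f"sweep at {V:+.0f} mV not at steady state "
                    f"(relative drift {drift:.1%})"
                )
        volts.append(V)
        conds.append(i_ss / V)  # pA / mV = nS
    order = np.argsort(volts)
    return GVCurve(voltage_mV=np.asarray(volts)[order],
                   conductance_nS=np.asarray(conds)[order])


def _test_segment(tr: CurrentTrace) -> CurrentTrace:
    """Middle segment of a hold-step-tail sweep, located from voltage edges."""
    v = tr.voltage_mV
    changes = np.flatnonzero(np.abs(np.diff(v)) > 1e-9) + 1
    if len(changes) == 0:
        # test voltage equals holding (and tail): the whole sweep is the step
        a, b = 0, len(v)
    elif len(changes) == 1:
        a, b = changes[0], len(v)
    else:
        a, b = changes[0], changes[1]
    return CurrentTrace(
        time_s=tr.time_s[a:b],
        voltage_mV=v[a:b],
        current_pA=tr.current_pA[a:b],
        po=tr.po[a:b] if tr.po is not None else None,
        meta=dict(tr.meta),
    )


def fit_boltzmann(gv: GVCurve, z0: float = 0.82) -> BoltzmannFit:
    """Fit G(V) = Gmax / (1 + exp(-zF(V - V1/2)/RT)).

    The slope is parameterized by the equivalent gating charge ``z`` so the
    fit shares units with the kinetic model.
    """
    V = gv.voltage_mV
    G = gv.conductance_nS
    if len(V) < 5:
        raise ValueError("need >= 5 voltages spanning the inflection")
    params = lmfit.Parameters()
    params.add("Gmax", value=float(G.max()), min=1e-12)
    params.add("V_half_mV", value=float(V[np.argmin(np.abs(G - G.max() / 2))]))
    params.add("z", value=z0, min=0.05, max=5.0)

    def resid(p):
        x = (p["z"] * FARADAY * (V - p["V_half_mV"]) * 1e-3
             / (GAS_CONSTANT * T_DEFAULT))
        return p["Gmax"] / (1.0 + np.exp(-x)) - G

    res = lmfit.minimize(resid, params, method="leastsq")
    if not res.success:
        raise RuntimeError("Boltzmann fit did not converge")
    p = res.params
    fit = BoltzmannFit(
        Gmax=float(p["Gmax"].value), V_half_mV=float(p["V_half_mV"].value),
        z=float(p["z"].value), rss=float(np.sum(res.residual ** 2)),
        stderr={k: (p[k].stderr if p[k].stderr else np.nan) for k in p},
    )
    if not (V.min() <= fit.V_half_mV <= V.max()):
        warnings.warn(
            f"fitted V1/2 = {fit.V_half_mV:+.1f} mV lies outside the sampled "
            f"voltage range [{V.min():+.0f}, {V.max():+.0f}] mV"
        )
    return fit


def delta_v12_series(control: BoltzmannFit,
                     liganded: list[tuple[float, BoltzmannFit]]) -> pd.DataFrame:
    """Concentration dependence of the activation-midpoint shift.

    Returns a DataFrame with columns ``conc_M`` and ``dV_half_mV`` where
    dV1/2 = V1/2(L) - V1/2(control).
    """
    rows = [{"conc_M": L, "dV_half_mV": bf.V_half_mV - control.V_half_mV}
            for L, bf in liganded]
    return pd.DataFrame(rows).sort_values("conc_M").reset_index(drop=True)
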