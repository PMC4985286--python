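"""Operational Type I / Type II agonist classification and AP charge flux.

A Type I agonist (menthol-like) stabilizes the open state: deactivation
slows with concentration and tail relaxations become bi-exponential. A
Type II agonist (AITC-like) destabilizes the closed state: activation
accelerates while deactivation is untouched and relaxations stay
mono-exponential. These kinetic signatures — not the steady state, which is
mechanism-blind — are what distinguish the two classes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gating import open_probability_closed_form
from .params import GateParams, LigandSpec
from .protocols import VoltageProtocol
from .simulate import SimResult, simulate
from .traces import CurrentTrace


class AgonistLabel(str, Enum):
    TYPE_I = "TYPE_I"
    TYPE_II = "TYPE_II"
    INDETERMINATE = "INDETERMINATE"


@dataclass
class AgonistCall:
    """Classification verdict with the evidence it rests on."""

    label: AgonistLabel
    evidence: dict = field(default_factory=dict)


def classify_agonist(tau_table: pd.DataFrame,
                     spearman_threshold: float = -0.8,
                     deact_stability: float = 0.20) -> AgonistCall:
    """Classify an agonist from relaxation time constants vs concentration.

    ``tau_table`` needs columns ``conc_M``, ``tau_act_s`` (activation at
    +120 mV), ``tau_deact_s`` (deactivation at -80 mV) and boolean
    ``bi_deact`` (tail needed a second exponential). TYPE_II requires a
    strong monotone acceleration of activation (Spearman <= -0.8), a stable
    deactivation tau (relative change < 20%) and mono-exponential tails
    throughout; TYPE_I requires tail slowing plus bi-exponentiality.
    Conflicting or insufficient evidence yields INDETERMINATE.
    """
    required = {"conc_M", "tau_act_s", "tau_deact_s"}
    if not required <= set(tau_table.columns):
        raise ValueError(f"tau_table needs columns {sorted(required)}")
    df = tau_table.sort_values("conc_M").reset_index(drop=True)
    evidence: dict = {"n_concentrations": len(df)}
    if len(df) < 3:
        evidence["reason"] = "fewer than 3 concentrations"
        return AgonistCall(AgonistLabel.INDETERMINATE, evidence)

    rho_act = stats.spearmanr(df["conc_M"], df["tau_act_s"]).statistic
    tau_d0 = df["tau_deact_s"].iloc[0]
    tau_dmax = df["tau_deact_s"].iloc[-1]
    rel_deact = (tau_dmax - tau_d0) / tau_d0
    bi_deact = bool(df["bi_deact"].any()) if "bi_deact" in df.columns else False
    evidence.update(
        spearman_tau_act=float(rho_act),
        rel_change_tau_deact=float(rel_deact),
        any_bi_exponential_tail=bi_deact,
    )
    type_ii = (rho_act <= spearman_threshold
               and abs(rel_deact) < deact_stability and not bi_deact)
    type_i = rel_deact > deact_stability and bi_deact
    if type_ii and not type_i:
        return AgonistCall(AgonistLabel.TYPE_II, evidence)
    if type_i and not type_ii:
        return AgonistCall(AgonistLabel.TYPE_I, evidence)
    evidence["reason"] = "conflicting or insufficient kinetic signatures"
    return AgonistCall(AgonistLabel.INDETERMINATE, evidence)


def tau_table_from_traces(traces: list[CurrentTrace],
                          material_amplitude: float = 0.10) -> pd.DataFrame:
    """Relaxation time-constant table for :func:`classify_agonist`.

    Each trace must carry ``conc_M`` metadata and a hold/activation/
    deactivation piecewise command. Mono-exponential taus are fitted to the
    activation and deactivation segments; a tail counts as materially
    bi-exponential only when the second component both survives the F-test
    and carries at least ``material_amplitude`` of the major amplitude —
    any 10-state model produces tiny extra components (re-openings,
    binding relaxation) that do not distinguish the agonist classes.
    """
    from .analysis import fit_exponentials, select_n_components
    from .fitting import _segments_from_trace

    rows = []
    for tr in traces:
        if "conc_M" not in tr.meta:
            raise ValueError("each trace needs conc_M metadata")
        segs = _segments_from_trace(tr)
        if len(segs) < 3:
            raise ValueError("expected a hold/activation/deactivation sweep")
        bounds = np.cumsum([0.0] + [s[0][-1] + (s[0][1] - s[0][0]) for s in segs])
        t0 = tr.time_s[0]
        act = tr.segment(t0 + bounds[1], t0 + bounds[2])
        deact = tr.segment(t0 + bounds[2], t0 + bounds[3])
        fa = fit_exponentials(act, 1)
        fd1 = fit_exponentials(deact, 1)
        fd2 = fit_exponentials(deact, 2)
        bi = select_n_components(fd1, fd2,
                                 min_rel_amplitude=material_amplitude) == 2
        rows.append({
            "conc_M": float(tr.meta["conc_M"]),
            "tau_act_s": float(fa.tau_s[0]),
            "tau_deact_s": float(fd1.tau_s[0]),
            "bi_deact": bi,
        })
    return pd.DataFrame(rows).sort_values("conc_M").reset_index(drop=True)


@dataclass
class PhiEstimate:
    phi: float
    stderr: float | None
    n_points: int


def phi_from_fits(log_alpha: np.ndarray, log_keq: np.ndarray) -> PhiEstimate:
    """REFER slope from (log alpha, log K_eq) pairs of a perturbation family.

    phi = 1: the perturbation acts entirely through the opening rate (early
    movement); phi = 0: entirely through closing (late movement).
    """
    la = np.asarray(log_alpha, dtype=float)
    lk = np.asarray(log_keq, dtype=float)
    if len(la) < 2:
        raise ValueError("need >= 2 points for a slope")
    if np.ptp(lk) < 1e-12:
        raise ValueError("degenerate K_eq spread: slope undefined")
    if len(la) == 2:
        slope = (la[1] - la[0]) / (lk[1] - lk[0])
        return PhiEstimate(phi=float(slope), stderr=None, n_points=2)
    res = stats.linregress(lk, la)
    return PhiEstimate(phi=float(res.slope), stderr=float(res.stderr),
                       n_points=len(la))


def equipotent_concentration(params: GateParams, ligand_a: LigandSpec,
                             ligand_b: LigandSpec, conc_a: float,
                             V: float, tol: float = 1e-6) -> float:
    """Concentration of ligand B matching ligand A's steady-state Po at V.

    Root-found on the closed-form open probability; raises if B cannot reach
    the target even at saturation.
    """
    if conc_a < 0:
        raise ValueError("concentration must be non-negative")
    if conc_a == 0:
        return 0.0
    target = open_probability_closed_form(params, ligand_a, conc_a, V)
    po0 = open_probability_closed_form(params, ligand_b, 0.0, V)
    # saturating Po of B: each of 4 bound ligands multiplies Keq by e^{-ddG/RT}
    k0 = po0 / (1.0 - po0)
    k_inf = k0 * math.exp(-4.0 * ligand_b.ddG / ligand_b.RT)
    po_max = k_inf / (1.0 + k_inf)
    if target > po_max - 1e-15:
        raise ValueError(
            f"target Po {target:.4f} unreachable: ligand {ligand_b.name} "
            f"saturates at Po {po_max:.4f}"
        )
    if abs(target - po0) < tol:
        return 0.0

    def f(log_conc: float) -> float:
        return open_probability_closed_form(params, ligand_b, 10 ** log_conc, V) - target

    lo, hi = -15.0, 2.0
    sol = optimize.brentq(f, lo, hi, xtol=1e-13)
    conc_b = 10 ** sol
    if abs(open_probability_closed_form(params, ligand_b, conc_b, V) - target) > tol:
        raise RuntimeError("bisection did not reach the requested tolerance")
    return conc_b


def combined_ligand_sim(params: GateParams, menthol_spec: LigandSpec,
                        L_menthol: float, aitc_ddG_effect: float,
                        protocol: VoltageProtocol) -> SimResult:
    """Type I + Type II co-application via the scalar opening-rate shortcut.

    The Type II component is folded into the unliganded opening rate as a
    fixed decrease of the closed-to-transition-state barrier:
    alpha0 -> alpha0 * exp(-effect/RT), beta0 unchanged; the Type I ligand
    keeps its full 10-state treatment. The full 50-state two-ligand lattice
    is deliberately not modelled.
    """
    if aitc_ddG_effect > 0:
        raise ValueError("the Type II barrier effect must be <= 0 (J/mol)")
    scaled = GateParams(
        alpha0=params.alpha0 * math.exp(-aitc_ddG_effect / params.RT),
        beta0=params.beta0, z=params.z, temperature=params.temperature,
    )
    return simulate(scaled, menthol_spec, L_menthol, protocol)


@dataclass
class ChargeMetrics:
    """Inward/outward charge displacement, baseline subtracted (magnitudes)."""

    q_in_pC: float
    q_out_pC: float
    I_hold_pA: float
    cumulative_in_pC: np.ndarray | None = None
    cumulative_out_pC: np.ndarray | None = None

    @property
    def net_pC(self) -> float:
        """Net charge (outward positive)."""
        return self.q_out_pC - self.q_in_pC


def ap_peak_ratio(trace: CurrentTrace) -> float:
    """Peak-inward to peak-outward current ratio during a single AP.

    Uses absolute currents (as peak currents are read off a sweep), not
    baseline-subtracted ones. Type I agonists give larger ratios than
    Type II at equipotent concentrations: slow deactivation sustains the
    inward tail while slow activation limits the outward spike.
    """
    i = trace.current_pA
    if i.max() <= 0:
        raise ValueError("no outward current in trace")
    return float(-i.min() / i.max())


def ap_charge(trace: CurrentTrace, I_hold: float | None = None,
              baseline_s: float = 0.1) -> ChargeMetrics:
    """Charge displacement during an AP train, after holding-current subtraction.

    Q_out integrates the positive part of (I - I_hold), Q_in the magnitude
    of the negative part, both trapezoidal on the recorded grid. The holding
    current defaults to the mean over the pre-train baseline window.
    """
    t, i = trace.time_s, trace.current_pA
    if I_hold is None:
        m = t < t[0] + baseline_s
        if (t[m][-1] - t[0]) < 0.05 - 1e-9:
            warnings.warn("baseline window shorter than 50 ms; holding-current "
                          "estimate may be poor")
        I_hold = float(i[m].mean())
    di = i - I_hold
    pos = np.clip(di, 0.0, None)
    neg = np.clip(di, None, 0.0)
    # pA * s = pC
    cum_out = np.concatenate([[0.0], np.cumsum((pos[1:] + pos[:-1]) / 2 * np.diff(t))])
    cum_in = -np.concatenate([[0.0], np.cumsum((neg[1:] + neg[:-1]) / 2 * np.diff(t))])
    return ChargeMetrics(
        q_in_pC=float(cum_in[-1]), q_out_pC=float(cum_out[-1]),
        I_hold_pA=float(I_hold),
        cumulative_in_pC=cum_in, cumulative_out_pC=cum_out,
    )
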