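"""The 10-state voltage-dependent MWC gating scheme.

States are arranged on a 2x5 lattice: a closed tier C0..C4 and an open tier
O0..O4, where the index counts bound agonist molecules (0..4 of four
identical, independent sites). Vertical edges are the concerted gating
transition (voltage dependent); horizontal edges are ligand binding and
unbinding. The closed-state unbinding rate is fixed by detailed balance, so
every elementary square in the lattice is a thermodynamically closed cycle.

Rate laws
---------
Unliganded gating (gating charge z split symmetrically across the barrier):

    alpha0(V) = alpha0(0) * exp(+0.5 z F V / RT)
    beta0(V)  = beta0(0)  * exp(-0.5 z F V / RT)

With i bound agonists, each contributing ddG (< 0 for an agonist) to the
closed<->open free-energy difference:

    Type I  (open-state stabilization):   alpha_i = alpha0(V)
                                          beta_i  = beta0(V) * exp(i*ddG/RT)
    Type II (closed-state destabilization): alpha_i = alpha0(V) * exp(-i*ddG/RT)
                                            beta_i  = beta0(V)

Either way the equilibrium constant K_i = alpha_i/beta_i = K_0 * exp(-i*ddG/RT):
equilibrium is mechanism independent; only the kinetics differ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .params import FARADAY, N_SITES, GateParams, LigandSpec, Mechanism

N_STATES = 2 * (N_SITES + 1)

#: State labels in index order: closed tier then open tier.
STATE_LABELS: tuple[str, ...] = tuple(
    f"C{i}" for i in range(N_SITES + 1)
) + tuple(f"O{i}" for i in range(N_SITES + 1))


def state_index(conformation: str, i: int) -> int:
    """Map (conformation, bound count) -> flat state index.

    ``conformation`` is ``"C"`` or ``"O"``; ``i`` counts bound ligands (0..4).
    """
    if conformation not in ("C", "O"):
        raise ValueError(f"conformation must be 'C' or 'O', got {conformation!r}")
    if not 0 <= i <= N_SITES:
        raise ValueError(f"bound count must be in 0..{N_SITES}, got {i}")
    return i if conformation == "C" else N_SITES + 1 + i


def voltage_rates(params: GateParams, V: float) -> tuple[float, float]:
    """Unliganded opening and closing rates at membrane potential ``V`` (volts).

    Returns ``(alpha0(V), beta0(V))`` in s^-1. The product
    alpha0(V)*beta0(V) is voltage independent because the charge is split
    symmetrically between the two rates.
    """
    if not math.isfinite(V):
        raise ValueError(f"membrane potential must be finite, got {V}")
    x = 0.5 * params.z * FARADAY * V / params.RT
    return params.alpha0 * math.exp(x), params.beta0 * math.exp(-x)


def liganded_rates(params: GateParams, ligand: LigandSpec, i: int,
                   V: float) -> tuple[float, float]:
    """Opening/closing rates ``(alpha_i(V), beta_i(V))`` with ``i`` bound ligands."""
    if not 0 <= i <= N_SITES:
        raise ValueError(f"bound count must be in 0..{N_SITES}, got {i}")
    a, b = voltage_rates(params, V)
    if i == 0:
        return a, b
    shift = math.exp(i * ligand.ddG / ligand.RT)
    if ligand.mechanism is Mechanism.TYPE_I:
        return a, b * shift          # agonist (ddG<0): closing slows
    return a / shift, b              # agonist (ddG<0): opening accelerates


def binding_rates(ligand: LigandSpec, conformation: str, i: int,
                  L: float) -> tuple[float, float]:
    """Aggregate binding kinetics at occupancy ``i`` and concentration ``L`` (M).

    Four identical independent sites lump into forward rate ``(4-i)*kon*L``
    and backward rate ``i*koff`` with the conformation's unbinding rate.
    Returns ``(forward i->i+1, backward i->i-1)`` in s^-1.
    """
    if L < 0:
        raise ValueError(f"concentration must be non-negative, got {L}")
    if conformation not in ("C", "O"):
        raise ValueError(f"conformation must be 'C' or 'O', got {conformation!r}")
    if not 0 <= i <= N_SITES:
        raise ValueError(f"bound count must be in 0..{N_SITES}, got {i}")
    koff = ligand.koff_open if conformation == "O" else ligand.koff_closed
    forward = (N_SITES - i) * ligand.kon * L if i < N_SITES else 0.0
    backward = i * koff if i > 0 else 0.0
    return forward, backward


def build_generator(params: GateParams, ligand: LigandSpec, L: float,
                    V: float) -> np.ndarray:
    """Assemble the 10x10 generator matrix at fixed (V, L).

    Convention: ``Q[i, j]`` is the rate from state i to state j (i != j);
    the diagonal makes every row sum to zero. Only nearest-neighbour edges
    of the 2x5 lattice are populated.
    """
    Q = np.zeros((N_STATES, N_STATES))
    for i in range(N_SITES + 1):
        ci, oi = state_index("C", i), state_index("O", i)
        a, b = liganded_rates(params, ligand, i, V)
        Q[ci, oi] = a
        Q[oi, ci] = b
        for conf, idx in (("C", ci), ("O", oi)):
            fwd, bwd = binding_rates(ligand, conf, i, L)
            if i < N_SITES:
                Q[idx, state_index(conf, i + 1)] = fwd
            if i > 0:
                Q[idx, state_index(conf, i - 1)] = bwd
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


class VoltageGenerator:
    """Generator matrix as a cached function of voltage at fixed (ligand, L).

    The voltage enters every gating edge through the same factor
    e^{+-0.5zFV/RT}, so Q(V) decomposes into a constant binding part plus
    two voltage-scaled gating parts. Rebuilding from the cached parts is an
    order of magnitude cheaper than reassembling rate by rate — this is the
    hot path of ODE integration over arbitrary waveforms.
    """

    def __init__(self, params: GateParams, ligand: LigandSpec, L: float):
        self.params = params
        self.ligand = ligand
        self.L = L
        base = build_generator(params, ligand, L, 0.0)
        self._QA = np.zeros_like(base)   # opening edges at V=0
        self._QB = np.zeros_like(base)   # closing edges at V=0
        for i in range(N_SITES + 1):
            ci, oi = state_index("C", i), state_index("O", i)
            a, b = liganded_rates(params, ligand, i, 0.0)
            self._QA[ci, oi] = a
            self._QA[ci, ci] = -a
            self._QB[oi, ci] = b
            self._QB[oi, oi] = -b
        self._Qbind = base - self._QA - self._QB
        self._scale = 0.5 * params.z * FARADAY / params.RT

    def __call__(self, V: float) -> np.ndarray:
        x = math.exp(self._scale * V)
        return self._Qbind + x * self._QA + (1.0 / x) * self._QB


def steady_state(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator matrix (row convention).

    Solves the null space of Q^T and normalizes. Raises if the null space
    is not one-dimensional (degenerate/reducible generator).
    """
    ns = linalg.null_space(Q.T, rcond=1e-10)
    if ns.shape[1] != 1:
        raise np.linalg.LinAlgError(
            f"generator null space has dimension {ns.shape[1]}, expected 1"
        )
    p = ns[:, 0]
    p = p / p.sum()
    # tiny negative round-off is clipped; anything larger is a real failure
    if p.min() < -1e-9:
        raise np.linalg.LinAlgError("stationary vector has negative mass")
    p = np.clip(p, 0.0, None)
    return p / p.sum()


def open_probability_closed_form(params: GateParams, ligand: LigandSpec,
                                 L: float, V: float) -> float:
    """Equilibrium open probability from the MWC partition functions.

    Po = Z_O / (Z_O + Z_C) with Z_O = K0(V)*(1+L/Kd_O)^4 and
    Z_C = (1+L/Kd_C)^4, where Kd_O is the open-state affinity and
    Kd_C = Kd_O*exp(-ddG/RT). Identical for Type I and Type II ligands.
    """
    if L < 0:
        raise ValueError(f"concentration must be non-negative, got {L}")
    a, b = voltage_rates(params, V)
    K0 = a / b
    zo = K0 * (1.0 + L / ligand.Kd) ** N_SITES
    zc = (1.0 + (L / ligand.Kd) * math.exp(ligand.ddG / ligand.RT)) ** N_SITES
    return zo / (zo + zc)


def occupancy_distribution(ligand: LigandSpec, conformation: str,
                           L: float) -> np.ndarray:
    """Binomial occupancy distribution over 0..4 bound ligands within a tier."""
    Kd = ligand.Kd if conformation == "O" else ligand.Kd_closed
    p_bound = L / (L + Kd) if L > 0 else 0.0
    i = np.arange(N_SITES + 1)
    from scipy.stats import binom
    return binom.pmf(i, N_SITES, p_bound)


def delta_v_half(ligand: LigandSpec, L: float, z: float,
                 T: float | None = None) -> float:
    """Agonist-induced shift of the half-activation voltage (volts).

    dV1/2 = -(RT/zF) * ln[ (1+L/Kd)^4 / (1+(L/Kd)*exp(ddG/RT))^4 ].
    Zero at L=0, monotonically decreasing in L for an agonist, saturating
    at 4*ddG/(zF) as L -> infinity.
    """
    if L < 0:
        raise ValueError(f"concentration must be non-negative, got {L}")
    from .params import GAS_CONSTANT
    RT = GAS_CONSTANT * (ligand.temperature if T is None else T)
    x = L / ligand.Kd
    num = (1.0 + x) ** N_SITES
    den = (1.0 + x * math.exp(ligand.ddG / RT)) ** N_SITES
    return -(RT / (z * FARADAY)) * math.log(num / den)


def phi_value(params: GateParams, ligand: LigandSpec, V: float = 0.0) -> float:
    """REFER slope: d(log alpha_i) / d(log K_i) across occupancies i=0..4.

    phi = 1 means the ligand's energetic effect lands entirely on the
    opening rate (early movement of its binding site in the gating
    trajectory); phi = 0 means entirely on the closing rate (late movement).
    Voltage independent for this model.
    """
    if ligand.ddG == 0:
        raise ValueError("phi is undefined for ddG = 0 (no equilibrium perturbation)")
    log_a, log_k = [], []
    for i in range(N_SITES + 1):
        a, b = liganded_rates(params, ligand, i, V)
        log_a.append(math.log(a))
        log_k.append(math.log(a / b))
    slope = np.polyfit(log_k, log_a, 1)[0]
    return float(slope)


@dataclass(frozen=True)
class CycleCheck:
    """Detailed-balance diagnostics for one elementary square of the lattice."""
    i: int
    forward_product: float
    backward_product: float

    @property
    def ratio(self) -> float:
        return self.forward_product / self.backward_product


def detailed_balance_cycles(params: GateParams, ligand: LigandSpec, L: float,
                            V: float) -> list[CycleCheck]:
    """Cycle products around each square (C_i, C_i+1, O_i+1, O_i).

    With koff_closed fixed by detailed balance every ratio is 1; exposed as
    a diagnostic so tests and fits can assert thermodynamic consistency.
    """
    Q = build_generator(params, ligand, L if L > 0 else 1.0, V)
    checks = []
    for i in range(N_SITES):
        ci, cj = state_index("C", i), state_index("C", i + 1)
        oi, oj = state_index("O", i), state_index("O", i + 1)
        fwd = Q[ci, cj] * Q[cj, oj] * Q[oj, oi] * Q[oi, ci]
        bwd = Q[ci, oi] * Q[oi, oj] * Q[oj, cj] * Q[cj, ci]
        checks.append(CycleCheck(i=i, forward_product=fwd, backward_product=bwd))
    return checks


def open_mass(p: np.ndarray) -> float:
    """Total probability in the open tier of a 10-state distribution."""
    return float(np.asarray(p)[..., N_SITES + 1:].sum(axis=-1))
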