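"""Model parameter containers for the voltage-dependent MWC gating model.

The channel is a homotetramer with one agonist binding site per subunit.
Gating is a single concerted closed<->open transition whose rates carry the
voltage dependence; each bound agonist biases the closed<->open equilibrium
by a fixed free-energy increment ``ddG`` (negative for agonists).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

#: Faraday constant (C/mol)
FARADAY = 96485.0
#: Gas constant (J mol^-1 K^-1)
GAS_CONSTANT = 8.314
#: Default recording temperature, 23 degrees C (K)
T_DEFAULT = 296.15

N_SITES = 4


class Mechanism(str, Enum):
    """How an agonist partitions its free-energy effect between the rates.

    TYPE_I stabilizes the open state relative to the transition state:
    closing slows with each bound ligand, opening is untouched (menthol-like).
    TYPE_II destabilizes the closed state relative to the transition state:
    opening accelerates, closing is untouched (AITC-like).
    """

    TYPE_I = "type_I"
    TYPE_II = "type_II"


@dataclass(frozen=True)
class GateParams:
    """Unliganded gating parameters.

    Parameters
    ----------
    alpha0 : float
        Opening rate at 0 mV (s^-1).
    beta0 : float
        Closing rate at 0 mV (s^-1).
    z : float
        Effective gating charge (elementary charges); half assigned to each
        rate, i.e. a symmetric transition-state position along the field.
    temperature : float
        Absolute temperature (K).
    """

    alpha0: float
    beta0: float
    z: float = 0.82
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if not (self.alpha0 > 0 and math.isfinite(self.alpha0)):
            raise ValueError(f"alpha0 must be positive and finite, got {self.alpha0}")
        if not (self.beta0 > 0 and math.isfinite(self.beta0)):
            raise ValueError(f"beta0 must be positive and finite, got {self.beta0}")
        if not 0 < self.z < 5:
            raise ValueError(f"gating charge z must be in (0, 5), got {self.z}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")

    @property
    def RT(self) -> float:
        """Thermal energy per mole (J/mol)."""
        return GAS_CONSTANT * self.temperature


@dataclass(frozen=True)
class LigandSpec:
    """One agonist: binding affinity, energetic effect and kinetics.

    ``Kd`` is the open-channel dissociation constant (M). The closed-state
    affinity is weaker for an agonist: Kd_closed = Kd * exp(-ddG/RT).
    Unbinding from the open state is ``koff_open = kon * Kd``; unbinding from
    the closed state follows from detailed balance around each
    binding/gating square, ``koff_closed = koff_open * exp(-ddG/RT)``.
    """

    name: str
    mechanism: Mechanism
    Kd: float
    ddG: float
    kon: float
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        if not (self.Kd > 0 and math.isfinite(self.Kd)):
            raise ValueError(f"Kd must be positive and finite, got {self.Kd}")
        if not (self.kon > 0 and math.isfinite(self.kon)):
            raise ValueError(f"kon must be positive and finite, got {self.kon}")
        if not math.isfinite(self.ddG):
            raise ValueError(f"ddG must be finite, got {self.ddG}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if isinstance(self.mechanism, str) and not isinstance(self.mechanism, Mechanism):
            object.__setattr__(self, "mechanism", Mechanism(self.mechanism))

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature

    @property
    def koff_open(self) -> float:
        """Unbinding rate from the open state (s^-1)."""
        return self.kon * self.Kd

    @property
    def koff_closed(self) -> float:
        """Unbinding rate from the closed state, set by detailed balance (s^-1)."""
        return self.koff_open * math.exp(-self.ddG / self.RT)

    @property
    def Kd_closed(self) -> float:
        """Closed-state dissociation constant (M)."""
        return self.Kd * math.exp(-self.ddG / self.RT)

    def is_agonist(self) -> bool:
        return self.ddG < 0


# ---------------------------------------------------------------------------
# Parameter-file I/O (JSON): keys mirror the in-memory fields with explicit
# unit suffixes so files are self-describing.
# ---------------------------------------------------------------------------

def params_to_dict(gate: GateParams, ligands: list[LigandSpec] | None = None) -> dict:
    doc: dict = {
        "alpha0_s1": gate.alpha0,
        "beta0_s1": gate.beta0,
        "z": gate.z,
        "temperature_K": gate.temperature,
    }
    if ligands:
        doc["ligands"] = [
            {
                "name": lig.name,
                "mechanism": lig.mechanism.value,
                "Kd_M": lig.Kd,
                "ddG_J_per_mol": lig.ddG,
                "kon_per_M_s": lig.kon,
            }
            for lig in ligands
        ]
    return doc


def params_from_dict(doc: dict) -> tuple[GateParams, list[LigandSpec]]:
    gate = GateParams(
        alpha0=float(doc["alpha0_s1"]),
        beta0=float(doc["beta0_s1"]),
        z=float(doc["z"]),
        temperature=float(doc.get("temperature_K", T_DEFAULT)),
    )
    ligands = [
        LigandSpec(
            name=block["name"],
            mechanism=Mechanism(block["mechanism"]),
            Kd=float(block["Kd_M"]),
            ddG=float(block["ddG_J_per_mol"]),
            kon=float(block["kon_per_M_s"]),
            temperature=gate.temperature,
        )
        for block in doc.get("ligands", [])
    ]
    return gate, ligands


def save_params(path: str | Path, gate: GateParams,
                ligands: list[LigandSpec] | None = None) -> None:
    Path(path).write_text(json.dumps(params_to_dict(gate, ligands), indent=2) + "\n")


def load_params(path: str | Path) -> tuple[GateParams, list[LigandSpec]]:
    return params_from_dict(json.loads(Path(path).read_text()))
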