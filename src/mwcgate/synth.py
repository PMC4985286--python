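"""Synthetic whole-cell recordings with the statistical structure the
analysis assumes.

The generator runs the deterministic 10-state simulator and adds i.i.d.
Gaussian recording noise — the matched model for least-squares analysis.
It emulates voltage-clamp recordings in symmetric Na+ solutions sampled at
5-20 kHz; it does not emulate series-resistance error, capacitance
transients, line noise, or the slow inhibitory phase seen with millimolar
electrophile concentrations.

``reference_fixture`` ships the experimentally derived parameter set for
human TRPM8 gating with menthol (Type I) and AITC (Type II) that the whole
test suite uses as ground truth.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .params import GateParams, LigandSpec, Mechanism, T_DEFAULT
from .protocols import (VoltageProtocol, ap_train, ap_waveform,
                        relaxation_protocol, step_family)
from .simulate import RecordingConfig, simulate, to_current
from .traces import CurrentTrace, write_trace


def reference_fixture() -> tuple[GateParams, LigandSpec, LigandSpec]:
    """Reference gating and ligand parameters for human TRPM8 at 23 C.

    Unliganded gating: alpha0(0) = 10.4 s^-1, beta0(0) = 1.11e3 s^-1,
    z = 0.82. Menthol is the canonical Type I agonist (Kd = 21 uM,
    ddG = -4.5 kJ/mol, kon = 5.51e5 M^-1 s^-1); AITC the canonical Type II
    (Kd = 2.9 mM, ddG = -2.7 kJ/mol, kon = 9.5e4 M^-1 s^-1).
    """
    gate = GateParams(alpha0=10.4, beta0=1.11e3, z=0.82, temperature=T_DEFAULT)
    menthol = LigandSpec(name="menthol", mechanism=Mechanism.TYPE_I,
                         Kd=21e-6, ddG=-4.5e3, kon=551e3)
    aitc = LigandSpec(name="AITC", mechanism=Mechanism.TYPE_II,
                      Kd=2.9e-3, ddG=-2.7e3, kon=95e3)
    return gate, menthol, aitc


@dataclass
class SyntheticConfig:
    """Ground truth plus recording conditions for one synthetic dataset."""

    gate: GateParams
    ligand: LigandSpec
    concentrations_M: list[float]
    protocol: str = "relax"          # preset name or explicit protocols below
    protocols: list[VoltageProtocol] | None = None
    Gmax_nS: float = 10.0
    noise_sd: float = 0.01           # fraction of per-sweep peak |I|
    sampling_kHz: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 1.0 <= self.sampling_kHz <= 50.0:
            raise ValueError("sampling rate out of plausible band (1-50 kHz)")

    @property
    def dt(self) -> float:
        return 1e-3 / self.sampling_kHz


def _protocols_for(config: SyntheticConfig) -> list[VoltageProtocol]:
    if config.protocols is not None:
        return config.protocols
    if config.protocol == "relax":
        return [relaxation_protocol()]
    if config.protocol == "steps":
        return step_family()
    if config.protocol == "ap":
        return [ap_waveform(dt=config.dt)]
    if config.protocol == "ap-train":
        return [ap_train(ap_waveform(dt=config.dt))]
    raise ValueError(f"unknown protocol preset {config.protocol!r}")


def generate_recording(config: SyntheticConfig,
                       outdir: str | Path | None = None) -> list[CurrentTrace]:
    """Simulate the configured sweeps and add Gaussian recording noise.

    One trace per (concentration, sweep); deterministic given ``seed``.
    Metadata records the ground truth so downstream fits can be checked.
    When ``outdir`` is given, traces are also written as CSV files.
    """
    rng = np.random.default_rng(config.seed)
    rec = RecordingConfig(Gmax_nS=config.Gmax_nS)
    sweeps = _protocols_for(config)
    traces = []
    for L in config.concentrations_M:
        for k, proto in enumerate(sweeps):
            sim = simulate(config.gate, config.ligand, L, proto, dt=config.dt)
            i = to_current(sim, rec)
            if config.noise_sd > 0:
                sigma = config.noise_sd * np.abs(i).max()
                i = i + rng.normal(0.0, sigma, size=i.shape)
            tr = CurrentTrace(
                time_s=sim.time, voltage_mV=sim.voltage * 1e3, current_pA=i,
                po=sim.po if config.noise_sd == 0 else None,
                meta={
                    "ligand": config.ligand.name,
                    "mechanism": config.ligand.mechanism.value,
                    "conc_M": repr(float(L)),
                    "Gmax_nS": repr(config.Gmax_nS),
                    "noise_sd": repr(config.noise_sd),
                    "seed": str(config.seed),
                    "sweep": proto.name or str(k),
                    "true_alpha0_s1": repr(config.gate.alpha0),
                    "true_beta0_s1": repr(config.gate.beta0),
                    "true_z": repr(config.gate.z),
                    "true_Kd_M": repr(config.ligand.Kd),
                    "true_ddG_J_per_mol": repr(config.ligand.ddG),
                    "true_kon_per_M_s": repr(config.ligand.kon),
                },
            )
            traces.append(tr)
            if outdir is not None:
                Path(outdir).mkdir(parents=True, exist_ok=True)
                fname = f"{config.ligand.name}_{L:.6g}M_{tr.meta['sweep']}.csv"
                write_trace(Path(outdir) / fname, tr)
    return traces


def generate_study_bundle(outdir: str | Path, seed: int = 0,
                          noise_sd: float = 0.01,
                          sampling_kHz: float = 10.0) -> dict:
    """Emit the full synthetic study: step families, relaxation sets, AP trains.

    Relaxation sets cover three non-zero concentrations plus control at two
    test voltages per ligand (the inclusion rule for the global kinetic
    fit); step families support the G-V/Boltzmann stage; AP trains support
    the charge-flux comparison. Returns the manifest (also written to
    ``manifest.json``) listing every file with a sha256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gate, menthol, aitc = reference_fixture()
    datasets = {
        "steps_aitc": SyntheticConfig(
            gate=gate, ligand=aitc,
            concentrations_M=[0.0, 3e-4, 1e-3, 3e-3, 1e-2],
            protocol="steps", noise_sd=noise_sd,
            sampling_kHz=sampling_kHz, seed=seed + 1),
        "relax_menthol": SyntheticConfig(
            gate=gate, ligand=menthol,
            concentrations_M=[0.0, 1e-5, 3e-5, 1e-4],
            protocol="relax", noise_sd=noise_sd,
            sampling_kHz=sampling_kHz, seed=seed + 2),
        "relax_aitc": SyntheticConfig(
            gate=gate, ligand=aitc,
            concentrations_M=[0.0, 1e-3, 3e-3, 1e-2],
            protocol="relax", noise_sd=noise_sd,
            sampling_kHz=sampling_kHz, seed=seed + 3),
        "train_menthol": SyntheticConfig(
            gate=gate, ligand=menthol, concentrations_M=[3e-5],
            protocol="ap-train", noise_sd=noise_sd,
            sampling_kHz=sampling_kHz, seed=seed + 4),
        "train_aitc": SyntheticConfig(
            gate=gate, ligand=aitc, concentrations_M=[3e-3],
            protocol="ap-train", noise_sd=noise_sd,
            sampling_kHz=sampling_kHz, seed=seed + 5),
    }
    manifest: dict = {"seed": seed, "datasets": {}}
    for name, cfg in datasets.items():
        sub = outdir / name
        generate_recording(cfg, outdir=sub)
        files = {}
        for f in sorted(sub.glob("*.csv")):
            files[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
        manifest["datasets"][name] = {
            "ligand": cfg.ligand.name,
            "protocol": cfg.protocol,
            "concentrations_M": cfg.concentrations_M,
            "files": files,
        }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
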