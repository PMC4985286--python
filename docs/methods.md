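# Methods

## Model

The gating model is a concerted (MWC-type) allosteric scheme for a
homotetrameric channel with one agonist site per subunit. Two
conformations (closed, open) at occupancies 0–4 give ten aggregated
states on a 2×5 lattice. Vertical edges are the gating transition with
rates

    alpha_i(V), beta_i(V);   alpha_0(V) = alpha0(0) e^{+0.5 zFV/RT},
                             beta_0(V)  = beta0(0)  e^{-0.5 zFV/RT}

Temperature is fixed (23 °C, RT with R = 8.314 J mol⁻¹ K⁻¹,
F = 96485 C mol⁻¹); the enthalpic/entropic decomposition of the barrier is
deliberately absorbed into alpha0(0), beta0(0) — temperature-dependent
gating is out of scope. The gating charge z is split half-and-half
between opening and closing, so alpha(V)·beta(V) is voltage-invariant (a
tested invariant).

Each bound agonist multiplies the gating equilibrium constant by
f = e^{−ΔΔG/RT} (> 1 for an agonist, ΔΔG < 0). The mechanism decides
where that factor lands:

- Type I (open-state stabilisation):  beta_i = beta_0 f^{−i}, alpha_i = alpha_0.
- Type II (closed-state destabilisation): alpha_i = alpha_0 f^{i}, beta_i = beta_0.

Note the sign convention: agonists *slow closing* (Type I) or *speed
opening* (Type II). This is the only convention under which the
midpoint-shift equation below, the measured shift direction, and the
relaxation phenotypes are simultaneously consistent.

Binding uses the standard aggregation for four identical independent
sites: forward (4−i)·kon·L, backward i·koff. Kd is the *open-state*
dissociation constant, koff_open = kon·Kd; kon is conformation
independent and koff_closed = koff_open·e^{−ΔΔG/RT} follows from detailed
balance, which closes every elementary square of the lattice exactly
(cycle products are property-tested to 1e−10).

Equilibrium quantities are mechanism-blind. The open probability has the
closed form Po = Z_O/(Z_O+Z_C) with Z_O = K_0(V)(1+L/Kd)⁴ and
Z_C = (1+(L/Kd)e^{ΔΔG/RT})⁴, and the ligand-induced activation-midpoint
shift is

    dV1/2(L) = −(RT/zF) ln[(1+L/Kd)⁴ / (1+(L/Kd)e^{ΔΔG/RT})⁴],

monotone in L and saturating at 4ΔΔG/(zF). The REFER φ-value — the slope
of log alpha_i against log K_i over i = 0..4 — is exactly 0 for Type I
and 1 for Type II, independent of voltage.

## Reference parameters

`reference_fixture()` ships the experimentally derived set used as ground
truth throughout: alpha0(0) = 10.4 s⁻¹, beta0(0) = 1.11×10³ s⁻¹, z = 0.82,
T = 296.15 K; menthol (Type I): Kd = 21 µM, ΔΔG = −4.5 kJ/mol,
kon = 5.51×10⁵ M⁻¹s⁻¹; AITC (Type II): Kd = 2.9 mM, ΔΔG = −2.7 kJ/mol,
kon = 9.5×10⁴ M⁻¹s⁻¹.

## Simulation

Piecewise-constant protocols are solved exactly: within each segment the
master equation's solution is the matrix exponential, evaluated by
spectral decomposition of the 10×10 generator (falling back to a dense
`expm` with a logged warning if the eigenbasis is ill-conditioned,
condition number > 1e12). Sampled waveforms (action potentials) are
linearly interpolated — a continuous command, as a stimulus DAC file is —
and integrated with LSODA at rtol 1e−8 / atol 1e−10; a piecewise protocol
handed to the ODE path is integrated segment by segment so the voltage
discontinuity is exact. The two deterministic paths agree to < 1e−6 in Po
and both are validated against an event-driven Gillespie single-channel
simulator (the stochastic oracle) within Monte-Carlo error.

Current mapping is ohmic: I = Gmax·Po·(V−Erev) with Erev = 0 mV
(symmetric ~150 mM Na⁺ solutions); all rectification is carried by
Po(V). Series resistance, capacitance transients and leak are not
modelled; relaxation fits instead blank the first 0.2 ms after each
voltage edge.

## Protocols

Defaults: activation step families −140..+220 mV in 20 mV increments
(100 ms steps, −60 mV holding), two-step relaxation sweeps +120 mV then
−80 mV (100 ms each; step durations are configurable — the canonical
experiments used 100 ms steps), and a stylised small-diameter sensory
neuron action potential: rest −60 mV, peak +40 mV, 1 ms upstroke, 2 ms
repolarisation, 10 mV after-hyperpolarisation recovering with a 15 ms
time constant; trains are 8 Hz for 1 s (a typical firing rate of
cold-sensitive fibres) with a 100 ms resting baseline for holding-current
estimation. Sampling defaults to 20 kHz (protocols) and 10 kHz
(synthetic recordings), within the 5–20 kHz band of the recordings being
emulated. With these defaults the net time-integral of (V−V_rest) over
one AP is slightly negative (the AHP lobe marginally outweighs the
spike); only relative Type I/II behaviour is asserted on AP simulations,
never absolute currents, and no conclusion depends on the template's
fine shape.

## Analysis conventions

- Steady-state conductance: G = I_ss/V with I_ss the mean over the last
  10% of the test step; |V| < 10 mV excluded; drift > 5% across the
  averaging window flags the sweep. The 10% window is a declared
  convention.
- Boltzmann fits parameterise the slope by an equivalent charge z so
  G–V fits share units with the kinetic model.
- Exponential fits: least squares with a log-linear tail initializer and
  two fixed multiplicative restarts (lowest RSS wins) — deterministic by
  construction. Model selection between one and two components uses an
  extra-sum-of-squares F-test at p < 0.01 plus a 2% minimum relative
  amplitude for the second component.
- The agonist classifier consumes a table of mono-exponential
  activation/deactivation taus versus concentration. Type II requires
  Spearman(conc, tau_act) ≤ −0.8 with tail tau stable within 20% and no
  materially bi-exponential tails; Type I requires tail slowing beyond
  20% plus bi-exponential tails; anything else is INDETERMINATE. "Material"
  bi-exponentiality uses a 10% minor-amplitude floor rather than the 2%
  model-selection floor: any 10-state model produces small genuine extra
  components (binding relaxations, re-openings) even for Type II ligands,
  and those do not distinguish the classes.

## Parameter estimation

Stage 1 (steady state): (Kd, ΔΔG) are fit to a dV1/2-versus-concentration
series by least squares on the closed form above, Kd searched on a log
scale, z fixed at 0.82. If the highest concentration is below ~5× the
fitted Kd the shift has not begun to saturate, Kd and ΔΔG are only
jointly constrained, and the fit is flagged approximative (this fires for
the AITC series, which is solubility-limited at 10 mM).

Stage 2 (kinetics): with (Kd, ΔΔG, z) pinned, alpha0(0), beta0(0) and kon
are fit globally to relaxation time courses across ≥ 3 concentrations
(including control) and two voltages. koff is Kd·kon and the closed-state
unbinding rate is re-derived from detailed balance at every objective
evaluation — never a free parameter. Currents are normalised per sweep by
peak |I| so a shared maximal conductance drops out (the alternative, a
per-cell Gmax nuisance parameter, is unnecessary on normalised data). All
three parameters are searched in log space; kon is multi-started across
five decades (10³–10⁷ M⁻¹s⁻¹) and the lowest objective wins; parameters
ending at bounds are flagged. On noiseless synthetic data the round trip
returns the generating parameters to optimizer precision (≪ 0.1%); with
very fast kon the model degenerates to instantaneous binding equilibrium
and kon is reported with a wide interval rather than a point claim.

## Synthetic data

The generator runs the deterministic simulator and adds i.i.d. Gaussian
noise (default 1% of per-sweep peak current) — the matched model for
least-squares analysis, and the only noise model: no 1/f, line pickup,
series-resistance error or capacitive transients, and not the slow
inhibitory current decay seen experimentally at millimolar electrophile
concentrations. Passing tests on these data therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to every artefact of real recordings.
Everything is deterministic given the seed; trace files carry their
ground truth and seed in the metadata header, and the study bundle writes
a manifest with sha256 checksums.

Problem sizes used by the shipped studies: relaxation sets are 4 sweeps ×
2200 samples (10 kHz); step families 19 sweeps per concentration at
5–10 kHz; AP trains 1.1 s at 10 kHz; the Gillespie cross-checks use
3,000–10,000 channels. These sizes put every estimate deep in its
asymptotic regime while keeping a full test run under a minute of
simulation time.

## Known limitations

- The two-ligand (Type I + Type II) co-application is modelled by the
  scalar shortcut of folding the Type II effect into alpha0 (a fixed
  decrease of the closed-to-transition barrier); the full 50-state
  two-ligand lattice is intentionally not implemented.
- The classifier identifies the generating mechanism only in the
  moderate-effect regime (roughly |ΔΔG| ≲ 3 kJ/mol for Type II, or faster
  unbinding): a strong Type II agonist with slow unbinding genuinely
  slows the observed tail through liganded re-openings and presents the
  Type I phenotype. This is a prediction of the model, not a fitting
  artefact; the property tests pin one such point as a documented
  misclassification.
- Binding sites are independent and energetically equivalent;
  cooperativity between sites, multiple open states, and closed-closed
  transitions are out of scope, as is any temperature dependence.
- Single-channel simulation is an internal validation oracle, not a
  user-facing idealisation/dwell-time analysis feature.
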