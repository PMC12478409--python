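# Methods

This note records the scientific and numerical choices behind `gastroloop`:
the model structure, how the coefficient sets that the primary parameter
tables defer to supplementary sources were reconstructed, the numerical
treatment of the stiff closed loop, and what the package's tests do and do
not establish about real stomachs.

## Model structure and assumptions

The stomach is reduced to three lumped cylindrical compartments — fundus
(tonic), antrum (phasic), pyloric sphincter (tonic + phasic) — coupled to
the brainstem by algebraic afferent/efferent maps.  The core assumptions:

* **Quasi-steady signalling.**  Every neurotransmitter-release and
  receptor-response stage is a memoryless Michaelis–Menten/Hill (MMEHC)
  map evaluated at each ODE step.  Synaptic and vesicle kinetics,
  desensitisation, and second-messenger dynamics faster than the ~20 s
  slow-wave cycle are not resolved.
* **Normalised myosin pools.**  The four Hai–Murphy fractions
  (M, Mp, AMp, AM) sum to 1 per contractile system; absolute myosin
  concentrations are absorbed into the rate constants.  Phosphorylation and
  dephosphorylation are Michaelis–Menten fluxes in the substrate fraction
  (`kcat·[enzyme]·S/(km + S)`); attachment/detachment are first order
  (k_b, k_c, k_a).  The four derivatives sum to zero identically, so mass
  conservation holds to integrator precision.
* **Single-compartment antrum.**  No intragastric fluid mechanics; the
  peristaltic wave is represented by one radius trace, and gastric outflow
  depends only on the sphincter radius.
* **Deterministic loop.**  No channel noise, no afferent stochasticity;
  identical scenarios produce bitwise-identical trajectories at fixed
  solver settings.

### Direction of the fundic NANC pathway

The VIP branch produces an "MLCK inhibitory factor" φ_iψ,1 (a saturating
MMEHC of [VIP] with A = 1).  We compose it as
`[MLCK]to,1 = (1 − φ_iψ,1)·MLCK_act`, exactly parallel to the explicitly
stated sphincter composition `[MLCK]to,3 = (1 − φ_ih,to,3)·MLCK_act`.
Composing multiplicatively without the complement would make NANC firing
*increase* kinase activity, i.e. turn the relaxation pathway excitatory and
invert the volume–accommodation relationship; with A = 1 the complement
form is the only reading consistent with the pathway's physiological role.

### Distension geometry

The latch-bridge total maps to the fundic relative distension through

    RA₁ = [(1 − β₁·b) / (1 − β₁·b_max)]² ,

where `b_max` is the bridge total of the reference (zero-NANC, empty
stomach) state.  RA₁ = 1 at the full bridge complement and
RA₁ = (1 − β₁·b_max)⁻² at zero bridges.  We calibrate `b_max` so the
zero-bridge distension equals the open-cylinder radius ratio
`sqrt(V_max/V_min) = sqrt(1.2/0.08) ≈ 3.87`: a fully relaxed fundus holds
the full physiological volume at fixed cylinder length.  The same squared
form with β₃ = 236.32 governs the sphincter; there the numerator reaches
zero at b = 1/β₃, so a moderate latch-bridge complement closes the valve
completely — this is what seals the pylorus in the sympathetic state.

The antral unstressed radius and tissue length scale with the fundic
distension (`r_ini,2 ∝ RA₁`, `L_t,2 ∝ RA₁`): the antrum shares the
gastric wall, so its relaxed lumen grows as the stomach accommodates.
This single geometric coupling reproduces the observed √V scaling of the
relaxed antral radius (0.7, 1.1, 1.65 cm at 0.2, 0.5, 1.1 L) and makes the
occlusion *fraction* volume-invariant, matching the observation that
occlusion stays at ~78–79 % across volumes while the absolute contraction
amplitude grows.

Peristaltic narrowing is a chord construction: the contracting segment of
undeformed length L_t,2 deflects the wall inward by a depth
`d = f_occ·r_ini,2·S(λ₂)`, where S is a C¹ ramp (smoothstep) in the
tissue stretch, 0 below λ_on = 1.08 and 1 above λ_sat = 1.22.  The
deformed tissue half-length is the hypotenuse `ω₃,₂ = sqrt((L_t/2)² + d²)`,
so the chord relation `r_d = sqrt(ω² − L_t²/4)` recovers d.  The ramp's
saturation expresses that a fully recruited contraction occludes a fixed
fraction `f_occ = 1.31/1.65 ≈ 0.794` of the lumen; the onset threshold
keeps the relaxed phase (λ₂ ≈ 1.00–1.02) fully open.  The sphincter's
phasic closure uses the same ramp with lower thresholds
(λ_on = 1.03, λ_sat = 1.11), i.e. its closures are complete.

### Membrane and stress chain

ICC and SMC potentials follow a modified leaky-integrate-and-fire pair.
The stimulating current is `I = κ` inside a smooth periodic window of the
slow-wave phase (duty `t_open/t_end`) and 0 outside; the phase is a
continuous state `dφ/dt = cpm/60`, so no event detection is needed and the
right-hand side stays smooth for the stiff solver.  No spike-and-reset is
applied: the model is used as a slow-wave envelope generator.  The gap
junction current is oriented `I_couple = G_coup(V_ICC − V_SMC)` so that the
SMC follows the ICC (the printed operand order, taken with a plus sign in
the SMC equation, would repel the SMC from the pacemaker).  SMC voltage
gates Ca²⁺ through a logistic map (half-activation −40 mV, slope 2.5 mV)
and Ca²⁺ activates MLCK through a cooperative Ca–calmodulin saturation
(K = 0.4 µM, Hill 4) — the standard structure of smooth-muscle
excitation–contraction models, with the two constants calibrated (below).

Active stress uses the sliding-filament overlap parabola
`L̄ = ō − ō²/(2·ō_opt) + X̄` and
`σ = ō_B·L̄·(AMp+AM)·(λ_f,1 − ō − 1)`.  Because
`ō = (λ_f,1 − 1) + ō_chem` with `ō_chem = −ō_A/ō_B`, the last factor
collapses to `ō_A/ō_B` identically, so σ = ō_A·L̄·(AMp+AM): stress is
zero exactly when no bridges are attached and no additional offset is
needed.  Passive stress is the degree-5 polynomial
`E(λ) = Σ 𝒜_{s−1} λˢ` with `𝒜 = c·(0,0,0,−1,1)`, i.e. E = c·λ⁴(λ−1):
zero at λ = 1 (the relaxed state is the unstressed state), steeply
stiffening beyond.  The stretch ODE `dλ/dt = (σ−E)/η₂` uses the nonlinear
dashpot `η₂ = S₃·exp(S₄ + S₅(E−σ))·tanh(S₆(λ−0.982))`, floored at
10⁻³ kPa·s (configurable) so the dashpot can never become anti-dissipative
when the tanh factor changes sign; the exponent is clamped to ±8.

## Reconstructed parameters and calibration

The neural (MMEHC) table and the gastric table are taken verbatim.  The
remaining coefficient sets carry provenance `"supplementary-reconstructed"`
and are produced by `scripts/calibrate_reconstructed.py`, which treats the
reported steady operating points as calibration targets — the same role
the supplementary fits play in the source model.  Structure first, values
second:

* **Hai–Murphy rates** (shared by all three contractile systems):
  k_a = 0.8 s⁻¹, k_b = 1.0 s⁻¹, k_c = 1.5 s⁻¹, kcat_MLCP = 0.8 µM⁻¹s⁻¹,
  km = 1.  These set the ~1–2 s rise and fall of the phasic bridge pulse,
  fast enough that bridges decay to a few percent of peak between slow
  waves even at the shortest (11 s) cycle.  The kinase turnover kcat_MLCK
  is then the unique value (0.4263 µM⁻¹s⁻¹) for which the zero-NANC fundic
  steady state carries exactly the reference bridge total b_max (step 1 of
  the script).
* **Intramural volume map** (k_vol,h powers 1–8 below V_tot,o = 0.5 L,
  k_vol,l powers 1–9 above): for each volume on a grid, the NANC frequency
  that makes the fundic steady-state distension equal the open-cylinder
  target `RA₁ = sqrt(V/0.08)` is found by root finding through the full
  VIP/NO → enzyme → Hai–Murphy chain; the piecewise polynomials are
  least-squares fits to that inverse map (residuals < 0.2 Hz, continuity
  jump at V_tot,o < 0.05 Hz).  Above ≈ 1.12 L the required drive diverges
  (the VIP inhibition saturates at φ_iψ ≈ 0.96), so the fit covers
  [0.08, 1.12] L and the map extrapolates beyond; the studied scenarios
  stay at or below 1.1 L.
* **Mechanosensitive map**: logistic with f_min = 0.5 Hz, gain 12 Hz,
  midpoint 20 Hz, slope 1.8 Hz.  With the mechanoreceptor line
  (42.85·λ − 42.85), this keeps the antral cholinergic drive near baseline
  below ~0.6 L and recruits it at high volume, reproducing the reported
  ICC-amplitude pattern (comparable at 0.2/0.5 L, larger at 1.1 L).
* **Hyperelastic scale**: c is set so the weakest studied volume still
  drives the antral stretch past the occlusion saturation threshold
  (peak λ₂ ≈ 1.32 at 0.2 L); the calibrated value is c ≈ 31.3 kPa.
* **Chemosensitive map** (k_inter,chem, powers 1–9 of f_chem on
  [0, 30] Hz): anchored by inverting the sphincter tonic chain — for a
  target open radius, the required bridge total, then the required
  inhibitory fraction φ_ih, then the NANC frequency from the Hill inverse.
  Anchors: 0.46 cm at the 30 Hz chemoreceptor ceiling (g_cal ≈ 0), 0.13 cm
  at g_cal = 0.67 kcal/cm³, and radii at the other studied densities that
  reproduce the reported mean emptying rates given the realized phasic
  open fraction.  The polynomial is a weighted fit to a monotone (PCHIP)
  interpolant through the anchors; extrapolation beyond 30 Hz is refused.
* **PS phasic stimulus duty** (t_open,3/t_end = 0.662): tuned so the
  cycle-averaged squared opening fraction ⟨(r/r_open)²⟩ ≈ 0.408 matches
  the 0.05 mL/s mean emptying rate at 0.67 kcal/cm³ given the 0.13 cm
  open-state radius.
* **MLIF constants** (R, τ, V_rest): chosen to give a −67 → ≈ −28 mV ICC
  slow-wave envelope and an SMC excursion −60 → ≈ −38 mV under
  parasympathetic baseline drive, with an effective coupling gain
  G_coup·R_SMC = 3.  The Ca²⁺ half-activation sits between the
  parasympathetic and sympathetic SMC plateaus, which is what lets the
  15 Hz purinergic/nitrergic override collapse contraction amplitude.
* **Geometry references**: r_ini,1 = 1.5 cm (empty fundus);
  r_ini,2 = 1.65/sqrt(1.1/0.08) cm so the relaxed antral radius is 1.65 cm
  at 1.1 L; f_occ = 1.31/1.65; r_ini,3 = 0.2 cm with the tonic scale
  b_max,3 chosen so the fully relaxed sphincter saturates just above
  0.46 cm (and below r_max,3 = 0.48 cm).

Calibrated values are frozen in `gastroloop/_reconstructed.py`; every one
is an ordinary registry entry and can be overridden from a parameter file.

## Scenarios: what they emulate, and what tests show

The preset scenarios reproduce the study conditions: fixed-volume motility
at 0.2/0.5/0.6/1.1 L with near-zero caloric density, the sympathetic
override at 0.6 L, and emptying runs from V_meal(0) = 0.3 L (the initial
meal volume is not reported; 0.3 L is a configurable default in the range
of the liquid-meal protocols the model was compared against) at caloric
densities 0.33/0.38/0.50/0.67 kcal/cm³ with V_gas = 0.21 L.

Passing the scenario tests shows that the implemented loop reproduces the
reported steady operating points and orderings (occlusion, radii, emptying
rates, autonomic contrast) and that the structural invariants (mass
conservation, bounds, monotonicity, determinism) hold.  It does not
validate the model against new experimental data: the interneuron maps are
calibrated to those same operating points, so agreement there is a
consistency check of the reconstruction, not independent evidence.  Real
stomachs additionally exhibit antral wave propagation, duodenal feedback,
pressure–volume coupling and hormonal (e.g. CCK) dynamics that this lumped
model does not contain.

## Numerics

* Stiff BDF integration (SciPy `solve_ivp`), rtol 10⁻⁶, atol 10⁻⁸,
  max_step 0.25 s, all configurable per scenario.  A 200 s scenario takes
  ~1 s on one core; halving the tolerances changes every summary metric by
  far less than 1 % (tested).
* The stimulus window is a logistic of `cos(2π(φ − d/2)) − cos(πd)`
  (width ε = 0.04), smooth across the phase wrap.
* Initial states sit on the slow manifold: tonic cross-bridge systems
  start at their steady state for the scenario's drive (solved by a short
  relaxation integration plus a Newton polish), membranes at rest,
  stretches at 1.  The default transient discard is two baseline slow-wave
  periods (40 s); summary metrics average over the complete cycles after
  it, using the phase state to delimit cycles.
* Occlusion is defined on radius, `100·(r_relaxed − r_min)/r_relaxed` per
  cycle: this is the definition consistent with all three reported
  amplitude/relaxed-radius pairs (78.6 %, 80.9 %, 79.4 %).
* Emptying stops when V_meal reaches zero; the mass balance
  `V_meal(t) = V_meal(0) − ∫Q dt` holds to ~10⁻⁵ L (tested).
* Degenerate inputs: negative frequencies and concentrations raise at the
  public API; ψ is clamped to [0, 1] (logged when active); the MMEHC power
  is evaluated in log space and underflows to 0 instead of overflowing;
  η₂ is floored; polynomial maps are floored at 0 Hz and the
  chemosensitive map refuses extrapolation beyond its fitted domain.

## Known limitations

* The sphincter's phasic rhythm is phase-locked to the antral slow wave
  with a fixed lag (0.35 cycles); independent pyloric pacemaking is not
  modelled.
* Above ≈ 1.12 L the intramural volume map extrapolates; distension
  fidelity degrades toward the 1.2 L bound.
* The chemoreceptor senses the prescribed nutrient delivery rate
  γ_max·Ω/g_cal, not the instantaneous outflow, so duodenal feedback is
  feedforward in disguise — adequate for steady emptying, wrong for rapid
  transients.
* Reconstructed coefficients are calibrated, not identified: different
  (k_vol, k_inter) pairs could fit the same operating points.  Treat them
  as a working set, not ground truth.
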