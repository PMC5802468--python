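# Methods

This note documents the models, the calibration procedure, the synthetic
variant generator, and the numerical choices behind `pleiopace`, in the
same spirit in which simulation packages document their model assumptions.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scientific question

Many ion-channel and calcium-transporter genes are expressed both in
cortical neurons and in the sinoatrial node (SAN), the heart's primary
pacemaker. A variant that alters a channel's voltage dependence therefore
acts in both tissues at once. The package asks: for a population of such
variants, is the effect on neuronal firing *analogous* (same sign) or
*non-analogous* (opposite sign) to the effect on cardiac pacemaking?
The mechanistic hinge is intracellular Ca²⁺: in a layer-V pyramidal cell
(L5PC), Ca²⁺ entry activates hyperpolarizing SK channels, so Ca²⁺-channel
gain *lowers* the firing rate; in a SAN cell, Ca²⁺ entry and sarcoplasmic-
reticulum Ca²⁺ cycling are depolarizing forces, so the same gain *raises*
the pacemaking rate. Na⁺ and HCN channel gains increase excitability in
both cell types.

## Cell models

### Sinoatrial node cells (`san-mouse`, `san-rabbit`)

Both are parameterizations of one 28-state single-compartment
architecture in the Kurata / Maltsev–Lakatta "coupled-clock" lineage:

* membrane clock — L-type Ca²⁺ current split into Cav1.2- and
  Cav1.3-parameterized components (shared Ca²⁺-dependent inactivation
  gate), T-type Ca²⁺, funny current I_f, TTX-sensitive Na⁺, rapid
  (two-gate) and slow delayed-rectifier K⁺, Na⁺/K⁺ pump, and a small
  linear background current;
* calcium clock — SERCA uptake (maximal rate `serca.p_up`) into a network
  SR pool, diffusion to a junctional SR pool, release through RyRs with
  SR-load-dependent gating (4-state scheme) into a submembrane space,
  Na⁺/Ca²⁺ exchange converting submembrane Ca²⁺ into inward current,
  and explicit troponin/calmodulin/calsequestrin buffering.

All gates are Boltzmann steady-state/τ pairs; each gate carries an
additive half-point offset, a multiplicative slope factor and a
multiplicative τ factor as the variant-facing parameters.

Species-specific numbers follow the published descriptions of mouse and
rabbit central SAN cells where we could adopt them directly, most
importantly the funny current: half-activation −106.8 mV with slope
16.3 mV and reversal −24 mV (mouse-type, HCN4-dominated) versus
−52.5 mV, 9.0 mV and −4 mV (rabbit-type, mixed HCN1/HCN4). The full
published equation sets could not be transcribed verbatim, so the
remaining conductances were set to produce the canonical central-SANC
waveform (rabbit-type: MDP ≈ −70 mV, peak ≈ +21 mV, APD50 ≈ 70 ms) and
then two quantities were *calibrated to the published control values*,
as part of model construction:

1. the maximal funny-current conductance, so that the peak inward I_f on
   the steady cycle is 6.0 pA (mouse-type) / 6.7 pA (rabbit-type);
2. a global kinetic rate factor (a pure time rescaling of the whole ODE
   system — it preserves every waveform amplitude, every current trace
   and all parameter sensitivities, and only sets the clock), so that
   the control rates are 4.76 Hz (mouse-type, factor 1.0795) and
   2.90 Hz (rabbit-type, factor 0.9279).

Intracellular Na⁺ is held constant (7.5 / 8.0 mM), avoiding the
multi-minute drift time scale. The RyR Ca²⁺-dependent transition rates
saturate at 5 /ms (opening) and 2 /ms (inactivation); these caps are two
orders of magnitude above the rates visited on the single-cell limit
cycle and only matter in strongly driven tissue nodes.

Known limitation: changing `serca.p_up` alone has a weak effect on the
isolated-cell rate in this implementation — SR release here is triggered
by the action potential rather than by spontaneous late-diastolic release,
so the "calcium clock" modulates the cycle mainly through the
Ca²⁺-transient → NCX pathway. ATP2A2-type variants consequently act
mostly through the neuron side of the analysis.

### Reduced layer-V pyramidal cell (`neuron-reduced`)

A two-compartment (soma + apical dendrite) conductance-based neuron with
the canonical L5PC repertoire: transient and persistent Na⁺, delayed
rectifier, M-type K⁺, SK (steep 4th-order Ca²⁺ activation, half-point
0.43 µM), high-voltage-activated L-type and low-voltage-activated T-type
Ca²⁺, HCN and leak, plus a per-compartment Ca²⁺ pool with passive decay
(τ = 120 ms) and a saturable SERCA-like uptake term (`serca.p_up`).
Control properties computed by the test suite: stable rest near −74 mV,
rheobase ≈ 0.34 nA (1 s somatic DC), monotone f–I curve reaching
≈ 30 Hz at 1.4 nA. The model deliberately substitutes for full
multicompartmental reconstructions; every neuron-side claim the package
makes is directional (sign/monotonicity), never an absolute current
match. Cav1.2- and Cav1.3-targeting modifications both resolve onto the
single HVA L-type current (the model does not distinguish the subtypes).

### Atrial plug-in

The 2-D tissue model fills the space around the SAN disc with a
three-variable excitable membrane of the Fenton–Karma family, rescaled to
mV (rest −85 mV) with atrial-like action-potential duration. Parameters
`u_c = 0.10` and `τ_d = 0.15 ms` were set so that a SAN-driven wave can
launch against the resting-tissue sink; the model does not pace
spontaneously. Tissue-level acceptance is qualitative (1:1 conduction,
exit block, silencing) — no atrial waveform quantity is asserted.

## Variant representation and downscaling

A variant is a list of parameter modifications: additive offsets Δ (mV)
for half-activation/half-inactivation/reversal potentials, multiplicative
factors Γ > 0 for slope, τ, conductance and SERCA-rate parameters.
Scaling by s maps Δ → s·Δ and Γ → Γ^s, so negative s reverses a variant
exactly and scaling composes additively on the log scale.

The calibration finds the largest c ∈ [0, 1] such that the variant cell
still preserves its behavior class at every probed magnitude in [0, c] —
in *both* directions ±s, because the analysis protocol applies variants
at positive and negative ε and both must remain behavior-preserving.
(Scanning only the variant's own direction would let a variant with an
asymmetric dose response pass calibration and still lose pacemaking at
−ε.) The search is an ascending coarse scan (default step 0.1) plus
bisection to |Δc| ≤ 10⁻³; non-monotone violation patterns resolve to the
first violation from below. The many-variant pipeline uses a documented
coarser setting (step 0.2, resolution 0.02).

Behavior-preservation conditions and defaults:

| condition | quantity | default bound |
|---|---|---|
| A1–A3 | neuron spike counts at 0.8×, 1.05×, 1.5× control rheobase (1 s DC) | exact equality |
| A4 | neuron steady firing rate at the strong stimulus | ±25 % |
| A5 | AP peak / AP half-width | ±10 mV / ±25 % |
| B1 | SAN pacemaking rate | ±25 % |
| B2 | SAN AP amplitude / APD50 | ±20 % / ±25 % |

The near-rheobase probe sits at 1.05× rather than 1.0× because a probe at
exactly the (1 pA-resolved) rheobase is degenerate: any infinitesimal
threshold shift flips its spike count and forces c = 0 for every
threshold-shifting variant. Calibrated c values are configuration
dependent by construction; no absolute c is asserted anywhere.

## Synthetic variant tables

The curated functional-genomics table such an analysis would normally
consume is a literature product, so the generator emulates its
*structure*: seven gene classes (SCN1A, HCN1 → Na/HCN; CACNA1C, CACNA1D,
CACNB2, CACNA1I, ATP2A2 → Ca/transporter), a default 80:14 class mixture
out of 94 variants, gene-appropriate parameter targets, offsets drawn
uniformly in ±10 mV, factors log-uniformly in [1/3, 3], and 1–4
modifications per variant. What passing tests on these tables show is
that the *machinery and the sign structure* behave correctly for variants
spanning a realistic range of alteration types; they cannot certify any
specific literature variant.

## Protocols and analysis

f–I curves use 1 s somatic DC with the first 200 ms excluded; rates are
measured by cycle counting over the steady window ((n−1)/span), which is
continuous in model parameters and agrees with 1/mean ISI for stationary
trains. Rheobase is found by bisection to 1 pA on "≥ 1 spike from rest".
SAN rate uses upward 0 mV crossings on a 20 s recording (2 s settling;
the pipeline uses 6 s records started from the stored limit-cycle state).
Neuron-side variant summaries are mean firing rates over 0.35–1.4 nA;
SAN-side summaries are pacemaking rates; Pearson correlations between the
model columns are computed per gene class after dropping variants with
any missing value, and each variant is classified analogous /
non-analogous / neutral with a 1 % relative-change dead band (the dead
band suppresses sign flips from numerical noise).

## Tissue simulations

1-D: a chain of identical SAN cells coupled by D = 6×10⁴ µm²/ms
(cell length 70 µm — a declared convention for the index-to-distance
mapping), explicit forward-Euler reaction at 0.01 ms with automatic
sub-stepping to keep the diffusion update inside its stability bound.
The clamp protocol (pre-clamp, depolarizing pulse on a cell fraction,
release) follows the classical cable-excitation design. For the √D
conduction-velocity scaling measurement the chain uses a quiescent-but-
excitable parameterization of the rabbit cell (pacemaking suppressed),
a 240-cell chain, a deep pre-clamp (−78 mV, below this model's MDP) and
developed-wave fit windows — in a chain of *pacing* cells the front is
contaminated by a diastolic phase wave and no clean velocity exists.

2-D: operator-split monodomain on a 3×3 cm sheet (default 76×76 nodes,
Δt = 0.125 ms, reaction sub-stepped 10×; the published-resolution
151×151/0.02 cm preset is available through `TissueConfig`), anisotropic
diffusion 1.2 / 0.25 cm²/s, no-flux boundaries, a central SAN disc with
reduced internal diffusion, and two structural choices that a homogeneous
disc needs in order to drive an atrial sheet at all:

* a peripheral ring (outer 30 % of the radius) with amplified fast Na⁺
  (20×) and halved spontaneous drive — the classical center/periphery
  gradient reduced to two zones; the ring is a driven amplifier, not an
  oscillator;
* two coupling presets for the disc-interior diffusion factor
  (`weak` = 0.35, `strong` = 0.8 of the atrial value), because the true
  intranodal coupling is uncertain and the two clinically described
  failure modes live at opposite ends of it: at strong coupling the
  atrial load can silence a weakened node outright; at weak coupling an
  accelerated node produces premature beats that intermittently fail to
  capture the atrium (exit block, lengthened beat-to-beat intervals).

The bundled demonstration variant (synthetic, CACNA1C-type: activation
−20 mV, conductance ×6 raw, calibrated to c ≈ 0.27) exhibits, on top of
1:1 control conduction at radii 0.27 and 0.40 cm: silencing of the
0.27 cm node at ε = −1/2 under strong coupling, and exit block with
prolonged beat-to-beat intervals at the 0.40 cm node under weak coupling
at the full calibrated strength (ε = +1). Half-strength gain
applications (ε = +1/2) still conduct 1:1 in this model at every coupling
strength we probed: the behavior-preservation conditions cap the ε = 1/2
effect at roughly half the conduction-failure threshold. The exit-block
demonstration therefore uses the largest behavior-preserving application;
this is a known divergence from the idealized expectation that ε = 1/2
suffices, and it is reported as such rather than tuned away.

## Numerical choices

* Single cells: LSODA (variable-step, stiff/non-stiff switching) with
  rtol = atol = 10⁻⁸, integration split at stimulus discontinuities;
  identical inputs are bit-reproducible (fixed solver, no wall-clock
  dependence). The engine-property tests verify < 0.1 % frequency shift
  under 10× tighter tolerances.
* Post-hoc state validation on every accepted run: |V| ≤ 200 mV, gating
  variables in [0, 1], concentrations > 0; violations raise an
  integration error naming the state.
* Tissue kernels are explicit (forward Euler + face-flux diffusion) with
  defensive state bounds active only in pathological driven regimes;
  the diffusion step conserves total membrane charge exactly under
  no-flux boundaries (tested to 10⁻¹³).
* AP widths are measured by linear interpolation between samples; the
  rising-edge search extends below the spike-detection threshold so low
  repolarization levels are not clipped.
* Spike detection: upward crossing of −20 mV (neurons) / 0 mV (SAN cycle
  counting) with a 2 ms / 20 ms refractory.
* Problem sizes used by the shipped tests (chosen to keep the default
  suite fast while leaving the measured quantities converged): 20 s SAN
  control runs, 6 s SAN records in the pipeline, 30-variant tables for
  the sign-structure analysis, 240-cell cables, 76×76 tissue grids with
  3–6 s of simulated time.

## Known limitations

* The SAN models are literature-guided reconstructions with documented
  calibration to the published control rate and I_f amplitude, not
  verbatim transcriptions of the published equation sets; absolute c
  values and absolute current magnitudes beyond the calibrated ones are
  not comparable to any specific publication.
* The neuron is a reduced morphology; back-propagation, dendritic Ca²⁺
  spikes and synaptic integration are out of scope.
* P_up has weak isolated-cell rate authority (see above).
* The 2-D tissue is a two-zone approximation of a continuous
  center–periphery gradient; exit block at half-strength gain
  applications is not reproduced (full calibrated strength is required).
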