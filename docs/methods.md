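# Methods

`bulbnet` simulates a few coupled glomerular microcircuits of the rodent
olfactory bulb — compartmental mitral, granule and periglomerular (PG)
cells joined by dendro-dendritic reciprocal synapses — and reproduces the
odor-coding analyses built on such models: linear-kernel fits of mitral
responses to pulsed odor input, residual/noise goodness scores, and the
phase- and delta-rate decorrelation of sister mitral cells under
respiration-sampled input.

## Cell models

All cells are branched-cable models with Hodgkin–Huxley-style channels.
Units are mV, ms, µm, nA, µS at every interface; membrane parameters are
specific (F/m², Ω·m², Ω·m).

**Mitral cell.** Reduced morphology: a 20 µm soma, a Na-rich initial
segment, a 300 µm primary dendrite ending in an 8-compartment tuft, and two
lateral (secondary) dendrite trunks that each split into three branches of
25 µm segments. The passive membrane is tuned so an exponential fit to the
somatic charging transient under a −100 pA step gives τ_m ≈ 50 ms. The
channel set is Na, fast and slow delayed-rectifier K, A-type K, L-type Ca
with a single-shell calcium pool, Ca-dependent K, and a dedicated
initial-segment Na channel; K reversal is −80 mV in interneurons and −70 mV
in the mitral cell.

**Granule cell.** Two compartments (soma + peripheral dendrite) with Na, K
and KA channels. Densities are calibrated so the spike threshold measured
under a slow somatic ramp (0.1 pA/ms) is ~25 mV above rest, a single
0.2 nS AMPA+NMDA event produces a ~2 mV EPSP, a dense train of 100 EPSPs at
6 ms intervals makes the cell fire only after hundreds of milliseconds of
integration, and a 35 Hz background barrage alone does not make it fire.

**PG cell.** Three compartments in two phenotypes built from the same
morphology by varying Ih, T-type Ca, K, KA and KCa densities: a
low-threshold-spiking variant (sag under −100 pA, rebound burst on release,
low-threshold spike at +100 pA) and a plateauing variant (sag at −50 pA,
burst with plateau at +50 pA). Populations are composed 1/3 plateauing and
2/3 LTS. Resting potentials sit near −65 mV.

Channel kinetics printed with the model description (the initial-segment
and granule Na channels, granule KA, PG T-type Ca, PG Ih, and the KCa
calcium half-points 0.015 / 0.0055 mM) are implemented exactly; the
remaining channels derive from the classic mitral-cell model they cite and
are shipped as clearly marked externally-sourced constants. Because those
rows are cited rather than printed, channel *densities* are treated as the
free parameters and recalibrated against the measured cell properties
above; the frozen result lives in `bulbnet/params/cells.yaml`.

The `trap` rate function's singular branch is guarded at |V−th| ≤ 1 µV and
evaluates to its analytic limit a·q·2^((T−24)/10) there; the temperature is
35 °C throughout. The PG Ih time-constant prefactor (0.85) is read as s⁻¹,
giving activation time constants of hundreds of ms, as expected for Ih.

## Numerics

Gate variables advance by exponential Euler using voltage lookup tables
(0.05 mV spacing) that pre-tabulate both the steady state and the per-step
decay factor; the cable equation is solved implicitly with the trapezoid
(Crank–Nicolson) rule in tree (Hines) order, vectorized over cell
populations with identical topology and JIT-compiled inner loops (a
backward-Euler setting is available via the theta parameter). Synapses are dual-exponential
conductance states driven by delayed spike events; NMDA conductances are
multiplied by the standard extracellular-Mg sigmoidal block
(1/(1 + [Mg]/3.57·e^(−0.062 V)), [Mg] = 1 mM) evaluated at the previous
step's voltage. Spikes are upward crossings of 0 mV at the soma with a 1 ms
refractory period for event emission; presynaptic release of all of a
cell's synapses is triggered by this somatic detector (dendritic
back-propagation is simulated electrically but does not gate release).

The default step is 25 µs for single-cell work; network protocols run at
50–100 µs. With the trapezoid scheme, halving the step from 25 to 12.5 µs
moves mitral spike times by less than 0.05 ms, and network firing rates at
100 µs match those at 50 µs to within a few percent, so the scaled-down
protocol runs use 100 µs.

## Network construction

Geometry is planar (the granule-layer projection). A central glomerulus
sits at the origin with 0–6 lateral glomeruli in an 850×850 µm² field, two
mitral cells per glomerulus with somata 150–350 µm from their glomerulus,
1000 PG cells per glomerulus, and a granule lattice of 2500 cells per
(100 µm)² (2 µm spacing). Each mitral cell forms 10⁴ reciprocal granule
synapses — 80 on the soma, the rest uniform per unit length along the
primary and lateral dendrites — and the granule partner of each synapse is
drawn uniformly from the lattice sites within the granule dendritic extent
(100 µm in each planar coordinate) of the synapse site. Each mitral cell
also forms 100 reciprocal PG synapses, every PG completes 25 mitral→PG
inputs (delays uniform 0–40 ms), PG→mitral delays are exponential with
mean 160 ms, and every PG receives 50 ORN synapses.

A scaling identity constrains this generator: with the synapse count and
granule density fixed, the expected number of granule cells shared by a
mitral pair is (synapses)²/(density × overlap area of the two dendritic
fields), independent of the detailed branch layout and of the selection
window. Reproducing the published shared-granule count (~1200 in a
3-glomerulus default network) therefore fixes the lateral dendritic reach;
the calibrated value is 1650 µm (62 segments of 25 µm per branch beyond a
100 µm trunk), within the ~1–1.5 mm span reported for rat mitral lateral
dendrites. The same calibration lands the aggregated-singles count at ~95
per mitral cell.

**Schemes.** `random` rotates all cells arbitrarily. `directed` aims one
lateral mitral cell's dendrite at alternating central sisters. `default`
adds super-inhibition to each directed pair: 100 extra shared granule cells
chosen from the target's proximal singles and connected to the closest
segment of the directed dendrite; granule→mitral weights of the pair's
shared granules ×4 (and ×4 for all proximal granule→mitral synapses of
lateral mitral cells, standing in for their own unmodeled super-inhibitors);
mitral→granule weights from the source beyond 100 µm path distance ×3.
`slice` is a two-cell default-style network (somata 50 µm apart) with
granule cells farther than 100 µm from the A–B plane discarded.

**Weights.** Granule→mitral strengths start from 1 nS (1.5 nS in
random/directed networks, which lack super-inhibition) and decay
exponentially along the dendrite (length constant 100 µm primary, 150 µm
secondary) and proportionally with diameter. Every synaptic weight is
drawn log-normally with 25% relative SD about its putative value. A weak
auto-inhibitory synapse (5 pS) sits at every reciprocal granule site and is
activated by the host mitral cell's own spike.

**Aggregation.** After pruning unconnected granule cells, singly-connected
granule cells are aggregated 100:1 per mitral cell: each aggregate keeps
one mitral→granule input and emits its group's total inhibitory weight as
10 staggered synapses (exponential extra delays, SD 160 ms), conserving the
summed conductance-time integral exactly; shared granule cells are kept
1:1. Aggregated sites keep their members' 5 pS auto-inhibitory shares.

## Stimuli

ORN input is inhomogeneous Poisson (1 ms dead time) driven by per-glomerulus
rate waveforms: concentration and air-flow series convolved with random
Gaussian kernels (latency-to-peak 150–350 ms, width 250–450 ms,
pre-multiplied to start from zero) plus a constant 0.5 Hz baseline, with an
optional logistic output non-linearity (18/(1+exp(−(r−7.2)))). Kernel
amplitudes are scaled so steady-state respiration-convolved peaks fall in
0.8–3 Hz (air) and 2.4–9 Hz (odor at 1% saturated vapor). The respiration
waveform is the printed three-term dual-exponential expression with period
0.5 s, half-rectified and normalized to unit peak. Pulse-train protocols
gate 50 ms pulses with a 7-bit maximal-length sequence (350 ms per
repetition, phase-rotated per stimulus), filtered by the 40 ms valve time
constant, riding on a constant air pedestal at 1/3 of the respiration peak.

Granule cells receive one background Poisson train each (a proxy for the
many unmodeled mitral cells): 3.45 Hz in vitro, and in vivo 35 Hz modulated
waveform-proportionally by the respiration cycle (the mean stays 35 Hz; the
generator compensates the 1 ms dead time so the realized mean is 35 Hz).
The background synapse carries the mitral→granule AMPA+NMDA weights
(0.2 nS AMPA) and the modulation depth is ±50% of the mean. Both were
settled by a documented exploration: a stronger background weight or
full-depth modulation makes the aggregated-singles inhibition a large,
phase-locked, per-sister-independent noise source that decorrelates the
sisters in every connectivity scheme — including the random control —
which contradicts the reference behavior (only the directed
super-inhibitory scheme should decorrelate).

Inside network simulations the 400 ORN→mitral synapses per mitral and the
granule background use exact pre-generated per-synapse trains; the 50
ORN→PG synapses per PG are sampled as grouped Poisson counts per time step
(the per-train dead-time correction at these rates is below ~1% and is
absorbed by the input calibration).

## Input-strength calibration

As in the reference procedure, synaptic parameters are fixed from the
printed tables and only the glomerular input strengths are adjusted to
match mean mitral firing: a global multiplier on ORN→mitral weights (0.23)
and an independent gain on the air-flow drive (2.4) — air and odor ORN
rates are calibrated independently, exactly as done when matching mean
firing across connectivity schemes. With these frozen values,
freely-breathing default networks give mean central-mitral rates of
~13–14 Hz for odor at 1% saturated vapor and ~7–8 Hz for odorless air.
Non-default schemes reduce the central glomerulus's odor rate (factor 0.8
here) to match the default scheme's mean firing, following the reference's
matching criterion.

At reduced trial counts the delta-rate correlation is biased toward zero by
independent per-trial spike noise (each instance × odor entry is a rate
difference estimated from ~1–4 s of spiking). The scaled decorrelation
check therefore also reports a split-half (Spearman–Brown)
attenuation-corrected correlation, which estimates what the full 8-trial
protocol would measure; the published comparison uses the corrected
value.

## Analyses

Responses are spike histograms: 50 ms bins for pulse trains, 5 bins per
0.5 s cycle for phase analysis (the second cycle of each trial, averaged
over trials). Odor kernels are 2 s long at 50 ms (40 taps), fitted by plain
least squares on the stacked causal-convolution design of the two pulse
trains per odor with a constant column absorbing the air background;
two-odor responses are predicted as the rectified sum of the two fitted
kernels' convolutions. residual/noise divides the mean squared deviation of
a fit/prediction from the trial average by the mean across-trial variance
(SD-based); zero-noise cases yield an infinite-ratio sentinel rather than
an exception. Phase correlations are Pearson r over the 5 cycle bins with
zero/flat responses excluded; the delta-rate correlation strings each
sister's odor-minus-air mean-rate changes across every odor × instance into
one vector. The odor-morph model fits air, pure-odor and 4 morph responses
with shared per-bin representations, a saturation rate, 8
monotonicity-constrained weights (fitted as non-negative increments) and
the printed sigmoid exp(4.39x)/(1+exp(4.39x)); the optimizer is
multi-start least squares with a data-driven initialization that inverts
the sigmoid on the pure responses.

## Problem sizes used by the test suite and acceptance script

The full-scale experiments (50 network instances, 350 sister-pair–odor
combinations) remain available through the protocol parameters. The
package's own verification runs use reduced sizes, chosen as the smallest
that still expose each effect: connectivity statistics over 10 seeds; rate
calibration over 2 instances × 2 trials (acceptance script: 5 × 8);
decorrelation over 10 default instances × 2 odors (2 trials of 3
respiration cycles, with cycles 2–3 analyzed as repeats) against a
3-instance random-scheme reference; pairwise-inhibition asymmetry over 2
two-cell instances; all network runs at a 100 µs step.

## Known limitations

* The reduced 8-compartment tuft saturates under the printed nerve-shock
  volley (both weak and strong shocks drive it near the excitatory
  reversal), so the initiation-site switch (soma-first for weak shocks)
  is not reproduced; strong shocks do initiate in the tuft.
* The model's air/odor mean-rate ratio tracks the ORN drive ratio more
  linearly than in the reference, which is why the air-flow gain is a
  separate calibration knob.
* Release timing uses the somatic spike detector plus fixed delays;
  dendritic conduction delays and spike-failure gating along lateral
  dendrites are not modeled.
* Geometry is planar; granule-layer depth structure is projected out.
* Synthetic ORN drive cannot stand in for real odorant chemistry: passing
  tests demonstrate internal consistency with the model's published
  statistics, not predictions for particular odorants.
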