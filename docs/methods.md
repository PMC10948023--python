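# Methods

`retstim` simulates how subretinal electrical stimulation drives the
retinal network's second-order neuron, the bipolar cell (BC), through to
its synaptic output, and how it directly recruits retinal ganglion cells
(RGCs). The chain is: extracellular field → multicompartment cable →
L-type calcium channel and submembrane calcium in the BC terminals →
stochastic vesicle release from ribbon synapses. This note documents the
models, the numerical choices, the calibration of every quantity that the
underlying biophysics does not pin down, and the known limitations.

## Extracellular field

A stimulating micro-electrode is modeled as an ideal point source in an
unbounded homogeneous medium, V_e = I·ρ_ext/(4πr) with ρ_ext = 1000 Ω·cm
(mid-range retinal resistivity). There is no retina/vitreous boundary;
the analytic form is used as is. Multi-electrode fields superpose
linearly. For field-shape comparisons a uniform field can be constructed
with the same total on-axis voltage drop across the cell's z-extent as
the point source (`matched_uniform_field`). Waveforms are monophasic and
anodic; the cathodic phase of a charge-balanced photovoltaic pulse is
several times longer, lower in amplitude, and roughly 4× less effective,
and is not modeled. Waveforms are sampled piecewise-constant on the
solver grid; the default dt = 0.025 ms divides all standard pulse
durations, so pulse edges land exactly on steps.

## Cable model

Neurons are trees of cylindrical compartments. Each compartment n obeys

    C_n dV_n/dt = −I_ion,n + Σ_j [(V_j − V_n) + (V_e,j − V_e,n)] / (R_j/2 + R_n/2),

with the extracellular potential entering through the axial difference
terms (activating-function coupling) and branch points allowed more than
two neighbors. Specific membrane capacitance is 1 µF/cm²; intracellular
resistivity is 130 Ω·cm (BC) and 143.2 Ω·cm (RGC).

Integration is backward Euler at dt = 0.025 ms. Gates are advanced by
exact exponential (Rush–Larsen) updates evaluated at the previous
voltage; ionic conductances are then frozen for the linear voltage
solve, so each step solves one symmetric positive-definite system
(banded Cholesky after parent-before-child ordering; sparse LU fallback
for morphologies with large bandwidth). This is unconditionally stable
at the default step and first-order accurate; halving dt moves the
terminal potential at a pulse edge by <0.5 % of its deviation from rest
(tested). Gates and calcium start on their resting fixed point
(computed, not assumed) and a 50 ms stimulus-free settling run is
discarded before t = 0.

A divergence guard aborts integration if any potential leaves
[−200, +300] mV by default. Strong-stimulus protocols widen this guard
explicitly (±4 V): the passive polarization of near-electrode dendritic
compartments is linear in current at ≈ −37 mV/µA, so 4–20 µA pulses —
part of the standard protocol grid — lawfully exceed the default band
without any numerical divergence. Calcium is floored at 1e-4 µM: the
continuous equation self-limits through the diverging Nernst potential
when V exceeds E_Ca, but the discrete update can overshoot.

## Membrane mechanisms

**BC.** A leak (g_L = 0.5 mS/cm², E_L = −60 mV = rest) covers the whole
membrane; an L-type calcium channel (g_Ca = 0.5 mS/cm²) sits on the
terminals only. i_CaL = g_Ca·m²·h·(V − E_Ca) with
α_m = 0.21(V+5)/(1−exp(−(V+5)/10.5)), β_m = 0.02·exp((12−V)/12),
h∞ = 1/(1+exp((V+55)/66.4)), τ_h = 292 ms. The activation time constant
peaks at ≈0.85 ms; `act_tau_scale` rescales τ_m pointwise without moving
m∞ (used in the chronaxie sensitivity analysis). E_Ca is recomputed
every step as the divalent Nernst potential from the submembrane
calcium (T = 296.15 K, [Ca]_e = 1800 µM). Submembrane calcium in a
50 nm shell follows d[Ca]/dt = −i_Ca/(2F·d) − ([Ca] − 0.1 µM)/50 ms,
advanced by its exact exponential solution per step. Removable
singularities in the rate functions are evaluated by a 3-term Taylor
expansion within |x| < 1e-4 of the pole. All rates are taken at 23 °C
(room-temperature ex-vivo conditions); no Q10 correction.

**RGC.** The classic five-channel ganglion-cell repertoire (Na, K, Ca,
Ca-activated K with 1 µM half-activation, leak) with section-wise
densities (dendrite/soma/hillock/AIS/axon; e.g. g_Na 50/70/175/350/100
mS/cm²) shipped as an editable CSV. The rate functions use the standard
published forms (e.g. α_m = 6·x/(1−e^(−x)) with x = 0.1(V+30)); E_Na =
+35 mV, E_K = −75 mV. E_L is solved per section at initialization so
that the entire cell rests exactly at −65 mV — a uniform rest carries no
axial current, so it is a true steady state and the zero-stimulus drift
is <1e-7 mV/s.

## Morphologies

Published reconstructions of the modeled cells are not deposited, so the
package ships stylized stand-ins with every dimension config-exposed,
plus a standard SWC reader/writer. The z axis is retinal depth with
z = 0 at the implant plane; the outer plexiform layer (OPL) sits near
z ≈ 10–20 µm.

The default BC (soma 6 µm at z = 25 µm; four 4 µm dendrites reaching
1.5 µm down into the thin OPL band — BC dendrites retract in the
degenerate retina being modeled; a 30 µm × 0.55 µm axon; eight 3×4 µm
terminal boutons) was calibrated once against the published model's two
passive signatures: the terminal charging time constant under a current
pulse (≈0.2 ms; achieved 0.18–0.19 ms) and the uniform-field vs
point-source terminal depolarization excess (~25 %, range 18–31 %;
achieved 28.5 %). These two anchors fix the axon's RC product and the
cell's position relative to the electrode's 1/r curvature; no
release-dependent quantity entered this calibration, and the geometry
was frozen afterwards. The stylized RGC has a 15 µm soma near the
vitreal surface, a 60 µm dendritic field in the IPL, hillock and AIS,
and a 1000 µm axon so that the spike-propagation threshold criterion
(arrival ≥950 µm from the soma) is testable. All compartments are
3–5 µm long.

The stimulation electrode sits on the BC soma's vertical axis, 15 µm
toward the implant (in the OPL). Its exact lateral offset is not
specified by the source; on-axis is the default and the choice is
config-exposed. For RGC runs the same electrode plane (z = 10 µm) is
used, i.e. ≈75 µm below the RGC soma in the stylized retina stack.

## Ribbon synapse

Each BC carries 8 terminals × 10 ribbon synapses; each synapse has 6
release sites of 5 vesicle rows (30 releasable vesicles; 2400 per
cell). Row 1 is the docked/primed **fast pool** (6/synapse), rows 2–5
the **slow pool** (24/synapse). Terminal calcium is converted to
instantaneous release rate constants, applied independently and
stochastically to every occupied slot each solver step. Vacant slots
refill from an unlimited reserve with τ = 1 s (0.5 s in the grating
protocols), and a vacated docked slot is re-primed by row advance from
the nearest occupied row at the same time constant. A vacancy-based
refill means release is exactly conservative per synapse (tested), and
release is rectified by construction — the rate is never negative.

Sampling is event-driven and statistically exact for piecewise-constant
rates: every occupied slot holds a unit-rate exponential threshold on
its pool's integrated hazard, and every vacant slot an absolute
exponential refill time. Per-synapse minima of both schedules make
quiet steps O(n_synapses) instead of O(n_slots), which is what keeps
multi-second Monte-Carlo protocols tractable. One vectorized RNG stream
(spawned from the master seed) drives the population; runs are
bit-reproducible for a fixed seed (tested), and a full enumeration of
the per-site 32-state Markov chain serves as an exact expectation
oracle in the test suite.

**Calcium sensors.** The source model's calcium-to-rate conversion is
not published, only its calibration anchors. A single Hill curve shared
by both pools cannot satisfy the three printed operating points
simultaneously — fast-pool emptying <20 ms with a ~50× transient under
the −60→−10 mV clamp (calcium rising through ~100 µM to ~300 µM),
near-inert slow pool at pulse-train calcium (~10–50 µM), and measurable
threshold release at ~2–4 µM — because the implied log-log slopes
differ by pool. Each pool therefore has its own saturating sensor
(`slow_sensor="shared"` restores a shared sensor with the fixed 40×
fast/slow ratio):

* fast (docked): k = A_f·Ca²/(60² + Ca²), A_f = 0.7596 ms⁻¹;
* slow: k = A_s·Ca²/(300² + Ca²), A_s = 0.008 ms⁻¹.

A_f is the factory calibration: a root-find on the clamp protocol's
transient/sustained ratio (~50×) subject to the ≤20 ms depletion bound
(achieved: depletion 8.3 ms, ratio 49, resting release <1e-4 ms⁻¹).
The fast sensor's n = 2 slope is forced by the anchors at ~2.5 µM
(threshold) and ~100 µM (clamp); steeper sensors (n = 4) make
sub-millisecond thresholds unreachable under the per-synapse release
criterion, shallower ones (n ≤ 1.6) destroy the clamp transient. A_s
was set once against the reported ~80 % synapse occupancy during 10 Hz
trains — the only printed anchor sensitive to the slow sensor's
mid-range — and frozen; the remaining pulse-train, sweep and grating
results then serve as validation, not calibration.

**Known structural misses.** (1) The sustained release rate over
0.5–2 s of the clamp is refill-capped at 30 vesicles/synapse/τ =
0.3 vesicles/ms/terminal, below the reported ≈0.5; the model reaches
0.5 only in the early post-transient phase (~100–300 ms), so the
reported value plausibly refers to that plateau. No rate parameter can
lift the cap. (2) Ten-hertz occupancy settles near ~65 % rather than
80 %: each 4 µA pulse empties the docked row (its rate at train calcium
is pinned high by the clamp anchors) and row advance then drains the
slow rows. Both misses are reported as-is by the acceptance checks.

**Release criterion for thresholds.** The activation criterion is a
mean release of ≥3 vesicles *per ribbon synapse* within the pulse plus
a 50 ms window, averaged over 20 stochastic repetitions. The whole-cell
reading (3 vesicles total across 80 synapses) sits barely above the
resting-release noise floor (~0.8 vesicles per window), yields no
rheobase plateau, and is retained only as an option
(`per_synapse=False`). An alternative calcium-elevation criterion
(terminal calcium exceeding a set level, default 1 µM) is provided; it
undercuts the vesicle criterion most at sub-millisecond durations
(tested).

## Protocols

* **Thresholds / strength–duration.** Bracketing doubles from 0.05 µA
  (failure below 100 µA returns an "inexcitable" result), then bisection
  to 1 % relative tolerance with common random numbers across
  evaluations. The RGC criterion is an action potential reaching the
  axon ≥950 µm from the soma within 3 ms of pulse offset
  (deterministic). Curves use log-spaced durations over 0.1–100 ms
  (13 by default; 10 in the acceptance runs) and the Weiss law is
  fitted in charge space, Q(d) = I_rh·(d + chronaxie), by linear least
  squares — the classical Weiss formulation, robust to the ~30×
  threshold dynamic range; an I-space nonlinear fit is available
  (`method="current"`) and reported alongside. The two conventions
  differ materially on non-ideal curves (chronaxie ≈ 4.2 vs ≈ 2.5 on
  the default BC curve).
* **Chronaxie sensitivity.** S–D curves are re-run with the L-type
  activation τ scaled ×{0.5, 1, 2} or the calcium removal τ scaled
  likewise, on a 0.3–30 ms duration grid (the full 0.1–100 ms grid
  makes the charge-fit intercept noisy at modest repetition counts);
  chronaxie is regressed on the scale. Activation-τ dependence is
  cleanly linear (R² > 0.99, positive slope). The removal-τ slope comes
  out weakly *negative* here (−0.12 ms per scale unit): with this
  package's release sensor, slower extrusion lowers short/mid-duration
  thresholds (post-pulse calcium tail) more than the long-duration end,
  flattening the curve — a direction opposite to the published model
  and a documented limitation of the surrogate calcium-to-rate
  conversion.
* **Pulse trains.** 4 ms / 4 µA anodic pulses at 2–50 Hz plus the CW
  limit, 2 s runs. Metrics: peak terminal V and calcium, steady-state
  calcium oscillation amplitude and floor (max − min within each pulse
  cycle over the final quarter of the run), peak and steady release
  rates (1 ms boxcar bins), oscillatory release rate, vesicles released
  in 1 s, occupancy over the first 2 s, and the charging time constant
  fitted over 1 ms after the first pulse edge.
* **Amplitude × duration sweep.** 2 Hz carrier, 1.5 s runs; maximum
  1 ms-binned release rate per (duration, amplitude). The response is
  non-monotonic in amplitude — above an upper threshold the terminal
  potential overshoots E_Ca during the pulse — and lower/upper
  half-maximum thresholds are extracted per duration.
* **Gratings.** Two identical BCs driven on alternate half-cycles of a
  1 Hz reversal by a 20/50/100 Hz, 4 ms carrier (or gated CW), refill
  τ = 0.5 s, summed release as the model RGC input. The per-half-cycle
  transient is release integrated above the sustained baseline (mean
  rate over the final quarter of the half-cycle). The summed trace
  shows two transients per grating cycle (frequency doubling).

All protocol outputs are seeded and bit-reproducible; the CLI writes
delimited tables plus a JSON run manifest (config snapshot, seed,
version, outputs).

## What the stylized setup does and does not show

Passing tests demonstrate the mechanisms — field-shape effects, calcium
low-pass filtering, synaptic high-pass/rectification, flicker fusion,
adaptation, nonlinear subunit summation — on a stylized morphology
whose free dimensions were matched to two printed passive signatures.
They do not certify absolute thresholds for real cells: thresholds
scale with the morphology's field coupling (and the source's own
thresholds differ ~2× from its reference experiment). Within those
limits the package reproduces the printed RGC/BC chronaxie separation,
the rheobase regime, the polarization comparison, the charging time
constant, the frequency dependence of calcium oscillations, the upper
stimulation threshold, and grating frequency doubling; the two
structural misses above are documented rather than tuned away.

## Reduced problem sizes

Defaults were chosen so a full protocol suite runs on one CPU core:
S–D curves 10–13 durations × 20 repetitions, sensitivity grids
3 scales × 6–7 durations × 8 repetitions, trains 2 s × 6–10 seeds,
sweeps 3 durations × 8–9 amplitudes × 3 seeds, gratings 3 s × 4 seeds.
These sizes leave Monte-Carlo standard errors well inside the assert
bands used by the test suite.
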