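# Model and methods

`isasim` is a conductance-based simulation of the two A-type potassium current
(I_SA) variants found in CA3 CCK+ hippocampal interneurons, and of the firing
phenotypes they produce: regular-spiking (RS) cells, whose I_SA is
right-shifted, fast-inactivating and fast-recovering, and transient-outward-
rectifier (TOR) cells, whose I_SA contains an additional left-shifted, slowly
inactivating, slowly recovering component. The central claim the package
reproduces is that exchanging only the I_SA complement of a model cell —
I_SA_RS against the 3:1 I_SA_RS + I_SA_TOR mixture — converts the firing
phenotype and selectively silences the cell during 8–15 Hz oscillatory drive.

## Channel models

All gated conductances use the Hodgkin–Huxley `g·m^a·h·(V−E)` form with
first-order gates relaxing as `x(t) = x_inf + (x0 − x_inf)·exp(−t/tau)`.
I_SA steady states are single Boltzmann functions; inactivation time constants
`tau_h(V)` are monotone-cubic (PCHIP) interpolations through anchor points,
clamped outside the anchored range; the activation time constant is fixed at
1 ms (fast relative to every measured phenomenon). E_K = −90 mV, E_Na =
+60 mV. Temperature scaling is omitted: all kinetics refer to the 34.5–36 °C
recording temperature.

### Measured values are procedure outputs, not channel parameters

The experimental kinetic numbers (recovery time constants 58.2/46.2/29.8/4.4 ms
for TOR cells and 11.8/8.0/7.1/3.3 ms for RS cells at −65/−75/−85/−120 mV;
inactivation decay 71.2 and 18.8 ms at −25 mV; availability midpoints −64.5 and
−57.4 mV) were produced by a concrete measurement procedure: whole-cell clamp
with ~2.8 MΩ uncompensated series resistance, a −50 mV control-trace
subtraction, current-area analysis and exponential fitting. The package
simulates that procedure faithfully, and therefore calibrates the *channel
level* parameters by fixed-point iteration until the *simulated procedure*
returns every measured value (to ~2%). The measured values are retained in
`channels.py` as `*_MEASURED` calibration targets; the calibrated channel
anchors differ from them by up to ~12% at individual voltages, which is
exactly the size of the series-resistance and subtraction biases.

Two further channel-level choices fill gaps the measurements leave open:

* **TOR activation (whole-cell profile).** Constrained by (i) the activation at
  −40 mV, calibrated once so the TOR-configured whole-cell simulation
  reproduces the measured 683 pA peak I_SA, and (ii) a small conductance foot
  (0.02) at −52 mV so the standing current near rest is negligible. The
  resulting steepness (k ≈ 2.5 mV) is an effective-model parameter: real Kv4
  activation is fourth-order (m⁴), and the foot of an m⁴ conductance curve
  whose per-gate slope is ~10 mV rises with an effective steepness of
  k/4 ≈ 2.5 mV. A first-order gate with a conventional ~10 mV slope at the
  same −40 mV anchor would place a large standing conductance across the whole
  subthreshold range and silences all oscillatory firing — quantitatively
  wrong in a way the steep effective curve is not.
* **Closed-state inactivation.** Between the recovery measurements
  (−65 mV and below) and the decay measurement (−25 mV) no time constant is
  printed. The TOR variant carries a notch there (40 ms at −55 mV, 60 ms at
  −45 mV), reflecting the hallmark Kv4 behaviour of faster inactivation from
  subthreshold closed states than either near-midpoint recovery or open-state
  decay. Functionally, the notch lets slow (1–6 Hz) depolarising ramps shed
  I_SA availability before threshold is reached, while fast theta-band rises
  do not.

The RS inactivation slope shares the TOR value (6.59 mV, solved from the
91.3% availability at −80 mV): the two printed RS points (V½ −57.4 mV and
52.7% at −60 mV) lie 2.6 mV apart and cannot identify a slope, and the same
Kv4.3 pore underlies both currents. Nucleated-patch activation profiles
(V½ −16.4/−8.9 mV, slopes solved from the printed activation at −40 mV) are
shipped as the `nucleated` presets and used for nucleated-patch simulations
(conductance and charge densities 1.91/3.86 nS/pF, 0.47/0.21 pC/pF targets);
an `hptx` preset carries the HpTX-sensitive component's inactivation values.
Heteropodatoxin block is modelled as the measured depolarising shift of
activation V½ (+12.4 mV TOR, +21.5 mV RS).

### Core spiking set

The non-I_SA conductances are a transient Na⁺ current (instantaneous m³,
V½ −31 mV, k 5 mV; h with V½ −45 mV, k 5 mV, τ 4 ms), a delayed-rectifier K⁺
current (n⁴, V½ −20 mV, k 8 mV, τ 0.4 ms), a slow adaptation K⁺ current
(V½ −25 mV, k 5 mV, τ 100 ms) and leak. The steep, right-placed Na activation
keeps the subthreshold Na window small — a prerequisite for a few hundred pA
of I_SA to hold off firing — while preserving a sharp upstroke. Densities
(soma/dendrite, S/cm²: Na 0.30/0.02, KDR 0.30/0.05, adaptation
1e-3/0.33e-3) were tuned once against the measured RS phenotype: AP threshold
≈ −37.5 mV at the 50 mV/ms slope criterion, half-width ≈ 0.4 ms,
spike-frequency accommodation, and 10–20 Hz firing under standardized steps.
The leak reversal is solved per compartment class so the core-equipped cell
rests at −64.7 mV; because the solution excludes I_SA (the phenotype switch
must leave every non-I_SA parameter bit-identical), the full-set equilibria
sit within ~1 mV of −64.7 mV and differ slightly between configurations.

## Morphology stand-in and area calibration

Reconstructed morphologies are not available as data. The stand-in is a
cylindrical soma (32 × 32 µm) with four unbranched dendrites (407 µm long,
5 µm diameter, ≤20 µm per segment; 85 compartments; total area ≈ 28 800 µm²,
electrotonically compact at ~0.4 λ). Passive parameters sit in the fitted
ranges (cm 1.015 µF/cm² default, g_leak 5.4e-5 S/cm², Ra 120 Ω·cm). The
template's total area and the activation working points were calibrated
jointly so that the simulated whole-cell activation protocol returns the
measured peak I_SA at −40 mV: 148 pA for the RS configuration (working point
0.0215 at −40 mV, inside the printed nucleated range) and 683 pA for the TOR
configuration. I_SA densities follow the published per-configuration table
(RS: 297e-5 soma / 99.1e-5 dendrite; TOR mixture: 128e-5 + 44e-5 soma,
42.7e-5 + 14.7e-5 dendrite, S/cm²; somatic:dendritic ratio 2.96:1).
Cell-to-cell variability: per-seed density jitter using the printed spreads as
coefficients of variation, and ±20% uniform jitter of all stand-in dimensions.

## Numerics

Backward-Euler integration of the branched cable (Hines elimination on the
tree) with analytic (Rush–Larsen) gate updates between voltage steps, the
standard staggered scheme; dt = 25 µs. All voltage-dependent gate quantities
are pre-tabulated on a 0.05 mV grid and linearly interpolated inside a numba
kernel. Synapses are biexponential conductances (excitatory 0.5/3 ms, E =
0 mV; inhibitory 1/8 ms, E = −70 mV — unprinted, typical for the measured
event amplitudes) implemented as per-compartment state pairs so events sum
linearly. Voltage clamp attaches an electrode conductance 1/Rs at the soma
(whole-cell Rs 2.76 MΩ uncompensated; nucleated 5 MΩ at 95% compensation).
I_SA is isolated exactly as in the experiments: every clamp run is repeated
with I_SA zeroed and electrode currents subtracted; the recovery protocol
additionally subtracts the −50 mV control traces. Steady states (resting
potentials, holding currents) come from damped fixed-point iteration on the
linearised cable (a backward-Euler step with dt → ∞). The integrator is
verified against closed-form oracles: passive RC charging (<0.5%), gate
relaxation under ideal clamp (<0.1%), charge conservation (<0.5%), and
dt-halving convergence (<0.1 mV RMS on subthreshold responses).

## Protocols

* **Activation:** 300 ms conditioning at −120 mV, 300 ms steps (−120…−20 mV
  whole-cell; −100…+70 mV nucleated), 100 ms test at −30 mV. Peak conductance
  normalises the peak current to the driving force (V + 90 mV); the −90 mV
  point is excluded. Decay time constants from single-exponential fits from
  the peak.
* **Steady-state inactivation:** test-pulse peaks after 300 ms prepulses
  (−100…−35 mV), normalised to maximum, Boltzmann-fitted with free amplitude
  and baseline.
* **Recovery:** −120 mV 345 ms, −30 mV 500 ms, recovery step (−65/−75/−85/
  −120 mV) of 1–233 ms (12 log-spaced intervals), −30 mV test; current *area*
  versus interval, single-exponential fit, R² < 0.9 flagged.
* **MP dependence of firing:** a standardized current step (bisection to the
  smallest 20 pA-grid amplitude reaching ≥12 Hz from −60 mV — the low side of
  the 10–20 Hz window, mirroring near-rheobase standardized steps) applied as
  an *absolute* amplitude after 3 s holding at each prepulse potential; only
  the holding current varies between trials. Spikes at the 50 mV/ms slope
  criterion with 2 ms merging; delays measured from step onset.

The TOR kinetics round-trips run on the I_SA_TOR component at its component
density (44e-5/14.7e-5 S/cm²): at that density the simulated currents match
the real cells' magnitudes and hence their series-resistance bias. The pure
variant at the full 1.72 mS/cm² would triple the currents and corrupt the
measured kinetics with clamp artifacts the experiments did not have.

## Oscillatory drive

Excitatory events arrive in one Gaussian package per cycle. The
frequency-dependent width rule evaluates
`(1000/f)·0.633 + 69.25112·0.67747^f + 1000/f`; the last term is the package
period, the first two terms are read as the ±3σ extent of the package
(σ = width/6), which keeps the subthreshold membrane potential sinusoidal at
every frequency. A literal reading (all events at a fixed lag within the
cycle) is available behind `eq1_literal`. Event amplitudes: excitatory
normal(0.22 nS, variance 0.01 nS²), inhibitory normal(2 nS, variance
0.1 nS²), truncated at zero; targets uniform over compartments; inhibitory
times uniform over the duration. Simulations run 20 cycles or at least 5 s.

Inhibition scales with excitation — one inhibitory event per 20 excitatory
events (`INH_PER_EXC_EVENT = 0.05`) — producing a balanced, high-conductance
background whose shot noise makes firing probabilistic per cycle. This ratio
was chosen once so the driven mean membrane potential stays near rest and
output rates remain below ~50 Hz across the swept strengths. With a fixed low
inhibitory rate the 4–10 Hz output regime exists only at razor-thin
suprathreshold margins, where any added conductance abolishes all spikes and
no band structure can appear.

The silencing experiment pairs runs: one seeded train per (cell, frequency,
strength, repeat) condition is played into the same cell in RS and in TOR
configuration; per-pair percentage rate reduction is averaged per input band
(1–6, 8–15, 25–100 Hz) over conditions whose baseline (RS) output falls in
4–10 Hz. Sub-seeds derive deterministically from the global seed and the
condition indices. Desk scale: 3 stand-in cells × 3 train seeds × 6 strengths
(150…1500 events/package) × 10 frequencies (2–100 Hz), ≈ 12 min on one CPU.

## What the stand-ins do and do not show

The generator emulates the *statistical structure* of the study — calibrated
current amplitudes and kinetics, package-structured drive, cell-to-cell
parameter scatter — not the real reconstructions or recordings. Passing tests
show the pipeline recovers what it puts in (parameter recovery at 10 pA noise:
availability V½ to <1 mV, recovery τ to <10%) and that the biophysical
mechanism (availability dynamics of the TOR component) produces band-selective
silencing with the correct ordering in every simulated cell. They do not show
that real CCK+INs carry exactly these parameters.

## Known limitations

* The TOR onset delay from −80 mV holding is ~80–120 ms against the measured
  252 ± 15 ms. The delay grows only logarithmically with the ratio of
  available I_SA to the step's suprathreshold margin, and configurations that
  lengthen it (smaller cells, weaker background conductance) push the
  oscillatory-drive comparison into a regime where all bands saturate at 100%
  spike loss. The package keeps the band-selective headline and the
  qualitative delay phenotype (TOR 2–4× slower from −80 than from −60 mV; RS
  unchanged).
* The 1–6 Hz band reduction averages ~35–40% against the reported 9.8%:
  marginal low-frequency cycles fire through fluctuation-driven spikes on the
  early package flank, where TOR availability is still high. High-output
  1–6 Hz conditions do show the reported ~5–15%.
* The measured probability-of-early-AP curve collapses only when delays exceed
  the 150 ms analysis window; with the shorter model delays that curve is
  nearly flat and its Boltzmann fit is not meaningful.
* The RS nucleated charge density under-predicts (≈0.08 vs 0.21 pC/pF); the
  printed RS working point and decay kinetics cannot integrate to the printed
  charge at the printed conductance density.
* Axons, synaptic release, CB1 signalling and temperature scaling are out of
  scope.
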