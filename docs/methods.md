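# Methods

## Model neuron

The cell is a single-compartment Wang–Buzsáki-type fast-spiking neuron:
transient Na⁺ (gNa = 35 mS/cm², ENa = 55 mV) with instantaneous activation
m∞ and first-order inactivation h; delayed-rectifier K⁺ (gK = 9 mS/cm²,
EK = −90 mV) with first-order activation n; passive leak (EL = −65 mV);
Cm = 1 μF/cm². Gate kinetics are scaled by the dimensionless factor φ = 5,
the canonical value for this model family. This cell type was chosen
because it fires sustained, temporally precise trains over a wide input
range — the firing mode of the sustained-firing IC neurons the model is
meant to emulate — and because its parameters are fully published.

The leak density gL is the model's knob for neuron-to-neuron diversity in
input resistance. For a spherical soma of diameter d (default 15 μm,
surface A = πd²), R = 1/(gL·A): the sweep densities 0.282, 0.50, 0.75,
1.99 and 5.3 mS/cm² correspond to 502, 283, 189, 71 and 27 MΩ, and the
reference cell (0.7 mS/cm²) to ~200 MΩ. The sphere-surface convention
A = πd² is the only one consistent with all of these round-numbered
resistances simultaneously.

The removable singularities of αm (V = −35 mV) and αn (V = −34 mV) are
evaluated by a second-order series branch for |argument| < 10⁻⁷, which
keeps the rates finite and continuous across the singular points.

## Synapse

Two conductances with reversal Esyn = 0 mV drive the cell:

* AMPA: τ_rise = 0.2 ms, τ_decay = 2 ms — fast kinetics typical of
  auditory neurons.
* NMDA: τ_rise = 5 ms, τ_decay = 100 ms, peak fixed at 25% of the AMPA
  peak. To mimic GluN2C/D-containing receptors the NMDA conductance
  carries **no Mg²⁺-block voltage dependence**: Isyn = (gA+gN)·(V−Esyn)
  with instantaneous V. The decay sits at the slow end of the 10–100 ms
  range reported for recorded GluN2D-mediated currents.

Each input pulse contributes g_max·N·(1−e^{−t/τ_rise})·e^{−t/τ_decay} with
N chosen analytically so a single pulse peaks exactly at g_max (peak time
t* = τ_rise·ln(1+τ_decay/τ_rise)). The double exponential is a difference
of two pure exponentials, so waveforms are evaluated *exactly* on the
integration grid by a one-pole recursive filter seeded with each pulse's
fractional-onset decay factor — O(steps) regardless of pulse count, and
independent of where onsets fall relative to the grid.

Two summation modes exist. `conductance_waveform` sums pulses linearly,
which is correct for well-separated events and is what the waveform-
analysis fixtures use. The default drive (`saturating_waveform`) models a
finite receptor pool: each pulse is scaled by the headroom 1 − g/g_max at
its onset and the gating is capped at g_max. The distinction matters: with
an unbounded linear sum, the slow NMDA term grows without limit at high
input rates, and for *any* decay constant in the plausible range the
accumulated conductance drives every cell — leaky or not — into
depolarization block, erasing the additive-gain regime and the onset spike
alike. With bounded gating the NMDA tonic level tops out near g_max and
the two observed regimes separate cleanly by membrane resistance (below).

## Calibration of synaptic strength

The physiologically meaningful regime has single inputs subthreshold
(EPSPs) and summed trains suprathreshold. Because the threshold
conductance depends strongly on gL (leaky membranes integrate a fast pulse
poorly), the AMPA strength is recalibrated per leak value: bisection finds
the threshold g_single at which a single AMPA-only pulse first spikes
(relative tolerance 10⁻⁴), and the default strength is 0.98·g_single,
validated to make a 1 s, 16 Hz AMPA+NMDA train fire. The near-threshold
placement is deliberate: in leaky cells the onset response requires the
train-onset transient to cross threshold before Na⁺ inactivation
accumulates, and strengths far below threshold lose that onset spike
(yielding silence instead of the one-spike-per-train collapse).

## The sweep experiment and its regimes

`run_sweep` crosses a geometric frequency grid (default 16–512 Hz, 4
steps/octave, 21 frequencies, both endpoints) with the two synaptic
conditions (AMPA-only rows force the NMDA ratio to 0) and a list of leak
values; trains last 1 s and each grid cell yields firing rate, spikes per
train, vector strength, and mean phase. The model is deterministic, so
repetitions default to 1; an optional zero-mean current-noise source
exists but is off by default. With the calibrated defaults:

* High-resistance cells (gL ≤ 0.75): the NMDA conductance adds firing at
  every frequency (additive gain, an upward shift of the rate MTF), while
  phase locking in the AMPA+NMDA condition degrades as input rate grows.
* Leaky cells (gL = 1.99, 5.3): the NMDA conductance drives depolarization
  block at fast trains; the rate MTF collapses to exactly one onset spike
  per train — never zero — and `classify_response` labels the profile
  "onset" when the whole top octave sits at one spike per train.

Vector strength is computed only when a train elicits more than 4 spikes
(strictly N ≥ 5); fewer spikes yield an explicit *undefined* flag rather
than 0, since a near-empty train carries no usable phase information.
Phase 0 is each input-pulse onset.

## Spike detection and response metrics

Spikes are upward crossings of 0 mV with a 1 ms refractory lockout and
linearly interpolated crossing times; 0 mV is unambiguous for the
full-height action potentials of this model. Evoked and spontaneous rates
are means of per-window rates over stimulus and quiet windows; dynamic
range is max − min of a rate MTF.

## Waveform analysis

Events are fit by least squares to
f(x) = y0 + amp·(1−e^{−(x−x0)/τ_rise})·e^{−(x−x0)/τ_decay} (zero before
onset), with bounded parameters and data-driven initialization (baseline
mean, extremum amplitude, τ_rise = 1 ms, τ_decay from time-to-half-decay).
Non-convergent or flat-trace fits raise rather than return degenerate
parameters. Direct measurements define amplitude as extremum − baseline
mean, halfwidth between the half-amplitude crossings flanking the peak,
rise time as the 10–90% interval (configurable to 20–80%), and decay τ by
a log-linear single-exponential fit from the peak down to 10% of the
amplitude — conventions chosen because each is testable against traces
generated from the template. Sweep averaging is a pointwise mean. Train
summation reports per-peak amplitudes from the *pre-train* baseline
(window k = [onset_k, onset_{k+1}), the last extended by one inter-pulse
interval) and the trapezoidal area under (trace − baseline). An optional
zero-phase Butterworth low-pass stage is provided; synthetic tests run
unfiltered.

## Expression tabulation

A cell is positive for a channel when ≥ 1 punctum co-localizes with its
tdTomato signal. Summaries count tdT⁺, Glun2d⁺, Glun2c⁺, double-positive,
single-positive and negative cells per grouping (overall, mouse, or IC
subdivision), with percentages relative to the group's tdT⁺ count, rounded
half-away-from-zero to one decimal — the rounding that reproduces all
published percentages from their counts. tdTomato-negative rows are
retained but excluded from denominators. `fixture_from_counts` expands
marginal counts (tdT⁺, 2d⁺, 2c⁺, both) into a minimal per-cell table whose
summary reproduces the marginals exactly; the packaged published per-slice
and per-subdivision marginals partition the same 521 cells.

## Synthetic data

* Phase-locked spike trains: an inhomogeneous Poisson process with von
  Mises intensity, λ(t) = rate·e^{κcos(2πft−φ)}/I₀(κ), realized by
  thinning a homogeneous process — exact, seedable, with κ mapping
  monotonically onto vector strength via VS = I₁(κ)/I₀(κ) (inverted
  numerically; evaluated with exponentially scaled Bessel functions to
  avoid overflow).
* Event traces: the exact forward model of the fit template plus iid
  Gaussian noise, so noiseless generation/fitting is an identity.
* Marker tables: a multinomial class draw per cell with puncta counts
  1 + Poisson(2) on positive channels, 0 otherwise.

What the generators do **not** emulate: spike-history dependence
(refractoriness, adaptation) in the point process, correlated or
non-Gaussian recording noise, series-resistance and filtering artifacts,
and biological clustering of marker expression by slice or animal. Tests
passing on these synthetics therefore validate the estimators'
correctness, not their robustness to every artifact of real recordings.

## Numerics

Integration is fixed-step classical RK4 (default dt = 0.01 ms) with
conductances and applied currents sampled on a half-step grid; the inner
loop is numba-compiled. At the default step, halving dt changes no spike
count and moves spike times by well under 0.1 ms, gating variables remain
in [0,1] to within 10⁻⁹, and with the active conductances removed the
trace matches the analytic RC solution to 10⁻⁶ relative error. The initial
state is the resting state obtained by root-finding the full steady-state
I–V relation below −40 mV (h, n at their steady states), so simulations
begin free of onset transients. Non-finite voltages abort integration with
an error naming the failure time.

## Problem sizes

The shipped test suite runs the full sweep — 21 frequencies × 2 conditions
× 6 leak values (the five sweep densities plus the 0.7 reference), 1 s
trains at dt = 0.01 ms, with per-leak calibration — plus a 200-replicate
noise-recovery study for the event fit; the complete suite finishes in
well under a minute on one core after JIT warm-up.

## Known limitations

* Single compartment; no dendritic filtering or synapse placement.
* No low-voltage-activated K⁺ or other subthreshold conductances, which
  could convert the depolarization-block onset response into phasic
  firing; sustained-firing cells are the modelling target.
* The NMDA conductance omits Mg²⁺ block entirely (GluN2C/D idealization)
  rather than implementing a weak voltage dependence.
* No short-term plasticity or stochastic vesicle release; the saturating
  gating is a receptor-pool bound, not depression.
* Synaptic kinetics and strength are calibrated/chosen, not measured; the
  sweep's conclusions are qualitative regime properties, not curve fits.
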