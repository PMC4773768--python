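# Methods

## The model

A peripheral nerve is modelled as a bundle of myelinated axons: one central
axon surrounded by `N` neighbours (default `N = 6`, matching the typical
packing seen in cross-sectional SEM of amphibian sciatic nerve).  Each axon
is a chain of `n_nodes` nodes of Ranvier joined by passive internodal
resistances `R_i`; internodes carry no leak of their own, so the circuit
granularity is one RC node per node of Ranvier.  Each node consists of a
capacitance `C` in parallel with four ionic branches — sodium, fast
potassium, slow potassium and leak — each an Ohmic conductance `g_x` in
series with a battery at its Nernst potential `e_x`, gated by a threshold
switch.

The nodal state equation (voltages mV, currents uA, times ms) is

    C_i dV_i/dt = I_axial,i + I_ephaptic,i − I_ion,i + I_stim,i
    I_ion,i     = Σ_{x open} g_x (1 + γ) (V_i − e_x)

### Demyelination

The demyelination factor γ ∈ [0, 1) is the fractional loss of myelin
thickness, `γ = (D0 − D)/D0`.  Thinner myelin exposes more conducting
membrane and narrows the dielectric gap, so every passive nodal element is
scaled multiplicatively: conductances as `g·(1 + γ)` (ionic resistances
`1/(g(1 + γ))`) and the nodal capacitance as `C·(1 + γ)^p`.  The exponent
`p` is configurable (`capacitance_gamma_exponent`) and defaults to 1 — the
same uniform scaling as the conductances.  Both effects slow conduction:
the leakier, more capacitive node takes longer to charge its downstream
neighbour to the sodium threshold.

### Gating semantics

The branches are threshold switches, not Hodgkin–Huxley gating variables: a
branch opens the first time its nodal voltage crosses its threshold `vth_x`
upward, conducts for a fixed open duration (defaults: Na 0.3 ms, fast K
1.0 ms, slow K 2.0 ms), then closes and is refractory for 3 ms.  These
durations control the spike shape and are configurable in the `gating`
config section.  A branch whose threshold lies at or below the resting
potential is statically open; the leak branch defaults to
`vth_leak = resting potential = −70 mV`, i.e. always conducting — the
conventional resolution of a leak that is formally listed with a threshold.

### Ephaptic coupling and alignment

Neighbouring axons interact non-synaptically through the shared
extracellular resistance `R_o`.  The coupling term injected into node `i`
is `α Σ_j (V_j − V_i)/R_o`, summed over the nearest node `j` of each
coupled axon, with star topology (centre ↔ each neighbour).  The alignment
factor `A ∈ [0.5, 1]` staggers the neighbours' node positions by
`(1 − A)·L`: `A = 1` is exact registration, `A = 0.5` even staggering by
half an internode; the nearest-node pairing used by the coupling follows
from these positions.  With identical axons, `A = 1` and simultaneous
stimulation the coupling term vanishes by symmetry, and `α = 0` decouples
the bundle exactly — both limits are regression-tested.

### Channel block

Neurotoxin blockade of the voltage-gated channels is phenomenological: a
block fraction β ∈ [0, 1] multiplies the three gated conductances by
`(1 − β)`, leaving leak and all potentials untouched.  Blockade depresses
the spike peak (and, at high β, stops propagation) while affecting latency
far less than demyelination does — the qualitative signature seen in
distal-amplitude reduction without latency change.

## Numerics

With switch flags frozen the circuit is linear, so integration is backward
Euler on the linear system (unconditionally stable; the nodal time
constants during the sodium upstroke are ~20 us, two orders below the
internodal delay).  The step is event-resolved: scheduled branch closings
and stimulus edges cap each sub-step so they occur exactly at step
boundaries, and upward threshold crossings detected inside a trial sub-step
are located by linear interpolation, the sub-step re-solved up to the
earliest crossing before the branch opens.  Event times (and hence
conduction timing) are therefore resolved well below the nominal `dt`; at
the default `dt = 0.005 ms`, halving `dt` moves the simulated velocity by
≈0.7 %.

Conduction velocity is the node-position difference divided by the
difference of first sodium-threshold crossing times between two window
nodes, excluding the stimulated node and the terminal node (edge effects);
a least-squares slope of position versus crossing time over the window is
exposed as an alternative estimator and agrees with the two-point value on
linear crossing profiles.  Positions in mm and times in ms make the ratio
numerically m/s.

Degenerate inputs fail loudly: non-finite voltages raise a numerical
instability error naming `dt`; a wave that never reaches the distal window
node raises a propagation-failure error (expected at extreme γ or β; the
`raise_on_failure=False` escape returns NaN velocities so sub-threshold
distal peaks can still be measured); equal crossing times raise a
degenerate-measurement error.

## Parameters

The published source for this class of model does not print its nodal
constants, so the packaged defaults are surrogate values chosen once at
amphibian node-of-Ranvier scale and recorded in `defaults.yaml`
(conductances mS, potentials mV, lengths mm, resistance kOhm,
capacitance pF):

| parameter | default | rationale |
|---|---|---|
| g_na, g_kf, g_ks, g_leak | 6e-4, 1.2e-4, 6e-5, 2e-5 mS | nodal conductance scale of an amphibian node (~0.1–1 uS), Na dominant |
| e_na, e_k, e_leak | +50, −90, −70 mV | textbook amphibian Nernst potentials |
| vth_na; vth_kf/ks | −50; −30 mV | spike threshold ~20 mV above rest; K branches recruited during the upstroke |
| R_i | 15 MOhm/internode | axoplasmic resistance of a ~10 um axon over a 2 mm internode |
| C | 11 pF | effective nodal + paranodal capacitance; sets the baseline velocity near the normal toad sciatic value (~32 m/s) |
| L | 2 mm | amphibian internode |
| n_nodes | 21 | 40 mm of nerve: long enough for a steady travelling wave with edge margins |
| α, R_o | 0.05, 5 MOhm | weak sub-threshold ephaptic interaction |
| stimulus | 0.05 uA, 0.1 ms, 1 Hz | supra-threshold pulse at node 0 of every axon (whole-nerve shock) |

Because these are surrogates, every quantitative result carries the config
digest in its provenance, and `calibrate_baseline` anchors the model to a
measured healthy velocity by bisecting a single knob — the internodal
length, to which velocity responds monotonically and almost linearly —
rather than refitting the whole parameter set.  Uncalibrated, the defaults
conduct at 31.97 m/s; calibration to 32.1 m/s needs a length scale of
1.002.

## Quantification

* `gamma_from_thickness(d0, d) = (d0 − d)/d0`, with `delta_d = d0 − d`;
  summaries report two decimals (the raw value is always retained), and a
  thickness above baseline raises an error unless explicitly clamped.
* `ncv_curve` evaluates one simulation per grid point (default 13 points on
  γ ∈ [0, 0.6]) and refuses to construct a non-strictly-decreasing table,
  so `gamma_from_ncv` — monotone piecewise-linear inversion, exact at the
  knots — is always well posed.  Piecewise-linear rather than spline
  interpolation guarantees monotone invertibility.  The curve reports the
  central axon's velocity.
* `replicate_stats` uses the sample SD (n−1 denominator).

## CAP analysis

Peaks are the global maximum of each channel after an artifact-blank window
(default 0.3 ms; positive-up sign convention keeps the biphasic trough out
of the search), refined by a three-point quadratic fit so latency
resolution is finer than the sample spacing.  Latency is the peak-to-peak
shift; NCV is electrode distance over latency.  No filtering is applied by
default; an optional moving-average window exists for noisy traces (the
flat peak top of a noisy signal otherwise biases raw amplitude maxima
upward).  The block index is `1 − (a_dist/a_prox)/baseline_ratio`, clamped
to [0, 1] with a flag, and is invariant to a common gain on both channels.
The sampling rate is never assumed: the file format requires it in the
metadata sidecar.

## Synthetic data

The generators supply every input format with programmed ground truth, all
deterministic given a seed:

* CAP recordings: a biphasic raised-cosine template (positive main lobe,
  0.35-amplitude after-lobe) per channel, the distal copy delayed by the
  programmed latency, plus i.i.d. Gaussian noise per channel.  The after-
  lobe vanishes near the main peak, so the noiseless maximum sits exactly
  at the programmed centre.
* Thickness tables: replicates `d0(1 − γ_true)(1 + cv·z)`, `z` standard
  normal, non-positive draws resampled so the replicate count (default 6)
  stays exact.
* Dose series: thickness loss follows the hyperbolic saturation law
  `Δmax·c/(c50 + c)` — fast initial rise, plateau — plus additive noise.

What the generators do **not** emulate: real CAPs are population sums with
dispersive, asymmetric waveforms, correlated noise and stimulus artifacts;
real SEM thickness scatter need not be Gaussian or unbiased.  Passing
round-trip tests therefore demonstrates the correctness of the measurement
pipeline on its stated signal model, not robustness to every property of
instrument data.

## Problem sizes

The default test and example workloads use the 7-axon, 21-node bundle with
`dt = 0.005 ms` over 6 ms (≈0.4 s per simulation), 13-point curves, and
100-seed Monte-Carlo batches for the signal round trips — sizes at which
every quantity reported here is reproduced from scratch in a few minutes on
one CPU.

## Known limitations

* Threshold-switched branches reproduce propagation and its γ/β dependence
  but not detailed spike shape, accommodation or repetitive-firing
  behaviour; no temperature dependence or channel noise.
* The ephaptic functional form (difference coupling through `R_o` with gain
  α at nearest-node pairing) is a modelling decision; the source class of
  models does not print its coupling term.
* The velocity–γ relation is realized by simulation, not a closed form, and
  its absolute scale at γ > 0 is steeper or shallower depending on the
  surrogate constants; only the baseline is calibrated.  Published in-vitro
  velocities at specific doses are treated as rank-order references, not
  point targets.
* Per-axon heterogeneity (different γ per axon) is supported by the API but
  the shipped defaults treat the bundle as homogeneous.
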