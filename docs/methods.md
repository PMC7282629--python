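# Methods

## The model in brief

`silentwm` implements a functional spiking-neuron account of visual working
memory in which information is *encoded* by firing but *maintained* in
activity-silent synaptic state. Two independent modules — one per visual
hemifield — each contain four leaky integrate-and-fire (LIF) populations:

| population | neurons | dims | intercepts | role |
|---|---|---|---|---|
| sensory | 1000 | 24 | U(0.01, 0.1) | encodes the 128×128 image through Gabor filters |
| memory | 1500 | 24 | U(0.01, 0.1) | recurrent, with calcium-kinetics STSP |
| comparison | 1500 | 4 | U(0.01, 1) | receives (sin 2θ, cos 2θ) from both streams |
| decision | 1000 | 1 | U(−1, 1) | integrates the signed orientation difference |

Membrane constants are τ_rc = 20 ms and τ_ref = 2 ms everywhere; maximum
rates are drawn from U(200, 400) Hz; the simulation step is 1 ms. The
positive intercepts of the sensory and memory populations mean those
neurons fire only when driven — with no input the network is exactly
silent, which is what makes the maintenance demonstrably activity-silent
in a deterministic simulation.

### Visual code

Stimuli are sine-wave gratings (spatial frequency 0.034 cycles/pixel,
hard circular aperture of diameter 128, luminance mapped so the grey
background is 0 on a [−1, 1] scale). A bank of 1000 randomized Gabor
filters per module provides the sensory encoders. The representational
basis W is the top 24 right-singular directions of a matrix T whose rows
are the canonical task gratings (1° orientation steps × two quadrature
phases, which span every phase) and the Gabor filters, all rows
normalized to unit length. Images encode as v = s·W′·pixels with the
scale s fixed so a full-contrast grating has unit norm. The task-neutral
impulse stimuli are deliberately *not* part of T; their representation is
whatever overlap they have with the memoranda's code. A consequence the
experiments rely on: the black bull's-eye (same spatial frequency as the
gratings, twice their contrast) projects strongly (norm ≈ 1.4) while a
uniform white disc barely registers (norm ≈ 0.14) because the Gabor bank
is nearly mean-free.

Orientation is read out as (sin 2θ, cos 2θ). Doubling the angle maps θ
and θ+180° — pixel-identical stimuli — to the same point, and the ratio
of the pair carries the orientation independently of response amplitude.
The comparison stage's output connection computes
d = sin 2θ_s·cos 2θ_m − cos 2θ_s·sin 2θ_m = sin(2(θ_s−θ_m)), monotone in
the difference over ±45°, which covers the tasks' largest difference
(42°); its sign encodes clockwise versus counter-clockwise.

Orientations are canonicalized into (−90°, 90°] (on a nano-degree grid)
*before* the phase is applied along the canonical axis; this makes the
θ ↔ θ+180° pixel identity exact for every phase, which a literal
sine-wave parameterization cannot achieve.

### Short-term synaptic plasticity

Each memory neuron carries resources x ∈ [0, 1] (transmitter) and
utilization/calcium u ∈ [U, 1]. Between spikes both relax exponentially
(x → 1 with τ_D = 0.2 s, u → U = 0.2 with τ_F = 1.5 s), integrated with
exact per-step exponentials (unconditionally stable at any step size).
At a spike, calcium jumps first, u ← u + U(1−u), and the released
fraction is r = u⁺·x⁻ — the post-influx calcium acting on the resources
available *before* depletion — after which x ← x − r. Synaptic
transmission on the recurrent connection scales each presynaptic spike by
r normalized by the rest-state release U(2−U), so a long-rested synapse
transmits with its baseline weight. This ordering matters: scaling by the
post-spike product u⁺x⁺ = u⁺(1−u⁺)x⁻ is non-monotone in calcium (a
facilitated synapse at u ≈ 0.55 would transmit exactly as much as a
rested one), which silently destroys pattern completion. Because the
modulation depends only on the presynaptic neuron, scaling the spike
before the factored decoder→encoder product transmits exactly what the
full weight matrix w_ij = (u_i x_i / U)·w⁰_ij would; a test checks this
equivalence against an explicitly materialized matrix.

### Recurrent connection and reactivation

The memory population's recurrent connection uses a two-component
synapse: a fast 5 ms lowpass (weight 1) and a slow 100 ms lowpass
(weight 1), an AMPA/NMDA-like mixture. The fast component lets a
synchronized volley recruit the next one before the leak erases it; the
slow component bridges the integration latency of weakly driven neurons
(≈50 ms near threshold). A single synapse at either timescale cannot
ignite pattern completion from a small seed.

The identity decoders of the recurrent loop are trained on the grating
manifold down to amplitude 0.02 (plus volume-filling points) and,
importantly, with *nonspecific activation patterns nulled*: activity
profiles in which neurons are recruited purely by excitability (ranked by
intercept or bias) are added to the least-squares system with target
zero. A non-selective reactivation pulse then feeds back only the
*selective* part of the response — the facilitation-weighted trace of the
stored item — rather than an arbitrary fixed direction.

The retro-cue reactivation ("non-specific population-wide input,
amplitude 0.02, 20 ms") is implemented as a direct membrane
depolarization of 0.02 voltage units per millisecond applied to every
non-refractory memory neuron. Interpreted as a current in any of the
model's current units, 0.02 cannot elicit a single spike from a silent
positive-intercept population (the resting drive sits 0.06–3.4 below
threshold across neurons), so the described cue-evoked reactivation would
be impossible; the voltage reading reproduces it. The pulse synchronizes
a small volley, the release-weighted feedback of which is biased toward
the facilitated item; the loop then amplifies that bias into a brief
burst whose decoded vector matches the stored orientation to within a few
degrees, re-facilitating the item's synapses in the process.

## Experiments

Event times are integer milliseconds. Reference task: items 0–250 ms to
both modules; cue pulse 1050–1070 ms to the cued module; impulse
2150–2250 ms to both; probe 2650–2900 ms; the decision is the sign of the
integrated decision value over probe onset + 500 ms, ties broken at
random. The impulse-duration variant presents the impulse from probe
onset − SOA to probe onset (SOA ∈ {0, 50, 100, 250, 500} ms; SOA 0 means
no impulse), keeping cue and probe times fixed. (The task description's
"1400 ms between cue and probe" conflicts with its own event arithmetic,
which gives 1600 ms; the arithmetic is followed.) The two-item variant:
items at 0–250 ms (the secondary module receives 90% input strength),
grey bull's-eye impulses at 1200 and 3550 ms, first probe 1800–2050 ms to
the primary module, reactivation pulse to the secondary module at
2250 ms, second probe 4050–4300 ms.

Each simulated participant is a freshly seeded model: new Gabor banks,
new neuron parameters, new decoders. Item orientations are uniform over
(−90°, 90°]; probes differ by a signed difference from the design's set;
each stimulus presentation draws one independent random phase (the
representational analyses optionally pin a constant phase, as their
figure-style conditions require). Trials sharing an event timeline are
integrated as one lock-stepped batch; all randomness flows from a master
seed through per-participant seed sequences, so runs are bit-for-bit
reproducible from the manifest.

The full-scale plans are 30×1344 (reference task), 20×280 (SOA variant)
and 19×1728 (two-item variant) trials. The shipped tests and the
acceptance script run scaled-down plans — typically 1–2 participants with
4–20 repetitions per condition cell — chosen so the whole suite completes
on a single CPU in minutes; the statistics they compute are the same.

## Analyses

Decoded memory-population vectors are lowpass-filtered (20 ms) and
compared with ideal vectors by absolute cosine similarity; timesteps with
decoded norm below 5% of the encoding peak are masked (with no spiking
there is nothing to decode). Bursts in population spike counts are
detected as upward crossings of a threshold on the 10 ms-smoothed rate.
Psychometric curves are exact response proportions per signed level; a
reference curve can be compared by R² and RMSD over matched levels.

The bi-stable demonstration adds zero-mean Gaussian current noise
(σ = 0.02 in projection units) and strengthens the slow recurrent
component (weight 1.6): with the loop near criticality, noise
occasionally re-ignites the facilitated pattern, the burst depresses
itself, and recovery on the τ_D timescale permits the next one. These two
values are the bi-stable preset, not the task-simulation defaults.

## Design choices at genuinely open points

- Gabor parameters (centres uniform in the aperture, orientation uniform,
  spatial frequency log-uniform within 2× of the stimulus frequency,
  envelope σ ∈ [8, 32] px) and the bank size (one filter per sensory
  neuron) are unconstrained by the task description; they were fixed once.
- T's rows are normalized before the SVD so images and unit-norm filters
  contribute comparably; without this the grating block (pixel norm ≈ 40)
  monopolizes the spectrum.
- Decoder regularization: 0.1 of the peak rate generally; 0.03 for the
  recurrent identity decode and 0.02 for the orientation readouts, which
  are trained on denser orientation-by-phase grids. Residual
  phase-conditional readout bias is amplified ≈3× by the recurrent fixed
  point and is the dominant source of behavioral noise, so these readouts
  are deliberately trained harder than the rest.
- Representations are treated as radius-1: decoders are trained up to
  amplitude 1.0 and the double-contrast impulse simply saturates.
- The comparison stage represents its 4-vector at radius √2 and its
  product decoder is trained on swapped pairs with negated targets, making
  the decoded difference antisymmetric by construction.

## Limitations

Tuning curves in the 24-dimensional code are narrow: |cosine| similarity
between ideal vectors falls to a ≈0.1 sidelobe floor beyond ≈15° of
angular separation, a hard consequence of truncating the grating manifold
to 24 orthonormal directions, so "similarity decreases with distance"
holds as a strong rank correlation rather than strict monotonicity out to
90°.

The model's weakest point is the strength of stimulus-driven
re-expression of the stored item. The cue pulse retrieves the memorandum
robustly because it arrives on a silent, resource-rested network; the
impulse and probe, by contrast, drive vigorous feedforward firing that
depletes resources within tens of milliseconds and crushes the
facilitated loop's share of the drive. As a result the cued module's item
similarity during the impulse stays well below the impulse similarity
(rather than briefly exceeding it), the reactivated secondary item in the
two-item task does not overtake the second impulse, and the hysteresis
that drives decisions is small relative to readout noise, giving a
shallow (though correctly signed and symmetric) psychometric curve and
leaving the SOA-dependent accuracy dip within sampling noise at practical
trial counts. Raising the recurrent gain enough to fix this breaks strict
delay-period silence — in this implementation the two requirements
compete for the same resource budget set by the plasticity constants.
The affected checks are asserted at their intended strength in the
acceptance suite and are expected to fail until a mechanism reconciles
the two regimes; all structural and kinetic checks, activity silence,
cue-driven recovery, the uncued ≈2:1 impulse/item ratio, and the
white-versus-black impulse contrast hold as described.

Motor processes, EEG forward modelling, probe gating between modules, and
dynamic (time-varying) coding are out of scope.
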