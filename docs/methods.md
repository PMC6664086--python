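# Methods

## Model

`gridwave` simulates a two-dimensional grid of cortical modules ("columns").
Every module holds K = K_F + K_B + K_I point neurons: strongly coupled
foreground excitatory cells (F), background excitatory cells firing
tonically at low rate (B), and inhibitory cells (I); the default composition
is 250/750/250 (4:1 excitatory:inhibitory). A reduced 150-neuron module
(30/90/30) with the same proportions is used for desk-scale runs (below).

### Neurons

Excitatory neurons are leaky integrate-and-fire units with spike-frequency
adaptation (SFA). Between synaptic events,

    dV/dt = -(V - E)/tau_m - (g_c/C_m) c
    dc/dt = -c/tau_c

with instantaneous jumps J at event arrivals. Crossing V_theta emits a
spike, resets V to V_r for an absolute refractory period tau_arp and
increments the fatigue c by alpha_c. Inhibitory neurons carry no fatigue
dynamics. This linear system has a closed-form solution, so the engine
advances each neuron exactly from event to event; a property test checks the
closed form against dense Runge-Kutta integration to <1e-6 relative error.

Default constants (mV, ms): E = 0, V_theta = 20, V_r = 5, tau_m = 20 (E) /
10 (I), tau_arp = 2 (E) / 1 (I), C_m = 1, alpha_c = 1. Adaptation strength
and timescale are regime parameters: g_c = 0.08, tau_c = 650 in the
slow-wave state; g_c = 0.06, tau_c = 150 in the asynchronous state. The
reduced adaptation in the wake-like state mirrors the neuromodulatory
suppression of SFA in wakefulness. The reset sits far below threshold
(theta - V_r = 15 mV): with the large synaptic jumps of the reduced module, a
reset close to threshold lets a couple of coincident excitatory events
re-fire a neuron immediately and the network escapes into a saturated
balanced state that adaptation can never terminate; we observed exactly that
failure before lowering V_r.

### Connectivity

Excitatory connection probability decays exponentially with the Euclidean
inter-module distance d (in inter-module-distance units, imd; physically
0.4 mm per imd): p(d) ~ exp(-d/lambda), normalized per target over the
modules present in the grid (open boundaries). Inhibitory projections are
strictly local to the module. Sampling is fixed-in-degree: every neuron
receives exactly M_s = round(0.9 K_s) synapses from each source population
(225/675/225 at full size, total 1125 per neuron), for every lambda — so the
total synapse count is independent of the connectivity range. Autapses are
resampled away; multapses are allowed. Weights are Gaussian with mean J_ts
and SD 0.25 J_ts (a coefficient of variation; drawn magnitudes are folded at
zero — a ~4-sigma event — so the source-sign convention holds exactly).
Delays default to 1 ms (equal to the communication step); a
distance-proportional policy with an axonal conduction speed is available.

### Engine

Execution is mixed time-/event-driven. A 1-ms communication step (never
longer than the minimum delay) paces the exchange of address-event packets
(neuron id, emission time) between logical partitions; each partition keeps
the double-ordered synaptic list of its own neurons (grouped by delay,
ordered by presynaptic index), demultiplexes matured spikes into per-neuron
event queues, merges the external Poisson events generated on the fly, sorts
each queue by (arrival time, recurrent before external, source id) and
advances neurons with the closed-form solution. Events arriving during the
refractory period are discarded. External drive comes from counter-based
random substreams keyed by (seed, neuron, step, purpose), so the spike
record is bit-identical for any number of partitions — a property the suite
asserts on a 3x3 grid for 1/2/4 partitions.

### Mean-field planner

A module is reduced to three populations whose rates follow

    F, B: d nu/dt = (phi(nu, c) - nu)/tau_E,  dc/dt = -c/tau_c + alpha_c nu
    I:    d nu/dt = (phi(nu) - nu)/tau_I

with phi the Ricciardi first-passage-time gain of the LIF neuron under the
diffusion approximation: mu = tau_m (sum_s M_s J_s nu_s + J_ext nu_ext) -
tau_m (g_c/C_m) c and sigma^2 = tau_m (sum_s M_s <J_s^2> nu_s +
<J_ext^2> nu_ext), second moments including the weight spread. The
erfcx-based integrand avoids overflow; the far-left tail is handled by its
leading-order closed form, and the sigma -> 0 limits are analytic. tau_E =
10 ms and tau_I = 5 ms are phenomenological. Fixed points are found by
scanning nu_F with B and I slaved to their quasi-stationary rates
(warm-started damped iteration plus Newton polish), bisecting sign changes,
and classifying stability by the numerical Jacobian of the 5-variable
system. The regime classifier integrates the system with small rate noise
(2 Hz sqrt(ms)) and counts hysteretic alternations of the smoothed nu_F
between 3 and 25 Hz: three or more cycles mark the slow-wave regime.

## Calibrated states

The complete synaptic parameter tables behind the published simulations are
not part of the available text, so the presets were calibrated with the
package's own planner and then refined against spiking runs; they are
editable configuration, not reference values.

Design targets: an asynchronous (AW) state with a single stable fixed point
whose population-average rate is 8.8 Hz (F/B/I = 19.6/4.9/9.8 Hz), and a
slow-wave (SW) state alternating at about 3 Hz between a quiet Down state
and a propagating Up bout. The AW table was obtained by inverting the gain
function row by row (each efficacy row only affects its target population);
the F row keeps its self-coupling low — a larger F-to-F efficacy folds the
rate nullcline and destabilizes the fixed point through the adaptation loop,
which is exactly the SW mechanism. The SW table combines: a quiet Down state
(all populations below ~3 Hz, stable), inhibition that is silent in the Down
state and recruited by F (preserving the escape barrier while capping the
Up branch), and strong adaptation that terminates each Up bout. External
Poisson rates are per population.

At the reduced module size the diffusion approximation carries a visible
bias (27-81 incoming synapses per population, jumps of 1-2.5 mV), so the
150-neuron tables are validated directly on network simulations: the AW
preset fires at F/B/I = 19.1/5.2/10.4 Hz against the predicted
19.6/4.9/9.8 (all within 7%), and the SW preset alternates at about
3 waves/s with fully quiet Downs. The 1,250-neuron tables are the reduced
tables scaled by the in-degree ratio (preserving the mean input), with the
F-to-F entry of the SW table re-tuned by the planner; their mean-field
pictures show the textbook phase-plane topology (AW: one stable fixed point
at 8.8 Hz average; SW: weakly stable low-rate fixed point, S-shaped rate
nullcline, noise-driven relaxation oscillation near 3 Hz).

## Activity analysis

Rates are binned at 5 ms (counts are kept, so rate-to-count resummation is
exact). Spectra use Welch's method. The MUA proxy is the module-average
rate; logMUA = log(MUA/MUA_down) plus zero-mean Gaussian noise of variance
0.5 emulating background fluctuations, with MUA_down bootstrapped per module
(30th-percentile start, then two iterations of threshold -> Down samples ->
mean) and silent bins floored at 0.1 Hz.

Transition detection deviates from the naive recipe in one place: the
detector thresholds the log of the *smoothed* MUA (20 ms boxcar) rather
than a smoothed logMUA. With 150-neuron modules a single spike moves the
per-bin log by whole log-units, and that shot noise otherwise swamps the
Up/Down bimodality. Thresholds are per module, at the midpoint of the two
dominant histogram modes (candidates closer than 0.8 log-units, or without
a clear dip, are rejected as unimodal — a stationary AW signal yields no
crossings). Crossing times are sub-bin interpolated. Pooled crossings are
segmented into discrete waves at silent gaps (>200 ms by default) and at
deep valleys of the crossing-density trace; isolated crossings (fewer than
~n_modules/10 companions within +-30 ms) are discarded as noise, since a
wavefront is collective.

Wavefront speed follows the gradient construction: V = 1/|grad T| pointwise
(central differences, one-sided at edges), converted to mm/s via the
physical inter-module distance; the border ring is excluded, as are points
whose gradient falls below the temporal resolution of the transition times
(half the MUA bin per imd) — such points are indistinguishable from
simultaneous and carry no finite speed. Statistics are means and SDs over
positions and waves.

## Desk-scale study conditions

Spiking runs use a 12x12 grid of reduced 150-neuron modules (21,600
neurons, 2.9 million synapses, in-degree 135): the problem size at which a
multi-second simulation completes in about a minute on one core. Slow-wave
runs last 4-5 s (12-19 waves per run), asynchronous runs 4 s; the
connectivity sweep covers lambda in {0.4, 0.5, 0.6, 0.7} imd. The
full-size presets (0.72M-46M neurons) are exercised analytically (size
accounting) and through the mean-field planner only.

## What the reduced network does and does not reproduce

Reproduced: the Up/Down alternation near 3 Hz with quiet Downs; the
asynchronous state at the 8.8 Hz design average, quantitatively matching
its mean-field fixed point; grid-traversing Down-to-Up wavefronts with
measurable transition-time maps; and all structural/accounting quantities.

Not reproduced: the absolute wavefront speed and its increase with lambda.
In the reduced module the Up state ignites as a brief, hot, locally
regenerative burst (the overshoot of a 30-neuron foreground pool before
inhibition catches up), so fronts sweep the 12x12 grid in tens of
milliseconds — roughly 60-150 mm/s rather than ~15 mm/s. Worse for the
trend: the kernel normalization redistributes a fixed synapse budget, so a
longer decay constant *dilutes the local loop* (interior local fraction 73%
at lambda = 0.4 versus 32% at 0.7). When ignition is regenerative-local,
that dilution slows each module's ignition more than the longer reach
compensates, and the measured speed stops growing (and at lambda = 0.7
falls) with lambda. The published fluctuation-driven escape regime, where
the front is carried by the spatial integral of a cool (~10-20 Hz) Up
state and speed grows linearly with lambda, requires the full 1,250-neuron
module's small relative fluctuations; we could not stabilize a cool Up
plateau at 150 neurons per module (every locally bistable configuration we
constructed bursts). The monotone speed-versus-lambda property test
therefore fails under these study conditions and is left failing; speeds
are reported as measured.

## Numerical choices

Ricciardi quadrature: adaptive with 1e-10 relative tolerance; fixed-point
residuals below 1e-8 Hz/ms; mean-field integration: Euler(-Maruyama), 0.5 ms.
Engine event times are continuous doubles within 1-ms windows; spike times
are the triggering event times. Ties in per-neuron queues break by
(recurrent before external, then source id); identical-key multapse events
inherit the canonical (delay, source, construction index) list order, which
is what makes the raster independent of partitioning. Serialization
quantizes weights to a per-kind 2-byte fixed point (scale chosen from the
largest magnitude present); a round trip is lossless after the first
quantization. External amplitudes are not sign-clipped. The counter-based
substreams use a splitmix64-style mixer; Poisson counts by Knuth inversion
(suitable for the <2 events/ms/neuron regime), normals by Box-Muller.

## Known limitations

- The diffusion approximation is only indicative at 27-81 inputs per
  population; reduced-module tables are therefore network-validated, and
  their mean-field classification is not asserted.
- Wave statistics at the reduced scale are burst-like (see above); absolute
  speeds exceed the biological range.
- Logical partitions exchange packets in memory; the transport interface is
  narrow by design, but no true message-passing backend is included.
- Synaptic plasticity is not implemented (kept off in the modeled study).
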