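# Methods

This note documents the model behind `retinasim`, its assumptions, the
parameter defaults and why they were chosen, what the synthetic scenes
do and do not emulate, and the numerical conventions.

## Scope and level of abstraction

The simulator is *behavioral*: it models the signal chain of a
retina-inspired sensor — change-detecting pixels, center–surround
pooling on a shared integration node, skewed-buffer/band-logic spike
generation — at the level of voltages, conductances and counts, not at
transistor level. Device physics enters only through a small set of
lump parameters (conversion gain, log slope, trip points, keeper and
pull conductances) and, in the variation engine, through behavioral
mismatch distributions. Transistor I–V nonlinearity is represented only
through the divider's saturating shape; spectral response, exposure
control, color filtering and readout electronics are out of scope.

## Bipolar stage

### Contrast rule (ideal backend)

A pixel signals ON when `(I_k − I_{k−1})/max(I_{k−1}, ε) ≥ θ` and OFF
for the mirrored decrease, boundary inclusive. The denominator is the
*previous* frame — the causal choice of reference luminance. The floor
`ε = 10⁻⁶` intensity units keeps the ratio (and the DVS log) defined at
zero light. Default `θ = 0.30`.

### APS path

`V_PX = clamp(v_reset − α·I, 0, V_rail)`. The defaults are a two-point
calibration from the model's reference operating points: mean pixel
outputs of 720 mV at the unit illuminance and 548 mV at 1.3× that
level, giving `α = 573.33 mV` per intensity unit and
`v_reset = 1293.3 mV`. That reset level exceeds a 0.8 V core supply, so
the pixel rail is a separate parameter (default 1.5 V); the core supply
`V_DD = 0.8 V` is a 22 nm-class value consistent with the comparator
trip points quoted relative to `V_DD/2`.

The sampler stores `V_C = V_DD/2 + (V_PX,k − V_PX,k−1)`; the
thresholder fires ON when `V_C ≤ V_DD/2 − δ` (APS voltage falls when
light rises) and OFF on the mirror side. Two calibrations of the trip
offset δ are provided:

* **local** — `δ = θ·α·I_{k−1}` per pixel, which makes the analog
  decision algebraically identical to the ideal contrast rule away from
  the clamp rails. This mode defines intent and is what the
  backend-agreement tests check.
* **global** (hardware-realistic) — `δ = θ·α·I_ref` with one fixed
  reference intensity, because a two-inverter thresholder has fixed
  trip points. The default `I_ref = 0.7` sits at the dim end of the
  unit operating range: a comparator sized for the minimum detectable
  contrast at the dim end gives stimuli at the specified contrast a
  decision margin (51.6 mV here), which is what lets the variation
  experiment signal correctly across all chip instances. With
  `I_ref` equal to the stimulus intensity the 30 %-contrast stimulus
  would sit exactly on the trip point and mismatch would flip half the
  instances; a real design would never be biased that way. The same
  0.7 design-margin factor is applied to the DVS comparator in the
  variation engine.

### DVS path

`V_LOG = m·ln((I+ε)/i_ref)` with `m = 70 mV` per e-fold. `m` is a
consistency choice (it makes a 1.3× contrast step 18.4 mV, the scale of
a realistic log front end), not a measured value. Events follow
standard event-camera semantics: per pixel, a reference voltage is
initialized at the first frame; each excursion of one threshold step
`m·ln(1+θ)` emits one event and moves the reference by exactly one
step, so large excursions emit multiple events. Timestamps are linearly
interpolated within the frame interval; ties are broken in raster
order. For monotone trajectories the event count is exactly
`floor(|ln(I_end/I_start)|/ln(1+θ))`; the crossing test carries a
10⁻⁶-step tolerance so trajectories landing exactly on a threshold
count inclusively despite log round-off. No refractory behavior beyond
the one-step reference update is modeled.

## Receptive-field geometry

Territories are rectangular tiles of the array (default 3×3); the tile
shape must divide the array shape (no implicit padding). Within each
territory every 4th pixel in raster order (donor fraction 1/4, stride
phase 0) is a *donor*: it is excluded from its own field's center and
its signal fans out to the surround set of every 8-connected neighbor.
Fan-out (rather than partitioning donors among neighbors) is the only
assignment under which each region donates fewer pixels than it keeps
while every interior field's surround still outnumbers its center; both
properties are asserted in tests, and interior surround dominance holds
exactly when the donor fraction exceeds 1/9. Edge and corner fields
simply have smaller surrounds (no wrap). Balanced weights
`w_s = w_c·|center|/|surround|` equalize expected pull-up and pull-down
under spatially uniform activity.

## Feature circuits

### OMS

Steady-state divider with keeper:
`V_INT = (w_c n_c V_DD + g0 V_DD/2)/(w_c n_c + w_s n_s + g0)`. The
keeper (default `g0 = 1` in the same arbitrary conductance units as the
unit pull device) is the explicit mechanism that rests the quiescent
node at `V_DD/2`; it also sets the sensitivity scale — with hundreds of
active devices it is negligible, for a handful it attenuates the
response. OMS counts ON and OFF signals alike (any contrast change is
an activation). The buffer trip defaults to `0.55·V_DD` — above the
quiescent point by design, the exact skew being a free parameter — and
the comparison is strict (a tie does not spike). Asynchronous input is
latched once per frame period; a pixel with at least one event in the
window counts once. Surround pooling uses a single transition (no
multi-frame low-pass), the simplest reading consistent with per-frame
evaluation.

An optional RC mode models the finite integration capacitor: within
each constant-activation segment the node relaxes exponentially toward
the divider value with `τ = c_int/(G_up + G_down + g0)`, continuous
across segments. `c_int` is expressed in conductance·time units so τ
comes out in the schedule's time unit. Note that settling to under
0.1 mV requires ~10 τ for a full-scale step (e^−5 of a 360 mV step is
still 2.4 mV); the tests assert the exponential law rather than a fixed
5 τ figure.

### LD

Same divider with equal ON/OFF weights `w_ld` and no center/surround
split: LD pools the field's whole territory. Band logic spikes high
above `V_TH,UP = 600 mV` and low below the mirrored
`V_TH,DN = V_DD − V_TH,UP = 200 mV` (only the upper trip is a reference
value; mirroring is the symmetric default, making bright and dark
approach trip at identical counts). The pure-OFF count needed to trip
low has the closed form `n > g0(V_DD/2 − V_TH,DN)/(w_ld·V_TH,DN)`,
i.e. 2 activations at defaults. Exact translation cancellation holds
for rigid objects fully inside a field on a uniform background;
partial-overlap transitions are evaluated but carry no guarantee.

## Synthetic scenes

The generator produces the canonical probe scenes with known ground
truth. Motion is integer-pixel with periodic wrap, so global background
motion is a permutation of pixel values and its event statistics are
stationary. Objects are squares or discs rendered at a constant
multiplicative contrast on the local background mean (dark ×0.3,
bright ×3 by default) so their edges always exceed the 30 % threshold.

The OMS scenes use an *active-line* texture: every 3rd row is a
high-contrast checker line (levels `0.7·b` / `1.3·b` around base
`b = 0.5`), the rest uniform. Under 1 px/frame horizontal translation
every active-line pixel fires every transition and no other background
pixel ever fires, so the event rate is exactly uniform at field
granularity: with the line period dividing the 21-pixel territory
height, every field sees the same active fraction (exactly 1/3 of its
center and of its surround donors), balanced weights cancel exactly,
and every undisturbed field sits at `V_INT = V_DD/2` to machine
precision. This choice isolates the balance mechanism: with an iid
random texture the field-level counts fluctuate by several percent,
which probes mismatch robustness rather than the mechanism itself (that
regime remains available via the `random` texture). The canonical array
is 63×63 — the 3×3 grid requires a divisible shape — with a fixed dark
square (half-width 5) in the central field for the global-only scene,
and a bright square moving diagonally at 3 px/frame for the
global-plus-object scene (14 frames keep it inside the canvas).

The LD scenes use a uniform static background with a centered square
that either grows 1 px of half-width per frame (loom, sides 5, 7, …,
19 staying inside one territory) or translates at 2 px/frame. What
these scenes do *not* emulate: photon and read noise (noise lives in
the variation module), sub-pixel motion, photorealistic texture,
occlusion by multiple objects, and camera optics. Passing the scene
tests therefore demonstrates the mechanisms — balance, cancellation,
escalation — under their stated assumptions, not detection performance
on natural video; the frame-stack reader accepts recorded imagery for
that purpose.

## Variation engine

Per chip instance: one global supply offset (σ = 10 mV default);
per-comparator trip offsets (σ = 5 mV); per-device log-normal strength
multipliers (σ = 0.05); per-pixel photoreceptor offsets (σ = 43.2 mV,
used as a scale reference for the behavioral offset model). Trip and
strength sigmas are free parameters — the corresponding device-level
distributions are foundry data — chosen at the scale of their printed
anchors and leaving the nominal contrast experiment margin. Standard
normal deviates are drawn before scaling, so sigma sweeps with a fixed
seed use common random numbers and per-sample margins (hence the
fraction-correct summary) are monotone in each sigma. In the APS
experiment the supply offset shifts the reset level and the sampler
reference identically, so it widens the pixel-voltage distributions but
cancels in the decision — the DVS photoreceptor offset likewise cancels
in the temporal difference while spreading the log voltages by ~43 mV.
This is the robustness mechanism the experiment demonstrates. The field
stages (OMS/LD) redraw every pull device and field comparator; with a
19 mV worst-field margin in the global-motion scene and a 5 mV trip
sigma, a ≈3.8σ outlier instance can emit a spurious spike (~0.1 % of
instances), which the summaries report honestly.

## Numerical conventions and problem sizes

Coordinates are 0-based `(row, col)`, origin top-left; transition `k`
compares frames `k−1 → k`; ON means intensity increase. All comparator
decisions at boundaries: bipolar thresholds inclusive, spike trips
strict. The canonical simulations (63×63, ≤20 frames, 1000 Monte-Carlo
samples) run in seconds on one core; the test suite and the acceptance
script each finish in well under a minute. These sizes are the
package's standard study conditions; everything scales to larger
arrays through the same interfaces.

## Known limitations

* The analog APS path with a global trip reference is only
  approximately contrast-scaling; the ideal backend is the reference
  semantics.
* `V_INT` is a resistive-divider abstraction; real pull devices vary
  their drive with drain–source voltage, making the node nonlinear in
  the activation counts beyond the saturation shape modeled here.
* LD translation cancellation is exact only for uniform backgrounds
  and objects fully inside a field.
* The event generator timestamps by linear interpolation of the log
  voltage between frames; intra-frame intensity trajectories are not
  modeled.
* No temperature, aging, or spatially correlated mismatch.
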