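# Methods

## The model

`mhfield` simulates a two-dimensional dynamic neural field of 100 × 100
conductance-based integrate-and-fire neurons with short-range Mexican-hat
lateral connectivity, the configuration proposed for the superficial
superior colliculus and, more generally, for any topographic map performing
winner-take-all target selection with a *short* inhibitory surround.

Each cell's membrane potential obeys

    tau_m dV/dt = -(V - V_0) - g_e (V - V_e) - g_i (V - V_i)

with dimensionless channel variables `g_e`, `g_i` that decay exponentially
(`tau_e = 3 ms`, `tau_i = 10 ms`) and receive instantaneous increments from
presynaptic spikes. Crossing `V_t = -50 mV` emits a spike, resets the cell
to `V_r = -80 mV`, and starts a 1.5 ms refractory period during which the
cell is clamped at `V_r` and exempt from all drive (its channel variables
keep decaying and accumulating, so synaptic state stays continuous). The
slower inhibitory channel is the load-bearing feature: excitation strikes
first and inhibition catches up, which produces the delayed inhibition
wave, the transient first membrane rise, and the suppression phenomena.

Lateral weights come from a difference of Gaussians,

    f(d) = (1 + beta) exp(-d² / 2 sigma²) - beta exp(-d² / 2 (K sigma)²),

whose net profile peaks at 1 at the origin and has an inhibitory ring for
`K > 1` (named variants: S1 `K=1.2, beta=6.0`; S2 `K=2.0, beta=1.43`,
optimised so its trough depth matches S1 within 1%; S3 `K=1.2, beta=8.0`).
Scaled by `alpha_e = alpha_i = 200`, the net kernel spans ≈ [-113, 200].

### Weight-channel convention

How the two DoG terms map onto the two channels is underdetermined by the
defining equations, and the choice is not cosmetic. Assigning the *raw*
first and second terms to `w_e` and `w_i` (they overlap everywhere) makes
persistent activity impossible: time-averaging the drive of a cluster
firing at any rate gives the sustaining condition
`Σw_e · tau_e · |V_t - V_e| > Σw_i · tau_i · |V_t - V_i|`, i.e.
`Σw_e / Σw_i > 2`, while the raw terms are bounded by
`(1+beta)/beta ≈ 1.17`. No gain scaling escapes this; simulations confirm
that the raw convention yields either map-wide runaway or no lateral
recruitment at all, never a localized persistent cluster — yet the model
is explicitly operated in a bistable regime. The package therefore splits
the **net** DoG (which is the object "normalized between -1 and 1") into
its positive part → `w_e` and negative part → `w_i` (`net-split`, the
preset default). Excitation and inhibition then act on disjoint annuli —
the classic construction for a bump attractor — and the field is bistable
between the all-off state and a localized cluster. The raw and
peak-normalised conventions remain selectable for sensitivity analysis.

### Units and the calibrated gain scale

The synaptic gains are specified in millivolts (`alpha = 200`,
`alpha_s = 4000`) but increment dimensionless channel variables. The
package reads them in SI units: deposits are `alpha · w · 1e-3`
(`MV_GAIN_SCALE`), matching how a units-aware simulator stores
millivolt-tagged quantities. This single conversion and the line width
(1 cell at column x = 50) were fixed **once** against one anchor — the
reference variant's single-cluster/suppression boundary at line lengths
18 → 20 — and never revisited. Everything else reported by the package
(S3 boundaries at 16/36/38, the S2 behaviour, shape-sweep boundaries,
two-stimulus fusion/suppression/repulsion, rise-speed optima at sizes
10/12/8, latency structure) is untouched validation.

## Numerics

- **Integration**: exponential-Euler at `dt = 0.01 ms` — with channels
  frozen over a step the membrane equation is linear and is advanced
  exactly by `V ← V* + (V - V*) exp(-dt (1+g_e+g_i)/tau_m)`. This is
  unconditionally stable even when total conductance makes the effective
  membrane time constant smaller than dt. Plain forward Euler
  (`method="euler"`) is provided; at the calibrated gain it is stable and
  reproduces every regime boundary identically.
- **Spike handling**: threshold test after the membrane update; all cells
  crossing in the same step spike together (no serialisation, so lattice
  symmetries are exact). Spikes deposit their kernel patch onto the
  neighbours' channels at the start of the *next* step (one-step synaptic
  latency). The lattice is open at the borders: contributions falling off
  the grid are dropped.
- **Refractoriness**: `V` clamped at `V_r`, drive ignored, channels keep
  integrating; the effective inter-spike floor is `1.5 ms + dt`.
- **Input**: rate curves are converted to deterministic spike trains (one
  spike whenever the running rate integral crosses an integer); each input
  spike increments `g_e` of the masked cells by `alpha_s · w_s · 1e-3`.
  A sustained 400 Hz profile over 200 ms gives exactly 80 spikes; the
  default transient profile (Gaussian, peak 400 Hz at 25 ms, sd 80 ms)
  gives 48.
- **Noise**: optional zero-mean Gaussian perturbation of V, specified as a
  per-millisecond sd (4 mV in the noise control) and applied per step
  scaled by sqrt(dt / record_dt); seeded, and never drawn when disabled,
  so noise-free runs are bit-reproducible regardless of seed.
- **Determinism**: no other randomness exists anywhere in the pipeline.

## Cluster detection and classification

A *spiking cluster* is a self-maintained group: activity that persists on
its own rather than echoing the input. Detection takes 8-connected
components (minimum 3 cells; both knobs configurable) of the cells that
spike during the final 50 ms of the run. A component counts as a cluster
if it recruits at least one cell outside the stimulus mask, or if its
members' mean rate in that window exceeds 1.5× the input's own mean rate
there. The margin matters only in a wide dead band: purely input-paced
stimulated cells were never observed above 1.11× the input rate, genuine
clusters never below 2.6×. Per-cluster centres of gravity are
spike-count-weighted means over the **whole** run; steady rates count only
members active in the window, so late-onset clusters are not diluted.

The suppressed / single / double / multiple classification drives the
reported regime boundaries. "Complete suppression" therefore means no
self-maintained cluster — stimulated cells still emit input-paced spikes
in every condition, which is unavoidable at the specified stimulus gain.

## What the generator emulates, and limits of a green test

Inputs are idealized microstimulation: binary masks (line, square,
rasterized disk, 2×2 point pairs) driven by a shared deterministic train.
They are spatially homogeneous and perfectly synchronous across the mask —
deliberately so, as in the protocols — which favours exact suppression;
real retinal input would be graded, asynchronous and noisy. Green tests
establish the *phenomenology of the connectivity regime* (selection,
suppression, multi-locus selection, attraction/fusion/repulsion and their
boundaries), not biophysical realism of any single neuron, and not
robustness to input statistics beyond the 4 mV noise control.

Known quantitative departures from the reference description, with the
package's own numbers (all reproduced by `scripts/acceptance.py` and the
test suite, never asserted blindly): steady cluster rates are lower
(S2 ≈ 424 Hz, S3 ≈ 274 Hz) than the 550–600 / 350–400 Hz described, and
three regime boundaries sit one 2-cell step away (two-stimulus suppression
extends to separation 20, repulsed doubles start at 22; circle suppression
ends at 24). These reflect implementation details of the original that the
defining equations do not pin down; all orderings and every other printed
boundary reproduce exactly.

## Parameters that matter

| parameter | default | unit | role |
|---|---|---|---|
| `tau_m, tau_e, tau_i` | 10, 3, 10 | ms | membrane / channel decay; `tau_i > tau_e` creates the delayed inhibition wave |
| `V_t, V_r, V_0, V_e, V_i` | −50, −80, −70, 0, −80 | mV | threshold, reset, rest, reversals |
| `refractory` | 1.5 | ms | caps rates at ≈600 Hz |
| `sigma` | 5 (size sweeps), 8.5 (two-stimulus) | cells | excitation range; sets which stimulus scales compete |
| `K` | 1.2–2.0 | – | inhibition/excitation extent ratio (short-range surround) |
| `beta` | 1.43–8.0 | – | inhibition depth of the DoG |
| `alpha_e = alpha_i` | 200 | mV | lateral gain (×10⁻³ into channel units) |
| `alpha_s` | 4000 (1333–4000 in competition) | mV | stimulus gain |
| `dt` / `record_dt` / duration | 0.01 / 1 / 200 | ms | clocks |
| `min_size`, `rate_margin` | 3 cells, 1.5 | – | cluster detection knobs (wide insensitive bands) |
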