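# Methods

This note documents the model implemented in `acdc`, the learning protocol,
the numerical choices, and the boundaries of what the simulations show. It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

Five coupled rate equations are integrated with forward Euler (step `dt`,
default 1 ms; all time constants in ms):

* **Excitatory RNN** (`n_exc` = 200 units, τ_rnn = 1):
  `τ_rnn dx_i/dt = −x_i + Θ(Σ_j W_ij x_j − J^EI x_I + J^EA γ_E a + x_in_i)`
  with the rectified sigmoid `Θ(u) = max(0, 2/(1+exp(−λu)) − 1)`, λ_rnn = 10.
  The context input `x_in` (magnitude 1) reaches one 20-unit subset as a
  square pulse over the first `input_pulse_ms` (default 100 ms); each Action
  node's feedback reaches a further 20-unit subset. At zero overlap all
  these projection target sets are disjoint.
* **Shared inhibitory unit**: `τ_rnn dx_I/dt = −x_I + J^IE Σx + J^IA γ_I Σa`,
  J^IE = 0.1.
* **Go accumulators** (τ_g = 1000, rectified at zero):
  `τ_g dg_j/dt = −g_j + ρ_G(t)·(Σ_i W^G_ji x_i − J^GN n_j) + I_add,j(t)`.
  The multiplicative gain ρ_G and additive input I_add are the modulation
  handles (both default to identity). A flag (`go_gain_on_drive_only`)
  restricts ρ_G to the excitatory drive instead of the full net input.
* **Action nodes** (τ_a = 10): `τ_a da_j/dt = −a_j + Θ(J^AG_j g_j − b)` with
  b = 0.5 and λ_a = 10⁴, i.e. a near-binary accumulation-to-bound readout.
  An action is *executed* at the first upward crossing of `rt_threshold`
  (0.5) by `a_j`; crossing times are refined below the sampling step by
  linear interpolation.
* **NoGo nodes** (τ_n = 10): `τ_n dn_j/dt = −n_j + ρ_N(t)·J^NA_j a_j`.
  ρ_N is the sustain handle; `J^NA` can also be lowered per action.

Gains γ_E = 21.4 > γ_I = 21.0. The attractor switch works in two phases:
the rising Action volley drives the shared inhibition above the active
assembly's recurrent support (the assembly extinguishes once
`J^IE Σx + γ_I a > 20·w_rec`, i.e. a ≈ 0.86), after which the volleyed
assembly's net input `(γ_E − γ_I)·a > 0` ignites it and its recurrent
weights take over.

### Integration step

`dt = 1 ms` sits exactly on the Euler stability boundary for τ = 1 ms
(update factor 1 − dt/τ = 0), so the inhibitory unit tracks fast transients
with a one-step lag that oscillates. This lag is *functionally part of the
model's operating regime*: it lets the next assembly ignite already during
the Action rise. At finer steps (0.5 or 0.25 ms) the lag mode disappears,
and then a switch cannot complete until the previous Action node's activity
has decayed to `a < (γ_E−γ_I)/γ_I`-level residuals, ~65 ms after execution
(τ_a = 10) — inter-action gaps of 50 ms become inexpressible and the
six-action sequence cannot be trained. We therefore keep dt = 1 ms and
accept its signature: cluster-ignition latency can flip between an early
(during-rise) and a late (post-extinction) mode by up to ~18 ms depending
on integration phase. This shows up as jitter in event times under strong
modulation and dominates the dispersion of the rescaling structure
statistic (measured s.d. ≈ 0.25 across the gain grid at dt = 1 versus
0.09 at dt = 0.5, where, however, the sequence itself cannot be learned).

### Noise

Per-step Gaussian noise (s.d. `noise_sd`) perturbs the excitatory,
inhibitory, Go and NoGo updates — never the Action update. By default
(`noise_mode="net_input"`) the noise enters the rate equation (the update
increment is scaled by dt/τ). The alternative `"step"` placement (plain
additive per step) makes the slow Go accumulator an unbounded random walk
(OU variance σ²τ_g/2dt far above the bound) — measured, it collapses
trained 200 ms reaction times to ~50 ms means and inverts the SD-vs-interval
law — so it is not the default.

## Learning

Both Hebbian sites use
`dW = [−α₁(1−post)·pre + α₂·post·pre·(W_max−W)]·dt`, clamped to [0, W_max],
with the presynaptic trace low-passed over τ_w. τ_w defaults to `dt`
(trace = instantaneous rate): filtering is not required by the model, and a
trace of ≥ 2 ms outlives the attractor switch, potentiating cross-assembly
weights until successive clusters weld into one (this is also the
documented failure regime of the rule).

Two gates keep the fast rule stable against the transients of the switch —
both are three-factor-style eligibility conditions chosen after measuring
the failure modes they prevent (each reproducible by disabling its flag):

1. **Recurrent LTP requires feedforward drive on the postsynaptic unit**:
   the context input at ≥ half magnitude, or a thalamic volley within
   `ltp_volley_fraction` (0.85) of its plateau — which, by the γ geometry,
   is the moment the previous assembly extinguishes. Assemblies thus wire
   during the volley that recruits them; the ~15 ms of residual co-activity
   at each switch, and the one-step inhibition hole at trial onset (which
   briefly flashes any weakly seeded assembly), leave no potentiation.
   Depression is ungated and erases incidental cross-weights each trial.
   Without this gate, cross-assembly weights saturate within a few trials
   at the printed learning rates — at *any* global rate rescaling, because
   slower rates also fail to form later assemblies (only ~20–40 ms of
   volley-driven activity exists per trial before an assembly can
   self-sustain).
2. **RNN→Go potentiation is recruited and windowed**: rows (Go nodes) are
   recruited stage by stage with the training curriculum; a recruited row
   potentiates only inside its association window — opening at the
   predecessor's volley plateau, closing at its own action's onset
   (`onset_threshold` = 0.05, well below the execution threshold because
   the switch begins while the Action node is still rising) — and is
   depression-only outside it. Without the window, every Go node races to
   wire onto the first assembly (they receive identical drive, and the
   potentiation term self-amplifies), scrambling action order; nothing in
   the ungated equations couples Go-node index to ordinal position.

The **delta rule** adjusts Go→Action couplings between trials:
`ΔW^AG_j = η (t_obs − t_des)`, times in seconds, η = 0.4. Training is
sequential: stage *j* runs trials (Hebbian learning on) until action *j*'s
error is below φ = 0.01 s, then advances. A trial in which the staged
action never executes uses the window end as `t_obs` (maximal corrective
update). Already-converged actions receive maintenance updates — without
them their timing drifts by ~10 ms while later stages' wiring matures.
`max_trials` defaults to 1000 per stage: near the bound the error
contraction per trial is `1 − η·b/W²`, so a 50 ms gap (W ≈ 10–11) needs
roughly 500–800 trials; a divergence guard aborts after 25 consecutive
growing-error trials (errors legitimately grow for a dozen trials while
within-trial wiring matures). The context pulse is withdrawn at sequence
onset (`context_until_onset`) so that an early execution inside the pulse
cannot re-ignite the first assembly against the switch.

## Modulation constructions

* Shifting: additive ±1 to the first Go node over a given duration.
* Rescaling: constant gain ρ on every Go node's net input (a
  `spare_first` flag implements the all-but-first variant that avoids the
  small onset shift of a global gain).
* Compositionality: piecewise-constant gain per desired-event segment. The
  Go node is a leaky accumulator, so the exact gain for re-timing interval
  Δt to Δd is `(1−e^(−Δt/τ_g))/(1−e^(−Δd/τ_g))` (default); the plain
  interval ratio Δt/Δd is available as `correction="linear"`.
* Sustain: gain ρ = 0.1 on one NoGo node's net input over an interval
  (default target; a Go-node variant exists), or a lowered per-action
  `J^NA`.

## Fixtures (the built-in study conditions)

`fixture_sequence("sim1")` is the canonical six-action grid (200, 250, 400,
700, 750, 900 ms in 1 s). `fixture_sequence("thunderstruck")` is the
sixteen-note riff: isosynchronous eighth notes at 140 bpm (214.29 ms) over
3500 ms with six pitches (B5, A5, G#5, F#5, E5, D#5); the note *order* is a
stylised reconstruction (pedal-note alternation with a descending line) —
event count, grid and pitch set carry the quantitative content, the order
does not. `fixture_tempo_grid("bossa")` is a stylised syncopated grid
(interval cycle 300/200/150/250 ms) whose gain ratios against the riff grid
stay within (0.5, 2). These fixtures emulate the *task*, not recorded
behaviour: passing tests show the circuit's computational properties, not a
fit to empirical motor data.

## Problem sizes

Defaults used by the tests and the acceptance script: 200 excitatory units
(340 for the sixteen-action riff — disjoint 20-unit projections for K
actions need (K+1)·20 units); 1 s training windows (3.5 s for the riff);
100 gains for the rescaling grid; overlap scanned 0–50% in 5% steps;
scalar variability at 100 RTs × 20 simulations per condition (the
full-scale 500 × 100 sits behind `full_scale=True`); 10×10 gain plane;
20×20 weight planes.

## Known limitations and measured deviations

* **Rescaling dispersion**: the sum-of-ratios statistic across the gain
  grid has mean ≈ 7.6–7.7 but s.d. ≈ 0.25, dominated by the dt = 1
  ignition-mode flips described above; the underlying structure invariance
  (interval-ratio vector constant to ~3%) holds.
* **Overlap robustness** is probed at test time: training *with* shared
  assembly members is structurally unstable (the first assembly's formation
  saturates a shared unit's outgoing weights, and the trial-onset
  inhibition hole then ignites the next assembly through that unit), so
  the default re-run mode trains with orthogonal projections and overlaps
  the feedback target sets afterwards. The measured survival boundary of
  the complete six-action sequence is 20% overlap (degrading monotonically
  to two actions at 50%); the boundary is set by whether re-volleyed
  remnants of the extinguished assembly survive as partial attractors, a
  margin very sensitive to the switch parameters.
* **Gain plane**: the full-sequence region is γ_E ≥ γ_I; at exact equality
  the one-step inhibitory lag still carries the switch, so the boundary is
  inclusive rather than strict.
* The shared inhibitory population is a single unit; basal-ganglia
  pathways are lumped into one excitatory Go→Action projection; no spiking,
  no conductances, no learning of the sustain signals.
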