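# acdc-seq

A simulator for the **ACDC model** (associative cluster-dependent chain) of
flexible motor sequence production: a clustered excitatory rate RNN
(premotor cortex) gated by a basal-ganglia/thalamus module of Go, NoGo and
Action nodes. The model learns precisely timed, temporally asynchronous
action sequences with two local learning rules, and then — without touching
a single weight — shifts them in time, rescales them, replays them on a new
tempo, or holds individual actions, purely through inputs to the
basal-ganglia module.

It is aimed at computational neuroscientists studying cortico-basal
ganglia-thalamic loops, interval timing, and motor sequence flexibility.

## The model

*Order lives in cortex, time in the basal ganglia.* The excitatory RNN
(N = 200 rate units, rectified-sigmoid transfer Θ(u) = max(0, 2/(1+e^(−λu)) − 1))
forms cell assemblies of 20 units; persistent activity of assembly *i* is an
attractor state encoding ordinal position *i*. One shared inhibitory unit
balances the network. Per action *j*, a **Go** node integrates evidence from
its assembly with a slow time constant (τ_g = 1000 ms) — an
accumulation-to-bound process:

    τ_rnn dx_i/dt = −x_i + Θ(Σ_j W_ij x_j − J^EI x_I + J^EA γ_E a + x_in)
    τ_rnn dx_I/dt = −x_I + J^IE Σ x + J^IA γ_I Σ a
    τ_g  dg_j/dt = −g_j + Σ_i W^G_ji x_i − J^GN n_j        (rectified)
    τ_a  da_j/dt = −a_j + Θ(J^AG_j g_j − b)
    τ_n  dn_j/dt = −n_j + J^NA a_j

The **Action** node *a_j* (motor thalamus) fires when its Go input exceeds
the negative bias *b*; its near-binary volley (λ_a = 10⁴) excites the *next*
assembly and the shared inhibitory unit. Because γ_E (21.4) exceeds γ_I
(21), the volley extinguishes the current attractor and ignites the next —
the chain advances. The **NoGo** node then silences the executed action.

Learning: a Hebbian rule `dW/dt = −α₁(1−x_post)·x̄_pre + α₂·x_post·x̄_pre·(W_max−W)`
wires the assemblies (recurrent site) and each assembly to its Go node
(RNN→Go site), while a supervised delta rule `ΔW^AG = η·(t_observed − t_desired)`
tunes each Go→Action coupling to the tutor's target time, stage by stage,
until the timing error falls below φ = 10 ms.

Flexibility needs no weight changes: an additive input to the first Go node
shifts the whole sequence; a multiplicative gain ρ on the Go net input
rescales it (ρ > 1 compresses); a time-varying gain plays it on any new
tempo grid; a weak gain on one NoGo node (or a lowered Action→NoGo
coupling) sustains one action.

## Worked example

`examples/learn_and_replay.py` trains the six-action sequence with targets
at 200, 250, 400, 700, 750 and 900 ms and replays it with frozen weights:

```
targets (ms):       [200. 250. 400. 700. 750. 900.]
frozen events (ms): [199.6 251.6 397.6 697.6 753.6 904.6]
training trials per stage: [37, 561, 136, 17, 452, 119]
final Go->Action couplings: [ 2.9  11.23  4.36  1.96 10.2   4.17]
Go-node selectivity: [0.87 0.86 0.87 0.87 0.86 0.87]
```

Every action lands within 5 ms of its target. Short inter-action gaps need
large Go→Action couplings (the accumulator must reach the bound quickly),
which is also why those stages take the most trials — near the bound the
delta rule's per-trial error contraction shrinks as 1/W². The selectivity
index near 1 shows each Go node listens almost exclusively to its own
learned assembly: order and timing are stored in separate weights, which is
exactly what the modulation experiments exploit
(`examples/temporal_flexibility.py`, `examples/sustained_activation.py`,
`examples/thunderstruck_riff.py`, `examples/scalar_variability.py`,
`examples/robustness_sweeps.py`).

A thin command line mirrors the library (`acdc --help`): `train`, `run`,
`shift`, `rescale`, `compose`, `sustain`, `thunderstruck`,
`scalar-variability` and `sweep {regime|sustainability|gamma|overlap}`, each
writing tab-separated tables plus a JSON manifest that reproduces the run
bit-for-bit.

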