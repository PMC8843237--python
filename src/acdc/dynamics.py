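"""Forward dynamics: nonlinearity, single Euler steps, whole trials, events.

Five coupled rate equations are integrated with forward Euler (default
dt = 1 ms): excitatory RNN units with a rectified-sigmoid transfer, one
shared inhibitory unit, slowly integrating Go accumulators, near-binary
Action nodes with a negative bias (accumulation-to-bound), and NoGo units
driven by Action feedback. An action is "executed" at the first upward
crossing of the Action trace through ``rt_threshold``.

Two equivalent routes exist: :func:`step_network` is the transparent numpy
reference used for unit tests and custom plasticity hooks, while
:func:`simulate_trial` normally delegates to the compiled kernel in
``acdc._kernel`` (identical equations, looped for speed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, List, Optional, Union

import numpy as np

from ._kernel import run_trial_kernel
from ._rng import generator
from .architecture import Architecture, WeightSet
from .modulation import ModulationSignal
from .params import ModelParams

__all__ = [
    "theta",
    "lowpass_update",
    "NetworkState",
    "StepInputs",
    "TrialRecord",
    "step_network",
    "simulate_trial",
    "detect_action_times",
]


def theta(x, lam: float):
    """Rectified sigmoid ``max(0, 2 / (1 + exp(-lam x)) - 1)``, in [0, 1).

    Monotone non-decreasing, zero at and below the origin; ``lam`` sets the
    steepness (the Action nodes use a near-step gain).
    """
    if lam <= 0:
        raise ValueError(f"lam must be > 0, got {lam}")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("theta received a non-finite input")
    z = np.clip(lam * x, -700.0, 700.0)
    out = np.maximum(0.0, 2.0 / (1.0 + np.exp(-z)) - 1.0)
    return out if out.ndim else float(out)


def lowpass_update(trace, x, params: ModelParams):
    """One Euler step of the presynaptic low-pass trace (time scale tau_w)."""
    trace = np.asarray(trace, dtype=float)
    x = np.asarray(x, dtype=float)
    out = trace + (params.dt / params.tau_w) * (x - trace)
    return out if out.ndim else float(out)


@dataclass
class NetworkState:
    """Instantaneous state of every unit plus the Hebbian presynaptic trace."""

    x: np.ndarray        #: excitatory RNN rates (n_exc,)
    x_bar: np.ndarray    #: low-pass presynaptic traces (n_exc,)
    x_inh: float         #: shared inhibitory rate
    g: np.ndarray        #: Go rates (n_actions,)
    n: np.ndarray        #: NoGo rates (n_actions,)
    a: np.ndarray        #: Action rates (n_actions,)
    t: float = 0.0       #: current time (ms)

    @classmethod
    def zeros(cls, arch: Architecture) -> "NetworkState":
        return cls(x=np.zeros(arch.n_exc), x_bar=np.zeros(arch.n_exc),
                   x_inh=0.0, g=np.zeros(arch.n_actions),
                   n=np.zeros(arch.n_actions), a=np.zeros(arch.n_actions))


@dataclass
class StepInputs:
    """Per-step modulation values consumed by :func:`step_network`."""

    additive_go: np.ndarray      #: (n_actions,)
    gain_go: np.ndarray          #: (n_actions,)
    gain_nogo: np.ndarray        #: (n_actions,)
    context: float = 0.0         #: multiplier on params.x_in

    @classmethod
    def quiet(cls, n_actions: int, context: float = 0.0) -> "StepInputs":
        return cls(additive_go=np.zeros(n_actions), gain_go=np.ones(n_actions),
                   gain_nogo=np.ones(n_actions), context=context)


@dataclass
class TrialRecord:
    """Traces and detected events of one simulated trial."""

    time_ms: np.ndarray
    a: np.ndarray                       #: Action traces (n_steps + 1, n_actions)
    event_times: np.ndarray             #: first crossing per action (ms; NaN = not executed)
    crossing_counts: np.ndarray         #: number of upward threshold crossings
    event_order: np.ndarray             #: executed action indices sorted by time
    duration_ms: float
    dt: float
    x: Optional[np.ndarray] = None      #: excitatory traces (n_steps + 1, n_exc)
    inh: Optional[np.ndarray] = None    #: shared inhibitory trace
    g: Optional[np.ndarray] = None      #: Go traces
    n: Optional[np.ndarray] = None      #: NoGo traces

    @property
    def n_actions(self) -> int:
        return self.a.shape[1]

    @property
    def executed(self) -> np.ndarray:
        """Boolean mask of actions that crossed the execution threshold."""
        return ~np.isnan(self.event_times)

    @property
    def n_executed(self) -> int:
        return int(self.executed.sum())


def detect_action_times(a_traces: np.ndarray, params: ModelParams,
                        dt: Optional[float] = None):
    """First upward threshold crossing (and crossing count) per Action node.

    ``a_traces`` has shape (n_steps + 1, n_actions) with row s at time s*dt.
    Returns ``(event_times, crossing_counts)`` where a never-crossing node
    gets ``NaN``. The first crossing time is refined below the sampling step
    by linear interpolation between the bracketing samples. Later crossings
    are counted but do not change the event time (a re-executed action shows
    up as ``crossing_counts > 1``).
    """
    dt = params.dt if dt is None else dt
    thr = params.rt_threshold
    a = np.asarray(a_traces, dtype=float)
    above = a >= thr
    rising = above[1:] & ~above[:-1]
    n_actions = a.shape[1]
    event_times = np.full(n_actions, np.nan)
    counts = rising.sum(axis=0).astype(int)
    for k in range(n_actions):
        idx = np.flatnonzero(rising[:, k])
        if idx.size:
            s = idx[0]  # crossing between samples s and s+1
            lo, hi = a[s, k], a[s + 1, k]
            frac = (thr - lo) / (hi - lo) if hi > lo else 1.0
            event_times[k] = (s + frac) * dt
    return event_times, counts


def _event_order(event_times: np.ndarray) -> np.ndarray:
    """Executed action indices sorted by time, ties broken by action index."""
    executed = np.flatnonzero(~np.isnan(event_times))
    return executed[np.lexsort((executed, event_times[executed]))]


def step_network(state: NetworkState, weights: WeightSet, arch: Architecture,
                 params: ModelParams, inputs: Optional[StepInputs] = None,
                 rng: Optional[np.random.Generator] = None,
                 noise_values: Optional[dict] = None) -> NetworkState:
    """One forward-Euler step of the five rate equations (numpy reference).

    Per-step Gaussian noise (s.d. ``params.noise_sd``) perturbs the
    excitatory, inhibitory, Go and NoGo updates -- never the Action update.
    Raises if the state goes non-finite, naming the offending variable.
    """
    if inputs is None:
        inputs = StepInputs.quiet(arch.n_actions)
    p = params
    dt = p.dt
    fb = arch.feedback_matrix(p)
    j_na_vec = p.j_na_vector(arch.n_actions)

    noise = {}
    if p.noise_sd > 0:
        if noise_values is not None:
            noise = noise_values
        elif rng is not None:
            noise["x"] = rng.normal(0.0, p.noise_sd, arch.n_exc)
            noise["inh"] = rng.normal(0.0, p.noise_sd)
            noise["g"] = rng.normal(0.0, p.noise_sd, arch.n_actions)
            noise["n"] = rng.normal(0.0, p.noise_sd, arch.n_actions)
        else:
            raise ValueError("noise_sd > 0 requires an rng or noise_values")

    def _noise(key, tau):
        if p.noise_sd <= 0:
            return 0.0
        scale = (dt / tau) if p.noise_mode == "net_input" else 1.0
        return scale * noise[key]

    net_x = (weights.w_rec @ state.x - p.j_ei * state.x_inh
             + fb @ state.a + inputs.context * p.x_in * arch.input_mask())
    x_new = state.x + (dt / p.tau_rnn) * (theta(net_x, p.lambda_rnn) - state.x) \
        + _noise("x", p.tau_rnn)

    net_i = p.j_ie * state.x.sum() + p.j_ia * p.gamma_i * state.a.sum()
    xi_new = state.x_inh + (dt / p.tau_rnn) * (net_i - state.x_inh) \
        + _noise("inh", p.tau_rnn)

    go_drive = weights.w_rnn_go @ state.x
    if p.go_gain_on_drive_only:
        net_g = inputs.gain_go * go_drive - p.j_gn * state.n + inputs.additive_go
    else:
        net_g = inputs.gain_go * (go_drive - p.j_gn * state.n) + inputs.additive_go
    g_new = np.maximum(0.0, state.g + (dt / p.tau_g) * (net_g - state.g)
                       + _noise("g", p.tau_g))

    a_new = state.a + (dt / p.tau_a) * (
        theta(weights.w_ga * state.g - p.b, p.lambda_a) - state.a)

    net_n = inputs.gain_nogo * (j_na_vec * state.a)
    n_new = state.n + (dt / p.tau_n) * (net_n - state.n) + _noise("n", p.tau_n)

    xbar_new = lowpass_update(state.x_bar, state.x, p)

    for name, val in (("x", x_new), ("x_inh", xi_new), ("g", g_new),
                      ("a", a_new), ("n", n_new)):
        if not np.all(np.isfinite(val)):
            raise FloatingPointError(f"non-finite value in state variable '{name}' "
                                     f"at t = {state.t + dt} ms")

    return NetworkState(x=x_new, x_bar=xbar_new, x_inh=float(xi_new),
                        g=g_new, n=n_new, a=a_new, t=state.t + dt)


def _context_schedule(n_steps: int, params: ModelParams) -> np.ndarray:
    ctx = np.zeros(n_steps)
    pulse = int(round(params.input_pulse_ms / params.dt))
    ctx[:min(pulse, n_steps)] = 1.0
    return ctx


def simulate_trial(weights: WeightSet, arch: Architecture, params: ModelParams,
                   modulation: Optional[ModulationSignal] = None,
                   duration_ms: float = 1000.0, seed: int = 0,
                   plasticity: Union[None, str, Callable] = None,
                   n_plastic_go: Optional[int] = None,
                   record_full: bool = True) -> TrialRecord:
    """Integrate one trial from a zero state and detect action events.

    The context input is a square pulse on the input target units over the
    first ``params.input_pulse_ms`` of the trial (overridable through the
    modulation signal's ``context`` series).

    ``plasticity`` selects fast within-trial learning: ``"hebbian"`` runs
    the Hebbian sites every step and **updates ``weights`` in place** --
    the recurrent site globally, plus the first ``n_plastic_go`` recruited
    RNN->Go rows (default: all), each row potentiating only inside its
    association window (predecessors executed, own action not yet) and
    depressing outside it. A callable is invoked as ``hook(state, weights,
    params)`` after every step (slow reference path); ``None`` freezes the
    weights.
    """
    p = params
    steps = duration_ms / p.dt
    n_steps = int(round(steps))
    if abs(steps - n_steps) > 1e-9:
        raise ValueError(f"duration_ms={duration_ms} is not a multiple of dt={p.dt}")
    k = arch.n_actions

    if modulation is None:
        modulation = ModulationSignal.identity(duration_ms, k, p.dt)
    if modulation.n_actions != k:
        raise ValueError(f"modulation covers {modulation.n_actions} actions, "
                         f"architecture has {k}")
    if modulation.n_steps < n_steps:
        raise ValueError(f"modulation spans {modulation.n_steps} steps, "
                         f"trial needs {n_steps}")
    context = (modulation.context[:n_steps] if modulation.context is not None
               else _context_schedule(n_steps, p))

    if callable(plasticity):
        return _simulate_trial_reference(weights, arch, p, modulation, context,
                                         n_steps, seed, plasticity, record_full)
    if plasticity not in (None, "hebbian"):
        raise ValueError("plasticity must be None, 'hebbian', or a callable")

    use_noise = p.noise_sd > 0
    if use_noise:
        rng = generator(seed, "noise")
        noise_x = rng.normal(0.0, p.noise_sd, (n_steps, arch.n_exc))
        noise_i = rng.normal(0.0, p.noise_sd, n_steps)
        noise_g = rng.normal(0.0, p.noise_sd, (n_steps, k))
        noise_n = rng.normal(0.0, p.noise_sd, (n_steps, k))
    else:
        noise_x = np.zeros((0, 0))
        noise_i = np.zeros(0)
        noise_g = np.zeros((0, 0))
        noise_n = np.zeros((0, 0))

    x_tr, xi_tr, g_tr, n_tr, a_tr = run_trial_kernel(
        weights.w_rec, weights.w_rnn_go, weights.w_ga,
        arch.feedback_matrix(p), arch.input_mask(), p.j_na_vector(k),
        np.ascontiguousarray(modulation.additive_go[:n_steps]),
        np.ascontiguousarray(modulation.gain_go[:n_steps]),
        np.ascontiguousarray(modulation.gain_nogo[:n_steps]),
        np.ascontiguousarray(context, dtype=float),
        noise_x, noise_i, noise_g, noise_n,
        use_noise, p.noise_mode == "net_input",
        plasticity == "hebbian",
        (k if n_plastic_go is None else int(n_plastic_go)) if plasticity == "hebbian" else 0,
        record_full, p.zero_self_connections, p.go_gain_on_drive_only,
        p.onset_threshold, p.ltp_volley_fraction, p.context_until_onset,
        p.ltp_volley_fraction * p.j_ea * p.gamma_e, 0.5 * p.x_in,
        p.dt * p.hebbian_rec_scale,
        p.dt * p.hebbian_go_scale,
        p.dt, p.tau_rnn, p.tau_w, p.tau_g, p.tau_a, p.tau_n,
        p.j_ei, p.j_ie, p.j_ia, p.j_gn, p.b,
        p.lambda_rnn, p.lambda_a, p.x_in, p.gamma_i,
        p.alpha1_rnn, p.alpha2_rnn, p.wmax_rnn,
        p.alpha1_rnn_go, p.alpha2_rnn_go, p.wmax_rnn_go)

    for name, tr in (("x", x_tr), ("inh", xi_tr), ("g", g_tr), ("a", a_tr)):
        if not np.all(np.isfinite(tr)):
            raise FloatingPointError(f"non-finite values in trace '{name}'")

    return _build_record(a_tr, p, duration_ms, n_steps,
                         x_tr if record_full else None,
                         xi_tr if record_full else None,
                         g_tr if record_full else None,
                         n_tr if record_full else None)


def _simulate_trial_reference(weights, arch, p, modulation, context, n_steps,
                              seed, hook, record_full) -> TrialRecord:
    """Pure-numpy trial loop via :func:`step_network` (custom hooks, tests).

    Noise arrays are pregenerated in the same layout as the compiled path so
    both routes consume identical draws for a given seed.
    """
    k = arch.n_actions
    noise_steps = None
    if p.noise_sd > 0:
        rng = generator(seed, "noise")
        nx = rng.normal(0.0, p.noise_sd, (n_steps, arch.n_exc))
        ni = rng.normal(0.0, p.noise_sd, n_steps)
        ng = rng.normal(0.0, p.noise_sd, (n_steps, k))
        nn = rng.normal(0.0, p.noise_sd, (n_steps, k))
        noise_steps = [{"x": nx[t], "inh": ni[t], "g": ng[t], "n": nn[t]}
                       for t in range(n_steps)]
    state = NetworkState.zeros(arch)
    sequence_started = False
    a_tr = np.zeros((n_steps + 1, k))
    if record_full:
        x_tr = np.zeros((n_steps + 1, arch.n_exc))
        xi_tr = np.zeros(n_steps + 1)
        g_tr = np.zeros((n_steps + 1, k))
        n_tr = np.zeros((n_steps + 1, k))
    for t in range(n_steps):
        ctx = context[t]
        if p.context_until_onset and sequence_started:
            ctx = 0.0
        inputs = StepInputs(additive_go=modulation.additive_go[t],
                            gain_go=modulation.gain_go[t],
                            gain_nogo=modulation.gain_nogo[t],
                            context=ctx)
        state = step_network(state, weights, arch, p, inputs,
                             noise_values=(noise_steps[t] if noise_steps else None))
        if state.a[0] >= p.onset_threshold:
            sequence_started = True
        if hook is not None:
            hook(state, weights, p)
        a_tr[t + 1] = state.a
        if record_full:
            x_tr[t + 1] = state.x
            xi_tr[t + 1] = state.x_inh
            g_tr[t + 1] = state.g
            n_tr[t + 1] = state.n
    return _build_record(a_tr, p, n_steps * p.dt, n_steps,
                         x_tr if record_full else None,
                         xi_tr if record_full else None,
                         g_tr if record_full else None,
                         n_tr if record_full else None)


def _build_record(a_tr, p, duration_ms, n_steps, x_tr, xi_tr, g_tr, n_tr):
    event_times, counts = detect_action_times(a_tr, p)
    return TrialRecord(time_ms=np.arange(n_steps + 1) * p.dt, a=a_tr,
                       event_times=event_times, crossing_counts=counts,
                       event_order=_event_order(event_times),
                       duration_ms=float(duration_ms), dt=p.dt,
                       x=x_tr, inh=xi_tr, g=g_tr, n=n_tr)
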