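"""Basal-ganglia input signals: the levers of temporal flexibility.

After a sequence is learned, its expression is manipulated *without weight
changes* through inputs to the Go/NoGo module:

* additive input to the first Go node   -> temporal shifting (earlier/later)
* constant multiplicative gain rho      -> temporal rescaling (compress/dilate)
* time-varying multiplicative gain      -> temporal compositionality (new tempo)
* weak multiplicative gain on a NoGo    -> sustained activation of one action
  node (or, alternatively, a lowered Action->NoGo coupling)

A :class:`ModulationSignal` stores dense per-step, per-node series so the
integration kernel can consume them directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .params import ModelParams

__all__ = [
    "ModulationSignal",
    "make_shift_signal",
    "make_rescale_signal",
    "make_tempo_signal",
    "make_sustain_signal",
    "weaken_an_coupling",
]


def _n_steps(window_ms: float, dt: float) -> int:
    steps = window_ms / dt
    rounded = int(round(steps))
    if abs(steps - rounded) > 1e-9:
        raise ValueError(f"window_ms={window_ms} is not a multiple of dt={dt}")
    return rounded


@dataclass
class ModulationSignal:
    """Per-step additive and multiplicative inputs to the BG module.

    ``additive_go``/``gain_go``/``gain_nogo`` have shape (n_steps, n_actions);
    ``context`` optionally overrides the default context-pulse schedule with a
    per-step multiplier on the context input magnitude.
    """

    additive_go: np.ndarray
    gain_go: np.ndarray
    gain_nogo: np.ndarray
    context: Optional[np.ndarray] = None
    dt: float = 1.0

    def __post_init__(self) -> None:
        if not (self.additive_go.shape == self.gain_go.shape == self.gain_nogo.shape):
            raise ValueError("modulation series must share one (n_steps, n_actions) shape")
        if np.any(self.gain_go < 0) or np.any(self.gain_nogo < 0):
            raise ValueError("multiplicative gains must be >= 0")

    @property
    def n_steps(self) -> int:
        return self.additive_go.shape[0]

    @property
    def n_actions(self) -> int:
        return self.additive_go.shape[1]

    @classmethod
    def identity(cls, window_ms: float, n_actions: int, dt: float = 1.0) -> "ModulationSignal":
        """The no-modulation signal (zero additive input, unit gains)."""
        t = _n_steps(window_ms, dt)
        return cls(additive_go=np.zeros((t, n_actions)),
                   gain_go=np.ones((t, n_actions)),
                   gain_nogo=np.ones((t, n_actions)),
                   context=None, dt=dt)

    def is_identity(self) -> bool:
        return (not self.additive_go.any()
                and np.all(self.gain_go == 1.0)
                and np.all(self.gain_nogo == 1.0)
                and self.context is None)

    # -- tabular text representation -----------------------------------------
    # piecewise-constant signals are stored as step functions: each row
    # (kind, node, t_ms, value) sets the series from t_ms onward.

    def to_file(self, path) -> None:
        """Write as tab-separated step-function rows (lossless for the
        piecewise-constant signals the constructors produce)."""
        import pandas as pd

        rows = [("meta", -1, self.n_steps * self.dt, self.dt)]
        series = {"additive_go": self.additive_go, "gain_go": self.gain_go,
                  "gain_nogo": self.gain_nogo}
        if self.context is not None:
            series["context"] = self.context[:, None]
        for kind, arr in series.items():
            for node in range(arr.shape[1]):
                col = arr[:, node]
                change = np.flatnonzero(np.diff(col)) + 1
                for idx in np.concatenate([[0], change]):
                    rows.append((kind, node if arr.shape[1] > 1 else -1,
                                 idx * self.dt, col[idx]))
        pd.DataFrame(rows, columns=["kind", "node", "t_ms", "value"]).to_csv(
            path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_file(cls, path) -> "ModulationSignal":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        meta = df[df.kind == "meta"].iloc[0]
        window_ms, dt = float(meta.t_ms), float(meta.value)
        n_steps = int(round(window_ms / dt))
        nodes = {k: int(df[df.kind == k].node.max()) + 1
                 for k in ("additive_go", "gain_go", "gain_nogo")}
        n_actions = max(1, *nodes.values())
        sig = cls.identity(window_ms, n_actions, dt)
        has_context = (df.kind == "context").any()
        if has_context:
            sig.context = np.zeros(n_steps)
        series = {"additive_go": sig.additive_go, "gain_go": sig.gain_go,
                  "gain_nogo": sig.gain_nogo}
        if has_context:
            series["context"] = sig.context[:, None]
        for kind, arr in series.items():
            sub = df[df.kind == kind].sort_values("t_ms")
            for _, row in sub.iterrows():
                start = int(round(row.t_ms / dt))
                cols = [int(row.node)] if row.node >= 0 else list(range(arr.shape[1]))
                for c in cols:
                    arr[start:, c] = row.value
        if has_context:
            sig.context = series["context"][:, 0]
        return sig


def make_shift_signal(amplitude: float, duration_ms: float, n_actions: int,
                      window_ms: float = 1000.0, dt: float = 1.0) -> ModulationSignal:
    """Additive input to the *first* Go node over the initial ``duration_ms``.

    Positive amplitude starts the sequence earlier, negative later; the
    inter-action structure is untouched.
    """
    sig = ModulationSignal.identity(window_ms, n_actions, dt)
    stop = min(_n_steps(duration_ms, dt), sig.n_steps)
    sig.additive_go[:stop, 0] = amplitude
    return sig


def make_rescale_signal(rho: float, n_actions: int,
                        window_ms: float = 1000.0, dt: float = 1.0,
                        spare_first: bool = False) -> ModulationSignal:
    """Constant multiplicative gain rho on every Go node's net input.

    rho > 1 compresses the sequence, 0 < rho < 1 dilates it. With
    ``spare_first`` the first Go node keeps unit gain, avoiding the small
    onset shift a global gain induces.
    """
    if rho <= 0:
        raise ValueError(f"rho must be > 0, got {rho}")
    sig = ModulationSignal.identity(window_ms, n_actions, dt)
    sig.gain_go[:, (1 if spare_first else 0):] = rho
    return sig


def make_tempo_signal(trained_times_ms: Sequence[float],
                      desired_times_ms: Sequence[float],
                      window_ms: float, dt: float = 1.0,
                      params: Optional[ModelParams] = None,
                      correction: str = "exponential") -> ModulationSignal:
    """Piecewise-constant Go gain that re-times a learned sequence.

    On the segment leading up to the k-th desired event the gain is chosen so
    the k-th Go accumulator, which was trained to need ``trained_interval_k``,
    reaches its bound after ``desired_interval_k`` instead. Because the Go
    node is a leaky accumulator with time constant ``tau_g``, the exact gain
    is ``(1 - exp(-dt_trained/tau_g)) / (1 - exp(-dt_desired/tau_g))``
    (``correction="exponential"``, default); ``correction="linear"`` uses the
    plain interval ratio ``dt_trained / dt_desired``, adequate for intervals
    much shorter than ``tau_g``.
    """
    trained = np.asarray(trained_times_ms, dtype=float)
    desired = np.asarray(desired_times_ms, dtype=float)
    if trained.shape != desired.shape:
        raise ValueError("trained and desired time lists must have equal length")
    if np.any(np.diff(desired) <= 0) or desired[0] <= 0:
        raise ValueError("desired times must be strictly increasing and > 0")
    if desired[-1] > window_ms:
        raise ValueError("desired times must fit within window_ms")
    if correction not in ("exponential", "linear"):
        raise ValueError("correction must be 'exponential' or 'linear'")

    tau_g = (params or ModelParams()).tau_g
    d_train = np.diff(np.concatenate([[0.0], trained]))
    d_des = np.diff(np.concatenate([[0.0], desired]))
    if np.any(d_des == 0):
        raise ValueError("desired intervals must be non-zero")
    if correction == "exponential":
        rhos = -np.expm1(-d_train / tau_g) / -np.expm1(-d_des / tau_g)
    else:
        rhos = d_train / d_des

    n_actions = len(trained)
    sig = ModulationSignal.identity(window_ms, n_actions, dt)
    bounds = np.concatenate([[0.0], desired])
    for k in range(n_actions):
        lo = int(round(bounds[k] / dt))
        hi = int(round(bounds[k + 1] / dt))
        sig.gain_go[lo:hi, :] = rhos[k]
    return sig


def make_sustain_signal(action_index: int, t_start_ms: float, t_end_ms: float,
                        n_actions: int, window_ms: float = 1000.0,
                        rho: float = 0.1, dt: float = 1.0,
                        target: str = "nogo") -> ModulationSignal:
    """Weak multiplicative gain on one NoGo (default) or Go node's net input.

    Damping the NoGo node's drive over ``[t_start_ms, t_end_ms]`` removes the
    shutdown of the executed action, sustaining its Action node.
    """
    if not 0 <= t_start_ms <= t_end_ms <= window_ms:
        raise ValueError("need 0 <= t_start_ms <= t_end_ms <= window_ms")
    if target not in ("nogo", "go"):
        raise ValueError("target must be 'nogo' or 'go'")
    sig = ModulationSignal.identity(window_ms, n_actions, dt)
    lo = int(round(t_start_ms / dt))
    hi = int(round(t_end_ms / dt))
    series = sig.gain_nogo if target == "nogo" else sig.gain_go
    series[lo:hi, action_index] = rho
    return sig


def weaken_an_coupling(params: ModelParams, action_index: int, new_j_na: float,
                       n_actions: int) -> ModelParams:
    """Parameter variant with one Action->NoGo coupling overridden.

    Lowering J^NA for one action slows that action's NoGo shutdown and
    lengthens its supra-threshold duration (the learning-based route to
    sustained activation).
    """
    if new_j_na < 0:
        raise ValueError("new_j_na must be >= 0")
    base = (list(params.j_na_per_action) if params.j_na_per_action is not None
            else [params.j_na] * n_actions)
    if not 0 <= action_index < n_actions:
        raise IndexError(f"action_index {action_index} out of range for {n_actions} actions")
    base[action_index] = new_j_na
    return params.replace(j_na_per_action=tuple(base))
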