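"""Learning: fast Hebbian wiring within trials, slow delta-rule timing between.

Two plastic sites share one Hebbian rule: recurrent weights among excitatory
RNN units (cluster formation) and RNN->Go weights (each cluster recruits its
Go node). The rule potentiates when filtered presynaptic and instantaneous
postsynaptic activity coincide, pushing weights toward a ceiling, and
depresses otherwise; weights are clamped to [0, wmax].

Action *timing* is learned by a supervised delta rule on the Go->Action
couplings: the signed difference between observed and desired execution time
(in seconds) scales the weight change, so an action produced too late gets a
stronger coupling and fires earlier on the next trial.

Sequences are trained stage by stage: the first action is timed to criterion
(|error| < phi) before delta updates move to the second, and so on, while
Hebbian learning runs globally within every training trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import substream
from .architecture import Architecture, WeightSet, build_architecture, initialize_weights
from .dynamics import simulate_trial
from .params import ModelParams

__all__ = [
    "SequenceSpec",
    "LearningCurve",
    "TrainingResult",
    "TrainingError",
    "hebbian_update",
    "delta_update",
    "train_sequence",
    "selectivity_index",
]


@dataclass(frozen=True)
class SequenceSpec:
    """Ordered target execution times (ms) within one trial window."""

    target_times_ms: Tuple[float, ...]
    window_ms: float = 1000.0
    note_labels: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        t = np.asarray(self.target_times_ms, dtype=float)
        if t.size < 1:
            raise ValueError("a sequence needs at least one target time")
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("target times must be strictly increasing and > 0")
        if t[-1] > self.window_ms:
            raise ValueError("target times must fit within window_ms")
        if self.note_labels is not None and len(self.note_labels) != t.size:
            raise ValueError("note_labels must match target_times_ms in length")

    @property
    def n_actions(self) -> int:
        return len(self.target_times_ms)

    @property
    def target_times_s(self) -> np.ndarray:
        return np.asarray(self.target_times_ms, dtype=float) / 1000.0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "order_index": np.arange(self.n_actions),
            "target_time_ms": list(self.target_times_ms),
        })
        if self.note_labels is not None:
            df["note_label"] = list(self.note_labels)
        return df

    def to_file(self, path) -> None:
        """Write as tab-separated text (round-trips exactly via from_file)."""
        df = self.to_frame()
        df["window_ms"] = self.window_ms
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_file(cls, path) -> "SequenceSpec":
        df = pd.read_csv(path, sep="\t")
        labels = (tuple(df["note_label"]) if "note_label" in df.columns else None)
        return cls(target_times_ms=tuple(df["target_time_ms"]),
                   window_ms=float(df["window_ms"].iloc[0]),
                   note_labels=labels)


@dataclass
class LearningCurve:
    """Per-trial, per-action timing errors and Go->Action weights."""

    frame: pd.DataFrame  #: columns trial, stage, action_index, error_s, w_ga

    def final_errors(self) -> np.ndarray:
        """Signed timing error (s) per action on the last trial recorded."""
        last = self.frame[self.frame.trial == self.frame.trial.max()]
        return last.sort_values("action_index").error_s.to_numpy()

    def errors_for(self, action_index: int) -> pd.DataFrame:
        return self.frame[self.frame.action_index == action_index]

    @property
    def n_trials(self) -> int:
        return int(self.frame.trial.max()) + 1 if len(self.frame) else 0

    def to_file(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


@dataclass
class TrainingResult:
    weights: WeightSet
    curve: LearningCurve
    arch: Architecture
    params: ModelParams
    spec: SequenceSpec
    trials_per_stage: List[int]


class TrainingError(RuntimeError):
    """Sequence training failed; carries the partial state for diagnosis."""

    def __init__(self, message: str, curve: LearningCurve, weights: WeightSet):
        super().__init__(message)
        self.curve = curve
        self.weights = weights


def hebbian_update(w: np.ndarray, pre_trace: np.ndarray, post: np.ndarray,
                   alpha1: float, alpha2: float, wmax: float,
                   params: ModelParams) -> np.ndarray:
    """One Euler step of the Hebbian rule, clamped to [0, wmax].

    ``dW[i, j] = (-alpha1 (1 - post_i) pre_j + alpha2 post_i pre_j
    (wmax - W[i, j])) * dt`` for postsynaptic rates ``post`` and low-pass
    presynaptic traces ``pre_trace``; the same Euler step ``dt`` as the
    dynamics. Works for both plastic sites (rows = postsynaptic units,
    columns = presynaptic RNN units).
    """
    pre = np.asarray(pre_trace, dtype=float)
    post = np.asarray(post, dtype=float)
    if w.shape != (post.size, pre.size):
        raise ValueError(f"weight shape {w.shape} does not match "
                         f"(post={post.size}, pre={pre.size})")
    dw = (-alpha1 * np.outer(1.0 - post, pre)
          + alpha2 * np.outer(post, pre) * (wmax - w)) * params.dt
    return np.clip(w + dw, 0.0, wmax)


def delta_update(w: float, t_observed_s: float, t_desired_s: float,
                 eta: float) -> float:
    """Supervised timing update: ``w + eta * (t_observed - t_desired)``.

    Times are in seconds. A too-slow execution (observed > desired) increases
    the Go->Action coupling, so the bound is reached earlier next trial.
    """
    if eta <= 0:
        raise ValueError(f"eta must be > 0, got {eta}")
    return w + eta * (t_observed_s - t_desired_s)


def _default_architecture(spec: SequenceSpec, seed: int,
                          cluster_size: int = 20,
                          overlap_frac: float = 0.0) -> Architecture:
    n_needed = (spec.n_actions + 1) * cluster_size
    return build_architecture(n_exc=max(200, n_needed), cluster_size=cluster_size,
                              n_actions=spec.n_actions, overlap_frac=overlap_frac,
                              seed=seed)


def train_sequence(spec: SequenceSpec, params: Optional[ModelParams] = None,
                   arch: Optional[Architecture] = None, seed: int = 0,
                   max_trials: int = 1000) -> TrainingResult:
    """Train a sequence to the phi timing criterion, stage by stage.

    Stage i runs training trials (Hebbian learning on within each trial) and
    applies the delta rule to action i's Go->Action weight between trials
    until |observed - desired| < phi seconds; earlier actions' weights stay
    at their converged values. A trial in which the staged action never
    executes uses the window end as the observed time (maximal corrective
    update). ``max_trials`` bounds each stage; exceeding it, or a timing
    error that grows for five consecutive trials, raises
    :class:`TrainingError` carrying the learning curve.
    """
    params = params or ModelParams()
    arch = arch or _default_architecture(spec, seed)
    if arch.n_actions != spec.n_actions:
        raise ValueError(f"architecture has {arch.n_actions} actions, "
                         f"spec has {spec.n_actions}")
    weights = initialize_weights(arch, params, seed)
    targets_s = spec.target_times_s
    window_s = spec.window_ms / 1000.0
    k = spec.n_actions

    rows: List[tuple] = []
    trials_per_stage: List[int] = []
    trial = 0

    def _record(errors_s: np.ndarray, stage: int) -> None:
        for j in range(k):
            rows.append((trial, stage, j, errors_s[j], weights.w_ga[j]))

    def _curve() -> LearningCurve:
        return LearningCurve(pd.DataFrame(
            rows, columns=["trial", "stage", "action_index", "error_s", "w_ga"]))

    for stage in range(k):
        prev_abs = np.inf
        grow_streak = 0
        for it in range(max_trials):
            trial_seed = int(substream(seed, "train-noise", trial).generate_state(1)[0])
            rec = simulate_trial(weights, arch, params, duration_ms=spec.window_ms,
                                 seed=trial_seed, plasticity="hebbian",
                                 n_plastic_go=stage + 1, record_full=False)
            observed_s = np.where(np.isnan(rec.event_times), window_s,
                                  rec.event_times / 1000.0)
            errors_s = observed_s - targets_s
            _record(errors_s, stage)
            err = errors_s[stage]
            trial += 1
            if abs(err) < params.phi:
                trials_per_stage.append(it + 1)
                break
            grow_streak = grow_streak + 1 if abs(err) > prev_abs else 0
            prev_abs = abs(err)
            # a long streak only: the error legitimately grows for a dozen
            # trials while within-trial Hebbian wiring is still maturing
            if grow_streak >= 25:
                raise TrainingError(
                    f"timing error for action {stage} grew on 25 consecutive "
                    f"trials (|error| = {abs(err):.3f} s)", _curve(), weights)
            # delta updates for the staged action plus maintenance updates
            # for already-converged actions, whose timing would otherwise
            # drift while later stages' Hebbian wiring matures
            for j in range(stage + 1):
                weights.w_ga[j] = delta_update(weights.w_ga[j], observed_s[j],
                                               targets_s[j], params.eta)
        else:
            raise TrainingError(
                f"action {stage} did not reach |error| < phi = {params.phi} s "
                f"within {max_trials} trials", _curve(), weights)

    return TrainingResult(weights=weights, curve=_curve(), arch=arch,
                          params=params, spec=spec,
                          trials_per_stage=trials_per_stage)


def selectivity_index(w_rnn_go: np.ndarray, arch: Architecture) -> np.ndarray:
    """Per Go node, the fraction of incoming weight from its own cluster.

    1.0 means perfectly selective wiring; a uniform matrix scores
    ``cluster_size / n_exc``. A node with zero total incoming weight gets
    ``NaN`` (selectivity undefined).
    """
    w = np.asarray(w_rnn_go, dtype=float)
    if w.shape != (arch.n_actions, arch.n_exc):
        raise ValueError(f"w_rnn_go shape {w.shape} does not match architecture "
                         f"({arch.n_actions}, {arch.n_exc})")
    clusters = arch.cluster_members
    out = np.full(arch.n_actions, np.nan)
    totals = w.sum(axis=1)
    for j in range(arch.n_actions):
        if totals[j] > 0:
            out[j] = w[j, clusters[j]].sum() / totals[j]
    return out
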