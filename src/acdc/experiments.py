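"""Study reproductions: learning, flexibility, behavior, and robustness sweeps.

Each function composes the library primitives (training, frozen trials,
modulation signals) into one published computational experiment and returns
plain data structures (dataclasses and pandas DataFrames) ready for export
or assertion:

* sequence learning and frozen reproduction;
* temporal shifting (additive Go input) with the shift-vs-duration line;
* temporal rescaling (multiplicative gain) with the sum-of-ratios structure
  statistic over a grid of gains;
* temporal compositionality (time-varying gain onto a new tempo grid);
* the sixteen-note riff demo replayed on a bossa-nova-style grid;
* scalar variability of noisy reaction times;
* robustness sweeps: fixed-connectivity regimes, sustainability vs the
  Action->NoGo coupling, the feedback-gain plane, and input overlap;
* PCA of the excitatory population trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import substream
from .architecture import Architecture, WeightSet, build_architecture
from .dynamics import TrialRecord, simulate_trial
from .modulation import (ModulationSignal, make_rescale_signal,
                         make_shift_signal, make_tempo_signal)
from .params import ModelParams
from .plasticity import (SequenceSpec, TrainingError, TrainingResult,
                         train_sequence)

__all__ = [
    "sum_of_ratios",
    "sustainability_auc",
    "pca_trajectory",
    "SweepResult",
    "run_learning_experiment",
    "run_shift_experiment",
    "run_rescale_experiment",
    "run_composition_experiment",
    "run_thunderstruck_demo",
    "run_scalar_variability",
    "sweep_regime",
    "sweep_sustainability",
    "sweep_gamma",
    "sweep_overlap",
    "ideal_weights",
]


# --------------------------------------------------------------------------
# derived statistics
# --------------------------------------------------------------------------

def sum_of_ratios(event_times_ms: Sequence[float]) -> float:
    """Structure statistic: sum of consecutive-triplet interval ratios.

    For times t_1 < ... < t_K the statistic is
    ``sum_k (t_{k+2} - t_{k+1}) / (t_{k+1} - t_k)`` over all K-2 triplets;
    it is invariant under uniform temporal rescaling of the sequence.
    """
    t = np.asarray(event_times_ms, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 event times")
    d = np.diff(t)
    if np.any(d <= 0):
        raise ValueError("event times must be strictly increasing (no zero intervals)")
    return float(np.sum(d[1:] / d[:-1]))


def sustainability_auc(record: TrialRecord) -> float:
    """Normalised area of Action activity above 0.5.

    ``sum_j integral max(a_j(t) - 0.5, 0) dt / duration`` -- zero when no
    action exceeds 0.5, and 0.5 for one action pinned at 1 over the whole
    window. Callers report 0 for incomplete sequences.
    """
    excess = np.maximum(record.a - 0.5, 0.0)
    return float(excess.sum() * record.dt / record.duration_ms)


def pca_trajectory(record: TrialRecord, n_components: int = 3):
    """Principal components of the excitatory population trajectory.

    Treats time points as samples, units as features. Returns
    ``(components, explained_variance_ratio)`` where ``components`` has shape
    (n_timepoints, n_components).
    """
    from sklearn.decomposition import PCA

    if record.x is None:
        raise ValueError("record has no excitatory traces (record_full=False)")
    pca = PCA(n_components=n_components)
    comps = pca.fit_transform(record.x)
    return comps, pca.explained_variance_ratio_


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Outcome grid of a two-parameter robustness sweep."""

    param_names: Tuple[str, ...]
    grids: Tuple[np.ndarray, ...]
    outcomes: np.ndarray          #: shape (len(grid_0), len(grid_1)) or (len(grid_0),)
    outcome_name: str
    seed: int
    metadata: Dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if self.outcomes.ndim == 1:
            return pd.DataFrame({self.param_names[0]: self.grids[0],
                                 self.outcome_name: self.outcomes})
        g0, g1 = np.meshgrid(self.grids[0], self.grids[1], indexing="ij")
        return pd.DataFrame({self.param_names[0]: g0.ravel(),
                             self.param_names[1]: g1.ravel(),
                             self.outcome_name: self.outcomes.ravel()})


# --------------------------------------------------------------------------
# hand-wired networks (fixed-connectivity regime analyses)
# --------------------------------------------------------------------------

def ideal_weights(arch: Architecture, params: ModelParams,
                  rec_weight: Optional[float] = None,
                  go_weight: Optional[float] = None,
                  ga_weight=None) -> WeightSet:
    """Hand-wired selective connectivity (no learning).

    Within-cluster recurrent weights at ``rec_weight`` (default: the
    recurrent ceiling), each Go node selectively driven by its own cluster at
    ``go_weight`` per synapse (default: the RNN->Go ceiling), and uniform or
    per-action Go->Action couplings ``ga_weight`` (default: the analytic
    values that place each action on the learned grid are *not* computed
    here -- pass explicit values).
    """
    rec_w = params.wmax_rnn if rec_weight is None else rec_weight
    go_w = params.wmax_rnn_go if go_weight is None else go_weight
    n, k = arch.n_exc, arch.n_actions
    w_rec = np.zeros((n, n))
    w_go = np.zeros((k, n))
    for j, members in enumerate(arch.cluster_members):
        w_rec[np.ix_(members, members)] = rec_w
        w_go[j, members] = go_w
    if ga_weight is None:
        ga = np.full(k, 2.0)
    else:
        ga = np.broadcast_to(np.asarray(ga_weight, dtype=float), (k,)).copy()
    return WeightSet(w_rec=w_rec, w_rnn_go=w_go, w_ga=ga)


# --------------------------------------------------------------------------
# learning and flexibility experiments
# --------------------------------------------------------------------------

def run_learning_experiment(spec: SequenceSpec,
                            params: Optional[ModelParams] = None,
                            seed: int = 0,
                            arch: Optional[Architecture] = None,
                            max_trials: int = 1000):
    """Train a sequence, then reproduce it with frozen weights.

    Returns ``(TrainingResult, TrialRecord)``: the full learning curve and
    one frozen trial over the training window.
    """
    params = params or ModelParams()
    result = train_sequence(spec, params, arch=arch, seed=seed,
                            max_trials=max_trials)
    record = simulate_trial(result.weights, result.arch, params,
                            duration_ms=spec.window_ms, seed=seed)
    return result, record


def run_shift_experiment(trained: TrainingResult,
                         amplitudes: Sequence[float] = (1.0, -1.0),
                         durations_ms: Sequence[float] = (0., 10., 20., 30., 40., 50., 60., 70., 80., 90., 100.),
                         trial_ms: float = 1300.0) -> pd.DataFrame:
    """Temporal shifting: additive input to the first Go node.

    For every (amplitude, duration) the first-event shift relative to the
    unmodulated baseline is measured, together with the change in the
    inter-event-interval vector (sequence structure). Returns a tidy frame
    with one row per condition plus per-amplitude linear-fit columns
    (``slope_ms_per_ms``, ``r_squared`` repeated on each row of the fit's
    amplitude).
    """
    p, w, arch = trained.params, trained.weights, trained.arch
    k = arch.n_actions
    base = simulate_trial(w, arch, p, duration_ms=trial_ms)
    if not np.all(base.executed):
        raise RuntimeError("baseline trial did not execute the full sequence")
    base_first = base.event_times[0]
    base_intervals = np.diff(base.event_times)

    rows = []
    for amp in amplitudes:
        for dur in durations_ms:
            sig = make_shift_signal(amp, dur, k, window_ms=trial_ms, dt=p.dt)
            rec = simulate_trial(w, arch, p, modulation=sig, duration_ms=trial_ms)
            complete = bool(np.all(rec.executed))
            shift = rec.event_times[0] - base_first if rec.executed[0] else np.nan
            max_dev = (np.abs(np.diff(rec.event_times) - base_intervals).max()
                       if complete else np.nan)
            rows.append((amp, dur, shift, complete, max_dev))
    df = pd.DataFrame(rows, columns=["amplitude", "duration_ms", "shift_ms",
                                     "complete", "max_interval_change_ms"])
    for amp in amplitudes:
        sub = df[(df.amplitude == amp) & df.shift_ms.notna()]
        slope, intercept = np.polyfit(sub.duration_ms, sub.shift_ms, 1)
        pred = slope * sub.duration_ms + intercept
        ss_res = float(((sub.shift_ms - pred) ** 2).sum())
        ss_tot = float(((sub.shift_ms - sub.shift_ms.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        df.loc[df.amplitude == amp, "slope_ms_per_ms"] = slope
        df.loc[df.amplitude == amp, "r_squared"] = r2
    return df


def run_rescale_experiment(trained: TrainingResult,
                           rhos: Optional[np.ndarray] = None,
                           trial_ms: float = 1300.0):
    """Temporal rescaling: constant multiplicative gain on all Go nodes.

    For each gain the six action times are detected and the sum-of-ratios
    structure statistic computed from the *measured* times. Returns
    ``(DataFrame, summary_dict)`` where the summary holds the mean and s.d.
    of the statistic over the gains that produced the complete sequence,
    plus the statistic of the nominal target grid for reference.
    """
    p, w, arch = trained.params, trained.weights, trained.arch
    k = arch.n_actions
    rhos = np.linspace(0.9, 1.2, 100) if rhos is None else np.asarray(rhos, float)
    rows = []
    for rho in rhos:
        sig = make_rescale_signal(float(rho), k, window_ms=trial_ms, dt=p.dt)
        rec = simulate_trial(w, arch, p, modulation=sig, duration_ms=trial_ms)
        complete = bool(np.all(rec.executed))
        sor = sum_of_ratios(rec.event_times) if complete else np.nan
        rows.append((rho, complete, sor, *rec.event_times))
    cols = ["rho", "complete", "sum_of_ratios"] + [f"t{j}" for j in range(k)]
    df = pd.DataFrame(rows, columns=cols)
    ok = df[df.complete]
    summary = {
        "mean_sum_of_ratios": float(ok.sum_of_ratios.mean()),
        "sd_sum_of_ratios": float(ok.sum_of_ratios.std(ddof=1)),
        "n_complete": int(df.complete.sum()),
        "n_rhos": len(df),
        "nominal_sum_of_ratios": sum_of_ratios(trained.spec.target_times_ms),
    }
    return df, summary


def run_composition_experiment(trained: TrainingResult,
                               desired_times_ms: Sequence[float],
                               trial_ms: Optional[float] = None):
    """Temporal compositionality: replay the sequence on a new tempo grid.

    Builds the piecewise-constant gain signal from the model's own measured
    (trained) times and the desired grid, runs one frozen trial, and reports
    the deviations of produced events from the desired times.
    """
    p, w, arch = trained.params, trained.weights, trained.arch
    desired = np.asarray(desired_times_ms, dtype=float)
    if trial_ms is None:
        trial_ms = float(np.ceil((desired[-1] + 100.0) / 100.0) * 100.0)
    base = simulate_trial(w, arch, p, duration_ms=trained.spec.window_ms)
    if not np.all(base.executed):
        raise RuntimeError("trained model did not reproduce its sequence")
    sig = make_tempo_signal(base.event_times, desired, trial_ms, dt=p.dt, params=p)
    rec = simulate_trial(w, arch, p, modulation=sig, duration_ms=trial_ms)
    deviations = rec.event_times - desired
    return rec, deviations


def run_thunderstruck_demo(params: Optional[ModelParams] = None, seed: int = 0,
                           max_trials: int = 1000):
    """Learn the sixteen-note riff, replay it, then re-time it bossa-style.

    Trains on the packaged riff fixture (16 isosynchronous eighth notes at
    140 bpm over a 3500 ms window, six distinct pitches), freezes the
    weights, reproduces the rock grid, and -- without any retraining --
    replays the same weights on the packaged bossa-style tempo grid through
    a time-varying multiplicative Go gain.

    Returns a dict with the training result, the rock and bossa trial
    records, and the desired bossa grid.
    """
    from .fixtures import fixture_sequence, fixture_tempo_grid

    params = params or ModelParams()
    spec = fixture_sequence("thunderstruck")
    result = train_sequence(spec, params, seed=seed, max_trials=max_trials)
    rock = simulate_trial(result.weights, result.arch, params,
                          duration_ms=spec.window_ms, seed=seed)
    bossa_grid = fixture_tempo_grid("bossa")
    bossa_window = float(np.ceil((bossa_grid[-1] + 200.0) / 100.0) * 100.0)
    sig = make_tempo_signal(rock.event_times, bossa_grid, bossa_window,
                            dt=params.dt, params=params)
    bossa = simulate_trial(result.weights, result.arch, params,
                           modulation=sig, duration_ms=bossa_window, seed=seed)
    return {"training": result, "rock": rock, "bossa": bossa,
            "bossa_grid": bossa_grid, "spec": spec}


def run_scalar_variability(intervals_ms: Sequence[float] = (200., 400., 600., 800.),
                           noise_sds: Sequence[float] = (0.01, 0.05),
                           n_rts: int = 100, n_sims: int = 20,
                           params: Optional[ModelParams] = None,
                           seed: int = 0, full_scale: bool = False):
    """Scalar variability: RT dispersion grows with the trained interval.

    A single-action model is trained (noise-free) per interval; for each
    noise level and simulation, ``n_rts`` noisy trials yield reaction times
    whose standard deviation is recorded (one SD per simulation). Trials in
    which the action never crosses threshold are excluded from the SD and
    counted as censored. ``full_scale=True`` uses 500 RTs x 100 simulations.

    Returns a DataFrame with columns interval_ms, noise_sd, sim, sd_ms,
    n_censored.
    """
    params = params or ModelParams()
    if full_scale:
        n_rts, n_sims = 500, 100
    rows = []
    for interval in intervals_ms:
        spec = SequenceSpec((float(interval),), window_ms=1000.0)
        trained = train_sequence(spec, params, seed=seed)
        for noise in noise_sds:
            noisy = params.replace(noise_sd=float(noise))
            for sim in range(n_sims):
                rts = []
                censored = 0
                for i in range(n_rts):
                    trial_seed = int(substream(
                        seed, f"scalar-{interval}-{noise}", sim * n_rts + i
                    ).generate_state(1)[0])
                    rec = simulate_trial(trained.weights, trained.arch, noisy,
                                         duration_ms=1000.0, seed=trial_seed,
                                         record_full=False)
                    if np.isnan(rec.event_times[0]):
                        censored += 1
                    else:
                        rts.append(rec.event_times[0])
                sd = float(np.std(rts, ddof=1)) if len(rts) > 1 else np.nan
                rows.append((interval, noise, sim, sd, censored))
    return pd.DataFrame(rows, columns=["interval_ms", "noise_sd", "sim",
                                       "sd_ms", "n_censored"])


# --------------------------------------------------------------------------
# robustness sweeps
# --------------------------------------------------------------------------

def _count_events(record: TrialRecord) -> int:
    return record.n_executed


def sweep_regime(ga_grid: Optional[np.ndarray] = None,
                 rec_grid: Optional[np.ndarray] = None,
                 params: Optional[ModelParams] = None,
                 n_actions: int = 6, seed: int = 0,
                 trial_ms: float = 1000.0) -> SweepResult:
    """Executed-action count in a hand-wired network vs (Go->Action, recurrent).

    Fixed selective connectivity: within-cluster recurrent weights at the
    ``rec`` grid value, selective RNN->Go wiring at the learning ceiling,
    uniform Go->Action couplings at the ``ga`` grid value. The Go->Action
    coupling controls how many actions fit in the window; the recurrent
    weight does not, provided the assemblies are self-sustaining.
    """
    params = params or ModelParams()
    # grids bracket the learned values (w_ga ~ 2..12, within-cluster w_rec ->
    # its ceiling); rec starts above the self-sustaining boundary
    # (cluster drive 20*w_rec must exceed the shared inhibition ~2)
    ga_grid = np.linspace(0.5, 16.0, 20) if ga_grid is None else np.asarray(ga_grid, float)
    rec_grid = np.linspace(0.2, 1.0, 20) if rec_grid is None else np.asarray(rec_grid, float)
    arch = build_architecture(n_exc=max(200, (n_actions + 1) * 20),
                              n_actions=n_actions, seed=seed)
    out = np.zeros((len(ga_grid), len(rec_grid)))
    for i, ga in enumerate(ga_grid):
        for j, rw in enumerate(rec_grid):
            w = ideal_weights(arch, params, rec_weight=float(rw), ga_weight=float(ga))
            rec = simulate_trial(w, arch, params, duration_ms=trial_ms,
                                 record_full=False)
            out[i, j] = _count_events(rec)
    return SweepResult(("w_ga", "w_rec"), (ga_grid, rec_grid), out,
                       "n_actions_executed", seed)


def sweep_sustainability(an_grid: Optional[np.ndarray] = None,
                         ga_grid: Optional[np.ndarray] = None,
                         params: Optional[ModelParams] = None,
                         n_actions: int = 6, seed: int = 0,
                         trial_ms: float = 1000.0) -> SweepResult:
    """Sustainability AUC in a hand-wired network vs (Action->NoGo, Go->Action).

    Lower Action->NoGo couplings weaken the shutdown of executed actions and
    lengthen their supra-threshold epochs. Cells whose sequence is incomplete
    score 0 by convention.
    """
    params = params or ModelParams()
    an_grid = np.linspace(0.05, 2.0, 20) if an_grid is None else np.asarray(an_grid, float)
    ga_grid = np.linspace(4.0, 20.0, 20) if ga_grid is None else np.asarray(ga_grid, float)
    arch = build_architecture(n_exc=max(200, (n_actions + 1) * 20),
                              n_actions=n_actions, seed=seed)
    out = np.zeros((len(an_grid), len(ga_grid)))
    for i, an in enumerate(an_grid):
        p = params.replace(j_na=float(an))
        for j, ga in enumerate(ga_grid):
            w = ideal_weights(arch, p, ga_weight=float(ga))
            rec = simulate_trial(w, arch, p, duration_ms=trial_ms,
                                 record_full=False)
            out[i, j] = (sustainability_auc(rec)
                         if _count_events(rec) == n_actions else 0.0)
    return SweepResult(("j_na", "w_ga"), (an_grid, ga_grid), out,
                       "sustainability", seed)


def sweep_gamma(trained: TrainingResult,
                ge_grid: Optional[np.ndarray] = None,
                gi_grid: Optional[np.ndarray] = None,
                trial_ms: float = 1000.0) -> SweepResult:
    """Executed-action count of the trained model over the feedback-gain plane.

    The learned sequence is reproduced only where the gain on excitatory
    feedback targets exceeds the gain on the shared inhibitory unit
    (gamma_e > gamma_i), the condition for the attractor switch.
    """
    ge_grid = np.linspace(19.0, 23.5, 10) if ge_grid is None else np.asarray(ge_grid, float)
    gi_grid = np.linspace(19.0, 23.5, 10) if gi_grid is None else np.asarray(gi_grid, float)
    out = np.zeros((len(ge_grid), len(gi_grid)))
    for i, ge in enumerate(ge_grid):
        for j, gi in enumerate(gi_grid):
            p = trained.params.replace(gamma_e=float(ge), gamma_i=float(gi))
            rec = simulate_trial(trained.weights, trained.arch, p,
                                 duration_ms=trial_ms, record_full=False)
            out[i, j] = _count_events(rec)
    return SweepResult(("gamma_e", "gamma_i"), (ge_grid, gi_grid), out,
                       "n_actions_executed", seed=0)


def sweep_overlap(overlaps: Optional[np.ndarray] = None,
                  spec: Optional[SequenceSpec] = None,
                  params: Optional[ModelParams] = None,
                  seed: int = 0, mode: str = "rerun",
                  max_trials: int = 1000) -> SweepResult:
    """Executed-action count as feedback projections overlap increasingly.

    ``mode="rerun"`` (default) trains once with orthogonal projections, then
    at each overlap fraction redirects part of every Action node's feedback
    target set onto the preceding projection's units and replays the learned
    sequence -- probing the robustness of the attractor-switch dynamics.
    ``mode="retrain"`` instead rebuilds the architecture with shared cluster
    members and retrains from scratch at each level (training failures keep
    the partially trained weights); with shared members the first formed
    cluster's outgoing weights ignite the next cluster at trial onset, so
    this stricter variant collapses at any overlap.
    """
    from .architecture import with_feedback_overlap
    from .fixtures import fixture_sequence

    params = params or ModelParams()
    spec = spec or fixture_sequence("sim1")
    overlaps = (np.arange(0, 11) * 0.05 if overlaps is None
                else np.asarray(overlaps, float))
    if mode not in ("retrain", "rerun"):
        raise ValueError("mode must be 'retrain' or 'rerun'")

    base = None
    if mode == "rerun":
        base = train_sequence(spec, params, seed=seed, max_trials=max_trials)

    counts = np.zeros(len(overlaps))
    for idx, frac in enumerate(overlaps):
        if mode == "retrain":
            arch = build_architecture(n_exc=max(200, (spec.n_actions + 1) * 20),
                                      n_actions=spec.n_actions,
                                      overlap_frac=float(frac), seed=seed)
            try:
                trained = train_sequence(spec, params, arch=arch, seed=seed,
                                         max_trials=max_trials)
                weights = trained.weights
            except TrainingError as err:
                weights = err.weights
        else:
            arch = with_feedback_overlap(base.arch, float(frac), seed=seed)
            weights = base.weights
        rec = simulate_trial(weights, arch, params,
                             duration_ms=spec.window_ms, record_full=False)
        counts[idx] = _count_events(rec)
    return SweepResult(("overlap_frac",), (overlaps,), counts,
                       "n_actions_executed", seed, metadata={"mode": mode})
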