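"""Model parameters for the ACDC circuit.

The associative cluster-dependent chain (ACDC) model couples a clustered
excitatory rate RNN (premotor cortex) to a basal-ganglia/thalamus module of
Go, NoGo and Action nodes. :class:`ModelParams` collects every scalar of the
published parameter set together with the integration settings (Euler step,
noise, context-pulse duration, execution threshold).

All time constants and durations are expressed in milliseconds; the Euler
step ``dt`` defaults to 1 ms so that a one-second trial is 1000 steps.
Timing errors fed to the delta rule are expressed in seconds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = ["ModelParams", "default_params"]


@dataclass(frozen=True)
class ModelParams:
    """Scalar parameters of the ACDC model.

    Defaults reproduce the published parameter set used for all nine
    simulations. Fields with no published value (``dt``, ``noise_sd``,
    ``input_pulse_ms``, ``rt_threshold``, ``noise_mode`` and the structural
    flags) are integration/measurement choices documented in
    ``docs/methods.md``.
    """

    # -- Hebbian rule, RNN recurrent site -----------------------------------
    alpha1_rnn: float = 0.01      #: depression rate for recurrent weights
    alpha2_rnn: float = 0.1       #: potentiation rate for recurrent weights
    wmax_rnn: float = 1.0         #: recurrent weight ceiling

    # -- Hebbian rule, RNN -> Go site ----------------------------------------
    alpha1_rnn_go: float = 0.00002
    alpha2_rnn_go: float = 0.4
    wmax_rnn_go: float = 0.05

    # -- Basal-ganglia / thalamus --------------------------------------------
    b: float = 0.5                #: Action-node negative bias (decision bound)
    eta: float = 0.4              #: delta-rule learning rate (weight / s of error)
    phi: float = 0.01             #: timing-error convergence criterion (s)

    # -- Fixed couplings ------------------------------------------------------
    j_ie: float = 0.1             #: excitatory RNN -> shared inhibitory unit
    j_ei: float = 1.0             #: shared inhibitory unit -> excitatory RNN
    j_ea: float = 1.0             #: Action -> excitatory RNN (feedback targets)
    j_ia: float = 1.0             #: Action -> shared inhibitory unit
    j_gn: float = 1.0             #: NoGo -> Go (inhibitory)
    j_na: float = 1.0             #: Action -> NoGo
    gamma_e: float = 21.4         #: gain on Action feedback to excitatory targets
    gamma_i: float = 21.0         #: gain on Action feedback to the inhibitory unit

    # -- Time constants (ms) --------------------------------------------------
    tau_rnn: float = 1.0
    tau_a: float = 10.0
    tau_n: float = 10.0
    tau_g: float = 1000.0         #: slow Go integration = evidence accumulation
    #: Presynaptic low-pass trace for the Hebbian rule. At tau_w = dt the
    #: trace equals the instantaneous rate (no effective filtering, which the
    #: model does not require); values of 2 ms and above let the trace of a
    #: dying assembly outlive the attractor switch and wire successive
    #: clusters together.
    tau_w: float = 1.0

    # -- Nonlinearity and input ----------------------------------------------
    x_in: float = 1.0             #: context input magnitude
    lambda_rnn: float = 10.0      #: sigmoid gain, RNN units
    lambda_a: float = 10000.0     #: sigmoid gain, Action units (near-binary)

    # -- Integration / measurement -------------------------------------------
    #: Euler step (ms). dt = 1 at tau_rnn = 1 sits on the Euler stability
    #: boundary, and the resulting one-step inhibitory lag is part of the
    #: model's operating regime: it lets the next cluster ignite during the
    #: Action rise, which is what makes inter-action gaps shorter than the
    #: Action node's ~65 ms inhibitory clearance time expressible at all.
    #: Finer steps (0.5, 0.25) remove that mode and with it the short gaps.
    #: See docs/methods.md.
    dt: float = 1.0
    noise_sd: float = 0.0         #: per-step Gaussian noise s.d. (0 = off)
    noise_mode: str = "net_input"  #: "net_input" (noise enters the derivative)
    #: or "step" (plain additive per step); see docs/methods.md.
    input_pulse_ms: float = 100.0  #: context square-pulse duration at trial onset
    rt_threshold: float = 0.5     #: Action level defining execution time
    #: Action level marking action *onset* for the plasticity association
    #: windows and context withdrawal -- well below rt_threshold because the
    #: attractor switch begins while the Action node is still rising.
    onset_threshold: float = 0.05
    #: Withdraw the context pulse once the first action has begun (prevents
    #: the input from re-igniting the first cluster when an early execution
    #: falls inside the pulse).
    context_until_onset: bool = True

    # -- Learning time scales --------------------------------------------------
    #: Dimensionless multipliers on the Euler step of each Hebbian site
    #: (1.0 integrates the rate constants per millisecond of simulated time).
    hebbian_rec_scale: float = 1.0
    hebbian_go_scale: float = 1.0
    #: Recurrent LTP requires external feedforward drive on the postsynaptic
    #: unit: a thalamic volley within this fraction of its plateau
    #: (j_ea * gamma_e), or the context input at half magnitude. Assemblies
    #: wire while being recruited; incidental co-activity at attractor
    #: switches or trial onset cannot weld successive clusters together.
    #: Set <= 0 to disable the gate. 0.85 places the eligibility onset at
    #: the previous assembly's extinction (a ~ 0.86 by the gamma geometry)
    #: while staying reachable by the briefest Action pulses, whose peaks
    #: approach ~0.95. See docs/methods.md.
    ltp_volley_fraction: float = 0.85

    # -- Structural flags ------------------------------------------------------
    zero_self_connections: bool = False  #: zero the recurrent diagonal each step
    go_gain_on_drive_only: bool = False  #: multiplicative Go gain spares NoGo term
    j_na_per_action: Optional[Tuple[float, ...]] = None  #: per-action J^NA override

    def __post_init__(self) -> None:
        for name in ("tau_rnn", "tau_a", "tau_n", "tau_g", "tau_w", "dt",
                     "phi", "eta"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("wmax_rnn", "wmax_rnn_go", "alpha1_rnn", "alpha2_rnn",
                     "alpha1_rnn_go", "alpha2_rnn_go", "gamma_e", "gamma_i",
                     "noise_sd", "j_na", "input_pulse_ms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if not 0.0 < self.rt_threshold < 1.0:
            raise ValueError(f"rt_threshold must lie in (0, 1), got {self.rt_threshold}")
        if not 0.0 < self.onset_threshold <= self.rt_threshold:
            raise ValueError("onset_threshold must lie in (0, rt_threshold]")
        if self.lambda_rnn <= 0 or self.lambda_a <= 0:
            raise ValueError("sigmoid gains lambda_rnn / lambda_a must be > 0")
        if self.noise_mode not in ("net_input", "step"):
            raise ValueError(f"noise_mode must be 'net_input' or 'step', got {self.noise_mode!r}")
        if self.hebbian_rec_scale < 0 or self.hebbian_go_scale < 0:
            raise ValueError("hebbian_rec_scale and hebbian_go_scale must be >= 0")
        if self.j_na_per_action is not None:
            if any(v < 0 for v in self.j_na_per_action):
                raise ValueError("j_na_per_action entries must be >= 0")

    # -- convenience -----------------------------------------------------------
    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def j_na_vector(self, n_actions: int):
        """Per-action Action->NoGo couplings as an array of length ``n_actions``."""
        import numpy as np

        if self.j_na_per_action is None:
            return np.full(n_actions, self.j_na, dtype=float)
        if len(self.j_na_per_action) != n_actions:
            raise ValueError(
                f"j_na_per_action has length {len(self.j_na_per_action)}, "
                f"expected {n_actions}")
        return np.asarray(self.j_na_per_action, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["j_na_per_action"] is not None:
            d["j_na_per_action"] = list(d["j_na_per_action"])
        return d


def default_params(**overrides) -> ModelParams:
    """The published parameter set, optionally with overrides."""
    return ModelParams(**overrides)
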