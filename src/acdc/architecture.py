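"""Network architecture: unit counts, cluster target sets, weight containers.

The excitatory RNN holds ``n_exc`` units. The context input excites one
subset of ``cluster_size`` units (the seed of the first cluster); each Action
node's excitatory feedback excites a further subset (the seed of the next
cluster in the chain). At ``overlap_frac = 0`` all these projection target
sets are pairwise disjoint (orthogonal projections); at ``overlap_frac = f``
each feedback set shares ``floor(f * cluster_size)`` units with the preceding
projection's set, which is how robustness to input overlap is probed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from ._rng import generator
from .params import ModelParams

__all__ = ["Architecture", "WeightSet", "build_architecture",
           "initialize_weights", "with_feedback_overlap"]


@dataclass(frozen=True)
class Architecture:
    """Unit counts and projection target sets of one ACDC network."""

    n_exc: int
    cluster_size: int
    n_actions: int
    overlap_frac: float
    input_targets: np.ndarray            #: (cluster_size,) indices of context targets
    feedback_targets: List[np.ndarray]   #: per Action node, (cluster_size,) indices

    @property
    def cluster_members(self) -> List[np.ndarray]:
        """Unit sets of the ordinal clusters: cluster i drives Go node i.

        Cluster 0 is seeded by the context input; cluster i (i >= 1) by the
        feedback projection of Action node i-1. There are ``n_actions``
        clusters; the last feedback projection has no Go node of its own.
        """
        return [self.input_targets] + list(self.feedback_targets[: self.n_actions - 1])

    def feedback_matrix(self, params: ModelParams) -> np.ndarray:
        """(n_exc, n_actions) map of Action feedback onto excitatory targets.

        Entry (i, j) is ``j_ea * gamma_e`` when unit i is a feedback target of
        Action node j, else 0, so the excitatory feedback drive is ``P @ a``.
        """
        p = np.zeros((self.n_exc, self.n_actions))
        for j, targets in enumerate(self.feedback_targets):
            p[targets, j] = params.j_ea * params.gamma_e
        return p

    def input_mask(self) -> np.ndarray:
        m = np.zeros(self.n_exc)
        m[self.input_targets] = 1.0
        return m


@dataclass
class WeightSet:
    """Plastic weight matrices of the model.

    ``w_rec``      recurrent weights among excitatory RNN units (n_exc, n_exc)
    ``w_rnn_go``   RNN excitatory units -> Go nodes (n_actions, n_exc)
    ``w_ga``       Go -> Action couplings, one per action (n_actions,)
    """

    w_rec: np.ndarray
    w_rnn_go: np.ndarray
    w_ga: np.ndarray

    def copy(self) -> "WeightSet":
        return WeightSet(self.w_rec.copy(), self.w_rnn_go.copy(), self.w_ga.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightSet):
            return NotImplemented
        return (np.array_equal(self.w_rec, other.w_rec)
                and np.array_equal(self.w_rnn_go, other.w_rnn_go)
                and np.array_equal(self.w_ga, other.w_ga))


def build_architecture(n_exc: int = 200,
                       cluster_size: int = 20,
                       n_actions: int = 6,
                       overlap_frac: float = 0.0,
                       seed: int = 0) -> Architecture:
    """Allocate projection target sets pseudo-randomly but reproducibly.

    With ``overlap_frac = f > 0`` each feedback target set shares
    ``floor(f * cluster_size)`` units with the target set of the preceding
    projection in the chain (input set for the first Action node).

    Raises
    ------
    ValueError
        If the disjoint-unit budget ``cluster_size + n_actions *
        (cluster_size - shared)`` exceeds ``n_exc``.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError(f"overlap_frac must lie in [0, 1), got {overlap_frac}")
    if n_actions < 1 or cluster_size < 1:
        raise ValueError("n_actions and cluster_size must be >= 1")
    shared = int(np.floor(overlap_frac * cluster_size))
    fresh_per_set = cluster_size - shared
    required = cluster_size + n_actions * fresh_per_set
    if required > n_exc:
        raise ValueError(
            f"architecture needs at least {required} excitatory units for "
            f"{n_actions} actions with cluster_size={cluster_size} and "
            f"overlap_frac={overlap_frac}; got n_exc={n_exc}")

    rng = generator(seed, "architecture")
    perm = rng.permutation(n_exc)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor:cursor + k]
        cursor += k
        return out

    input_targets = np.sort(take(cluster_size))
    feedback_targets: List[np.ndarray] = []
    prev = input_targets
    for _ in range(n_actions):
        carried = (rng.choice(prev, size=shared, replace=False)
                   if shared > 0 else np.empty(0, dtype=prev.dtype))
        targets = np.sort(np.concatenate([carried, take(fresh_per_set)]).astype(int))
        feedback_targets.append(targets)
        prev = targets

    return Architecture(n_exc=n_exc, cluster_size=cluster_size,
                        n_actions=n_actions, overlap_frac=overlap_frac,
                        input_targets=input_targets.astype(int),
                        feedback_targets=feedback_targets)


def with_feedback_overlap(arch: Architecture, overlap_frac: float,
                          seed: int = 0) -> Architecture:
    """Overlap the feedback projections of a trained architecture at test time.

    Each Action node's target set keeps ``(1-f)`` of its own units and
    replaces the rest with ``floor(f * cluster_size)`` units drawn from the
    *preceding* projection's target set (the context set for the first
    action), so the volley of action j partially re-excites the cluster it
    should extinguish. Cluster membership (and therefore the learned
    weights) is untouched -- this probes the robustness of the switch
    dynamics, not of learning.
    """
    if not 0.0 <= overlap_frac < 1.0:
        raise ValueError(f"overlap_frac must lie in [0, 1), got {overlap_frac}")
    rng = generator(seed, "feedback-overlap")
    shared = int(np.floor(overlap_frac * arch.cluster_size))
    prev = arch.input_targets
    new_targets: List[np.ndarray] = []
    for original in arch.feedback_targets:
        carried = (rng.choice(prev, size=shared, replace=False)
                   if shared > 0 else np.empty(0, dtype=int))
        kept = (rng.choice(original, size=arch.cluster_size - shared,
                           replace=False)
                if shared > 0 else original)
        new_targets.append(np.sort(np.concatenate([carried, kept]).astype(int)))
        prev = original
    return Architecture(n_exc=arch.n_exc, cluster_size=arch.cluster_size,
                        n_actions=arch.n_actions, overlap_frac=overlap_frac,
                        input_targets=arch.input_targets,
                        feedback_targets=new_targets)


def initialize_weights(arch: Architecture, params: ModelParams,
                       seed: int = 0) -> WeightSet:
    """Blank-slate recurrent matrix; Gaussian RNN->Go and Go->Action weights.

    ``w_rec`` starts at zero (clusters emerge through Hebbian learning),
    ``w_rnn_go`` ~ N(0.5/N, 0.1/N) clipped at zero, and ``w_ga`` ~ N(2, 0.2).
    """
    rng = generator(seed, "weights")
    n = arch.n_exc
    k = arch.n_actions
    w_rec = np.zeros((n, n))
    w_rnn_go = np.clip(rng.normal(0.5 / n, 0.1 / n, size=(k, n)), 0.0, None)
    w_ga = rng.normal(2.0, 0.2, size=k)
    return WeightSet(w_rec=w_rec, w_rnn_go=w_rnn_go, w_ga=w_ga)
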