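"""Hebbian rule algebra, delta rule, sequence training, learned structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acdc import (ModelParams, SequenceSpec, delta_update, hebbian_update,
                  selectivity_index, simulate_trial, train_sequence)
from acdc.architecture import build_architecture

from conftest import SEED


# ------------------------------------------------------------- Hebbian ----

def test_hebbian_silent_pair_unchanged():
    """Both terms vanish when presynaptic trace is zero."""
    p = ModelParams()
    w = np.full((3, 4), 0.02)
    out = hebbian_update(w, np.zeros(4), np.zeros(3), 0.01, 0.1, 1.0, p)
    np.testing.assert_array_equal(out, w)


def test_hebbian_coactivity_drives_to_ceiling():
    p = ModelParams()
    w = np.zeros((2, 2))
    for _ in range(5000):
        w = hebbian_update(w, np.ones(2), np.ones(2), 0.01, 0.1, 1.0, p)
    assert w == pytest.approx(np.ones((2, 2)), abs=1e-6)


def test_hebbian_depression_clamped_at_zero():
    p = ModelParams()
    w = np.zeros((1, 1))
    out = hebbian_update(w, np.ones(1), np.zeros(1), 0.01, 0.1, 1.0, p)
    assert out[0, 0] == 0.0


def test_hebbian_shape_mismatch_raises():
    p = ModelParams()
    with pytest.raises(ValueError):
        hebbian_update(np.zeros((2, 3)), np.zeros(2), np.zeros(2),
                       0.01, 0.1, 1.0, p)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_hebbian_bounds_invariant(seed):
    """Any update sequence keeps weights in [0, wmax] elementwise."""
    rng = np.random.default_rng(seed)
    p = ModelParams()
    wmax = float(rng.uniform(0.01, 2.0))
    w = rng.uniform(0, wmax, (4, 5))
    for _ in range(20):
        pre = rng.uniform(0, 1, 5)
        post = rng.uniform(0, 1, 4)
        w = hebbian_update(w, pre, post, 0.01, 0.4, wmax, p)
        assert np.all(w >= 0) and np.all(w <= wmax)


# --------------------------------------------------------------- delta ----

def test_delta_rule_signed_error():
    assert delta_update(2.0, 0.2, 0.2, 0.4) == 2.0
    assert delta_update(2.0, 0.3, 0.2, 0.4) == pytest.approx(2.04)
    assert delta_update(2.0, 0.1, 0.2, 0.4) < 2.0
    with pytest.raises(ValueError):
        delta_update(2.0, 0.3, 0.2, 0.0)


# ------------------------------------------------------- SequenceSpec -----

def test_sequence_spec_validation():
    with pytest.raises(ValueError):
        SequenceSpec((200.0, 150.0))
    with pytest.raises(ValueError):
        SequenceSpec((200.0, 1200.0), window_ms=1000.0)
    with pytest.raises(ValueError):
        SequenceSpec((200.0,), note_labels=("a", "b"))


def test_sequence_spec_file_round_trip(tmp_path):
    spec = SequenceSpec((200., 250., 400.), window_ms=1000.0,
                        note_labels=("B5", "A5", "G#5"))
    path = tmp_path / "spec.tsv"
    spec.to_file(path)
    assert SequenceSpec.from_file(path) == spec


# --------------------------------------------------------- selectivity ----

def test_selectivity_of_hand_built_matrices():
    arch = build_architecture(200, 20, 6, 0.0, seed=0)
    perfect = np.zeros((6, 200))
    for j, members in enumerate(arch.cluster_members):
        perfect[j, members] = 0.05
    np.testing.assert_allclose(selectivity_index(perfect, arch), 1.0)

    uniform = np.full((6, 200), 0.01)
    np.testing.assert_allclose(selectivity_index(uniform, arch), 0.1)

    dead = np.zeros((6, 200))
    assert np.all(np.isnan(selectivity_index(dead, arch)))


# ------------------------------------------------------------ training ----

def test_single_action_training_converges(params):
    """One action at 300 ms: timing error reaches the phi criterion and a
    frozen trial reproduces the target within 10 ms."""
    res = train_sequence(SequenceSpec((300.0,)), params, seed=SEED)
    assert len(res.trials_per_stage) == 1
    final = res.curve.final_errors()
    assert abs(final[0]) < params.phi
    rec = simulate_trial(res.weights, res.arch, params, duration_ms=1000.0)
    assert abs(rec.event_times[0] - 300.0) <= 10.0


def test_sequence_training_reaches_criterion(trained_sim1, params, sim1_spec):
    trained, record = trained_sim1
    assert len(trained.trials_per_stage) == sim1_spec.n_actions
    assert all(n <= 1000 for n in trained.trials_per_stage)
    # every action reproduced in order, within 10 ms of its target
    assert record.n_executed == 6
    assert list(record.event_order) == [0, 1, 2, 3, 4, 5]
    np.testing.assert_allclose(record.event_times,
                               sim1_spec.target_times_ms, atol=10.0)


def test_curriculum_errors_plateau_until_predecessor_converges(trained_sim1):
    """Action i+1's error stays flat until action i has reached criterion."""
    trained, _ = trained_sim1
    frame = trained.curve.frame
    for stage in range(5):
        during = frame[(frame.stage == stage) & (frame.action_index == stage + 1)]
        assert during.w_ga.nunique() == 1     # no delta updates yet
        assert during.error_s.std() < 0.05    # plateaued error level


def test_delta_fixed_point_after_convergence(trained_sim1, params):
    """On any trial whose timing error is within phi, the next Go->Action
    update is below eta * phi (the delta rule's fixed-point band)."""
    trained, _ = trained_sim1
    frame = trained.curve.frame
    last_stage = frame[frame.stage == 5]
    checked = 0
    for j in range(5):  # earlier, converged actions under maintenance updates
        rows = last_stage[last_stage.action_index == j]
        err = rows.error_s.to_numpy()
        w = rows.w_ga.to_numpy()
        small = np.abs(err[:-1]) < params.phi
        if small.any():
            assert np.all(np.abs(np.diff(w))[small]
                          <= params.eta * params.phi + 1e-12)
            checked += 1
    assert checked >= 3


def test_learned_recurrent_matrix_has_cluster_structure(trained_sim1, params):
    """Within-cluster weights near the ceiling, cross-cluster near zero."""
    trained, _ = trained_sim1
    w = trained.weights.w_rec
    clusters = trained.arch.cluster_members
    for members in clusters:
        block = w[np.ix_(members, members)]
        off_diag = block[~np.eye(len(members), dtype=bool)]
        assert off_diag.mean() > 0.9 * params.wmax_rnn
    for i, a in enumerate(clusters):
        for j, b in enumerate(clusters):
            if i != j:
                assert w[np.ix_(a, b)].mean() < 0.05


def test_learned_go_wiring_is_selective(trained_sim1):
    """Each Go node draws most of its input from its own cluster."""
    trained, _ = trained_sim1
    sel = selectivity_index(trained.weights.w_rnn_go, trained.arch)
    assert np.all(sel > 0.8)


def test_weight_bounds_after_training(trained_sim1, params):
    trained, _ = trained_sim1
    assert trained.weights.w_rec.min() >= 0
    assert trained.weights.w_rec.max() <= params.wmax_rnn + 1e-12
    assert trained.weights.w_rnn_go.min() >= 0
    assert trained.weights.w_rnn_go.max() <= params.wmax_rnn_go + 1e-12


def test_training_reproducible_under_seed(params):
    spec = SequenceSpec((250.0,))
    a = train_sequence(spec, params, seed=11)
    b = train_sequence(spec, params, seed=11)
    assert np.array_equal(a.weights.w_ga, b.weights.w_ga)
    assert np.array_equal(a.weights.w_rec, b.weights.w_rec)
    assert a.trials_per_stage == b.trials_per_stage
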