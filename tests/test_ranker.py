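"""Path embedding recursion, attention scorers, top-N aggregation."""

from __future__ import annotations

import numpy as np
import pytest

import pathdx as px
from pathdx import nn
from pathdx.nn import Tensor
from pathdx.ranker import (
    PathState,
    ScorerParams,
    aggregate_and_select,
    extend_path,
    init_path,
    relation_onehot,
    score_multiattn,
    score_multiattn_batch,
    score_triattn,
    score_triattn_batch,
)


def _params(kind="triattn", dim=4, onehot=3, seed=0):
    return ScorerParams.init(dim, onehot, kind, np.random.default_rng(seed))


def test_init_path_preserves_embedding_bit_exactly():
    h = np.array([0.1, -0.2, 0.3, 0.4])
    p = init_path("C1", h)
    assert np.array_equal(p.embedding.data, h)
    assert p.hops == (("C1", None),)
    q = init_path("C2", h + 1.0)
    assert q.terminal_cui == "C2" and p.terminal_cui == "C1"


def test_extend_path_is_deterministic_and_appends_hops():
    params = _params()
    p = init_path("A", np.ones(4))
    q1 = extend_path(p, 1, "B", np.full(4, 0.5), params)
    q2 = extend_path(p, 1, "B", np.full(4, 0.5), params)
    assert np.array_equal(q1.embedding.data, q2.embedding.data)
    assert q1.hops == (("A", None), ("B", 1))
    assert q1.n_hops == 1


def test_zero_ffn_gives_zero_embedding():
    params = _params()
    for layer in (params.path_ffn.fc1, params.path_ffn.fc2):
        layer.W.data[:] = 0.0
        layer.b.data[:] = 0.0
    p = init_path("A", np.random.default_rng(0).normal(size=4))
    q = extend_path(p, 0, "B", np.ones(4), params)
    assert np.array_equal(q.embedding.data, np.zeros(4))


def test_extend_path_hand_matrix_arithmetic_d2():
    # D=2, onehot=2: FFN input [p0, p1, r0, r1, h0, h1]
    params = ScorerParams.init(2, 2, "triattn", np.random.default_rng(1))
    W1 = np.arange(12.0).reshape(6, 2) * 0.1
    b1 = np.array([0.05, -0.05])
    W2 = np.array([[1.0, 0.5], [-0.5, 1.0]])
    b2 = np.zeros(2)
    params.path_ffn.fc1.W.data = W1
    params.path_ffn.fc1.b.data = b1
    params.path_ffn.fc2.W.data = W2
    params.path_ffn.fc2.b.data = b2
    p = init_path("A", np.array([1.0, 2.0]))
    q = extend_path(p, 1, "B", np.array([3.0, 4.0]), params)
    x = np.array([1.0, 2.0, 0.0, 1.0, 3.0, 4.0])
    expected = np.maximum(x @ W1 + b1, 0.0) @ W2 + b2
    assert np.allclose(q.embedding.data, expected, atol=1e-12)


def test_self_loop_terminates_and_blocks_extension():
    params = _params()
    p = init_path("A", np.ones(4))
    q = extend_path(p, params.onehot_size - 1, "A", np.ones(4), params)
    assert q.terminated
    with pytest.raises(ValueError, match="terminated"):
        extend_path(q, 0, "B", np.ones(4), params)


def test_relation_onehot_bounds():
    v = relation_onehot(2, 3)
    assert v.tolist() == [0.0, 0.0, 1.0]
    with pytest.raises(ValueError):
        relation_onehot(3, 3)


# ----------------------------------------------------------------------
# TriAttn
# ----------------------------------------------------------------------

def test_triattn_zero_tensor_gives_constant_head_output():
    params = _params("triattn")
    params.W_abc.data[:] = 0.0
    rng = np.random.default_rng(0)
    base = None
    for _ in range(3):
        p = init_path("A", rng.normal(size=4))
        s = score_triattn(rng.normal(size=4), rng.normal(size=4), p, params)
        base = s if base is None else base
        assert s == base  # alpha = 0 for any inputs


def test_triattn_single_entry_closed_form():
    dim = 2
    params = ScorerParams.init(dim, 2, "triattn", np.random.default_rng(2),
                               hidden=1)
    params.W_abc.data[:] = 0.0
    params.W_abc.data[0, 0, 0] = 1.0
    # make the head the identity on alpha: sigma = [1], phi = [1], no bias
    params.sigma.W.data = np.ones((1, 1))
    params.sigma.b.data[:] = 0.0
    params.phi.W.data = np.ones((1, 1))
    params.phi.b.data[:] = 0.0
    h_x = np.array([2.0, 5.0])
    h_v = np.array([3.0, 7.0])
    p = init_path("A", np.array([4.0, 9.0]))
    s = score_triattn(h_x, h_v, p, params)
    assert np.isclose(s, 2.0 * 3.0 * 4.0)  # (h_x)_1 (h_v)_1 (p)_1


def test_triattn_alpha_is_trilinear_in_h_x():
    params = ScorerParams.init(3, 2, "triattn", np.random.default_rng(3),
                               hidden=1)
    params.sigma.W.data = np.ones((1, 1))
    params.sigma.b.data[:] = 0.0
    params.phi.W.data = np.ones((1, 1))
    params.phi.b.data[:] = 0.0
    rng = np.random.default_rng(4)
    h_x, h_v, pe = rng.normal(size=3), rng.normal(size=3), np.abs(rng.normal(size=3))
    p = init_path("A", pe)
    # with an identity head the score IS alpha, so trilinearity is exact
    s1 = score_triattn(h_x, h_v, p, params)
    s3 = score_triattn(3.0 * h_x, h_v, p, params)
    if s1 > 0 and s3 > 0:  # ReLU passthrough region
        assert np.isclose(s3, 3.0 * s1, rtol=1e-9)
    # alpha computed independently by explicit triple loop
    W = params.W_abc.data
    alpha = sum(h_x[a] * h_v[b] * pe[c] * W[a, b, c]
                for a in range(3) for b in range(3) for c in range(3))
    if alpha > 0:
        assert np.isclose(s1, alpha, rtol=1e-9)


def test_triattn_batch_matches_single_path_calls():
    params = _params("triattn", dim=4)
    rng = np.random.default_rng(5)
    h_x, h_v = rng.normal(size=4), rng.normal(size=4)
    embs = rng.normal(size=(6, 4))
    batch = score_triattn_batch(h_x, h_v, Tensor(embs), params).data[:, 0]
    singles = [score_triattn(h_x, h_v, init_path("A", e), params)
               for e in embs]
    assert np.allclose(batch, singles, atol=1e-12)


# ----------------------------------------------------------------------
# MultiAttn
# ----------------------------------------------------------------------

def test_multiattn_difference_blocks_zero_when_p_equals_context():
    params = _params("multiattn", dim=4)
    v = np.random.default_rng(6).normal(size=4)
    p = init_path("A", v)
    s = score_multiattn(v, v, p, params)
    assert np.isfinite(s)
    # H and Z blocks: h - p = 0 when p == h_x == h_v
    from pathdx.ranker import _context_blocks
    H = _context_blocks(Tensor(v), Tensor(v.reshape(1, 4)))
    assert np.allclose(H.data[0, 2], 0.0)


def test_multiattn_zero_phi_scores_zero_everywhere():
    params = _params("multiattn", dim=4)
    params.phi.W.data[:] = 0.0
    params.phi.b.data[:] = 0.0
    rng = np.random.default_rng(7)
    for _ in range(3):
        p = init_path("A", rng.normal(size=4))
        assert score_multiattn(rng.normal(size=4), rng.normal(size=4),
                               p, params) == 0.0


def test_multiattn_batch_matches_single_path_calls():
    params = _params("multiattn", dim=4)
    rng = np.random.default_rng(8)
    h_x, h_v = rng.normal(size=4), rng.normal(size=4)
    embs = rng.normal(size=(5, 4))
    batch = score_multiattn_batch(h_x, h_v, Tensor(embs), params).data[:, 0]
    singles = [score_multiattn(h_x, h_v, init_path("A", e), params)
               for e in embs]
    assert np.allclose(batch, singles, atol=1e-10)


def test_scorers_are_pure_functions():
    for kind in ("triattn", "multiattn"):
        params = _params(kind, dim=4)
        rng = np.random.default_rng(9)
        h_x, h_v = rng.normal(size=4), rng.normal(size=4)
        p = init_path("A", rng.normal(size=4))
        f = score_triattn if kind == "triattn" else score_multiattn
        assert f(h_x, h_v, p, params) == f(h_x, h_v, p, params)


def test_dimension_mismatch_raises():
    params = _params("triattn", dim=4)
    p = init_path("A", np.ones(4))
    with pytest.raises(ValueError):
        score_triattn(np.ones(3), np.ones(4), p, params)


# ----------------------------------------------------------------------
# aggregation / selection
# ----------------------------------------------------------------------

def _path(cui, score):
    return PathState(hops=((cui, None),), embedding=Tensor(np.zeros(2)),
                     score=score)


def test_single_path_always_selected():
    sel, best = aggregate_and_select([_path("C9", 0.3)], n=5)
    assert sel == ["C9"] and best["C9"].score == 0.3


def test_tie_breaks_lexicographically():
    sel, _ = aggregate_and_select([_path("B", 1.0), _path("A", 1.0)], n=1)
    assert sel == ["A"]


def test_top_n_matches_brute_force_sort():
    rng = np.random.default_rng(10)
    paths, scores = [], []
    for i in range(50):
        cui = f"C{rng.integers(0, 12):02d}"
        s = float(rng.normal())
        paths.append(_path(cui, s))
        scores.append(s)
    sel, best = aggregate_and_select(paths, n=4)
    beta = {}
    for p, s in zip(paths, scores):
        beta[p.terminal_cui] = beta.get(p.terminal_cui, 0.0) + s
    expected = sorted(beta, key=lambda c: (-beta[c], c))[:4]
    assert sel == expected
    for cui in sel:
        cand = max((s for p, s in zip(paths, scores)
                    if p.terminal_cui == cui))
        assert best[cui].score == cand


def test_selection_is_nested_under_sum_aggregation():
    rng = np.random.default_rng(11)
    paths = [_path(f"C{rng.integers(0, 8)}", float(rng.normal()))
             for _ in range(30)]
    for n in range(1, 6):
        a, _ = aggregate_and_select(paths, n=n)
        b, _ = aggregate_and_select(paths, n=n + 1)
        assert set(a) <= set(b)


def test_empty_path_list_gives_empty_selection():
    sel, best = aggregate_and_select([], n=3)
    assert sel == [] and best == {}


def test_max_and_mean_aggregation_modes():
    paths = [_path("A", 1.0), _path("A", 3.0), _path("B", 2.5)]
    sel_max, _ = aggregate_and_select(paths, n=1, aggregate="max")
    assert sel_max == ["A"]
    sel_mean, _ = aggregate_and_select(paths, n=1, aggregate="mean")
    assert sel_mean == ["B"]  # mean(A)=2.0 < 2.5
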