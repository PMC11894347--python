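"""Loss closed forms, contrastive mining, training-loop contracts."""

from __future__ import annotations

import math

import numpy as np
import pytest

import pathdx as px
from pathdx import nn
from pathdx.nn import Tensor
from pathdx.training import (
    ContrastiveBatch,
    TrainConfig,
    contrastive_loss,
    evaluate_recall,
    mine_path_features,
    prediction_loss,
    split_dataset,
    train,
)
from pathdx.ranker import PathState


def _prob(v):
    return Tensor(np.array(v))


def test_bce_closed_form_two_candidates():
    probs = {"G": _prob(0.9), "N": _prob(0.1)}
    loss = prediction_loss(probs, [{"G"}])
    assert math.isclose(float(loss.data), -(math.log(0.9) + math.log(0.9)) / 2,
                        abs_tol=1e-12)
    swapped = prediction_loss(probs, [{"N"}])
    assert math.isclose(float(swapped.data),
                        -(math.log(0.1) + math.log(0.1)) / 2, abs_tol=1e-12)


def test_bce_near_perfect_probabilities_give_near_zero_loss():
    probs = {"G": _prob(1.0 - 1e-6), "N": _prob(1e-6)}
    assert float(prediction_loss(probs, [{"G"}]).data) < 1e-5


def test_bce_probability_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        prediction_loss({"G": _prob(1.0)}, [{"G"}])
    with pytest.raises(ValueError):
        prediction_loss({"G": _prob(-0.1)}, [{"G"}])


def test_bce_per_set_averaging_over_m_sets():
    probs = {"A": _prob(0.9), "B": _prob(0.8)}
    per_set = prediction_loss(probs, [{"A"}, {"B"}], mode="per_set")
    l1 = -(math.log(0.9) + math.log(1 - 0.8)) / 2
    l2 = -(math.log(1 - 0.9) + math.log(0.8)) / 2
    assert math.isclose(float(per_set.data), (l1 + l2) / 2, abs_tol=1e-12)
    union = prediction_loss(probs, [{"A"}, {"B"}], mode="union")
    assert math.isclose(float(union.data),
                        -(math.log(0.9) + math.log(0.8)) / 2, abs_tol=1e-12)


def test_contrastive_hinge_inactive_when_separated():
    a = Tensor(np.array([1.0, 0.0]))
    batch = ContrastiveBatch(anchor=a,
                             positives=[Tensor(np.array([2.0, 0.0]))],
                             negatives=[Tensor(np.array([-3.0, 0.0]))])
    # cos+ = 1, cos- = -1, margin 0.5 -> hinge inactive
    assert float(contrastive_loss(batch, 0.5).data) == 0.0


def test_contrastive_equal_features_give_margin():
    a = Tensor(np.array([1.0, 1.0]))
    f = Tensor(np.array([0.3, 0.8]))
    batch = ContrastiveBatch(anchor=a, positives=[f], negatives=[f])
    assert math.isclose(float(contrastive_loss(batch, 0.7).data), 0.7,
                        abs_tol=1e-12)
    assert float(contrastive_loss(batch, 0.0).data) == 0.0


def test_contrastive_matches_naive_loop_on_random_batch():
    rng = np.random.default_rng(0)
    a = rng.normal(size=6)
    pos = [rng.normal(size=6) for _ in range(4)]
    neg = [rng.normal(size=6) for _ in range(5)]
    margin = 0.4
    batch = ContrastiveBatch(anchor=Tensor(a),
                             positives=[Tensor(p) for p in pos],
                             negatives=[Tensor(n) for n in neg])
    got = float(contrastive_loss(batch, margin).data)

    def cos(u, v):
        return float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))

    acc = [max(0.0, margin - cos(a, p) + cos(a, n)) for p in pos for n in neg]
    assert math.isclose(got, float(np.mean(acc)), abs_tol=1e-12)


def test_contrastive_empty_side_contributes_zero():
    a = Tensor(np.ones(3))
    assert float(contrastive_loss(
        ContrastiveBatch(anchor=a, positives=[], negatives=[a]), 0.5
    ).data) == 0.0


def _paths_with_terminals(terminals):
    P = Tensor(np.arange(len(terminals) * 3, dtype=float).reshape(-1, 3) + 1.0)
    paths = [PathState(hops=((t, None),), embedding=P) for t in terminals]
    return paths, P


def test_mine_path_features_partitions_by_gold_membership():
    paths, P = _paths_with_terminals(["G1", "X", "G2", "Y", "Z"])
    rng = np.random.default_rng(1)
    batch = mine_path_features(paths, P, [{"G1"}, {"G2"}], Tensor(np.ones(3)),
                               k_negatives=10, rng=rng)
    assert len(batch.positives) == 2
    assert len(batch.negatives) == 3
    assert np.array_equal(batch.positives[0].data, P.data[0])


def test_mine_path_features_sampling_is_seeded():
    paths, P = _paths_with_terminals(["G", "a", "b", "c", "d", "e"])
    picks = []
    for _ in range(2):
        rng = np.random.default_rng(42)
        batch = mine_path_features(paths, P, [{"G"}], Tensor(np.ones(3)),
                                   k_negatives=2, rng=rng)
        picks.append([tuple(n.data) for n in batch.negatives])
    assert picks[0] == picks[1]
    assert len(picks[0]) == 2


def test_all_gold_paths_mean_no_negatives_and_zero_contrastive():
    paths, P = _paths_with_terminals(["G", "G"])
    rng = np.random.default_rng(2)
    batch = mine_path_features(paths, P, [{"G"}], Tensor(np.ones(3)), 4, rng)
    assert batch.negatives == []
    assert float(contrastive_loss(batch, 0.5).data) == 0.0


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

def test_zero_learning_rate_leaves_parameters_unchanged(synth_world, model):
    _, graph, records = synth_world
    before = [p.data.copy() for p in model.parameters()]
    cfg = TrainConfig(epochs=1, lr=0.0, seed=0)
    train(model, records[:8], graph, cfg)
    after = model.parameters()
    for b, a in zip(before, after):
        assert np.array_equal(b, a.data)


def test_same_seed_gives_identical_loss_curves(synth_world):
    _, graph, records = synth_world
    curves = []
    for _ in range(2):
        m = px.ModelParams.init(dim=16,
                                onehot_size=graph.relations.onehot_size,
                                kind="triattn", seed=5)
        _, logs = train(m, records[:16], graph,
                        TrainConfig(epochs=2, seed=9))
        curves.append([(l.total, l.prediction, l.contrastive, l.val_recall)
                       for l in logs])
    assert curves[0] == curves[1]


def test_loss_breakdown_total_is_sum_of_parts(synth_world, model):
    _, graph, records = synth_world
    from pathdx.training import case_loss

    rng = np.random.default_rng(0)
    cfg = TrainConfig()
    for rec in records[:5]:
        out = case_loss(rec, graph, model, cfg, rng)
        assert out is not None
        _, bd = out
        assert math.isclose(bd.total, bd.prediction + bd.contrastive,
                            rel_tol=1e-12)
        assert bd.prediction >= 0.0 and bd.contrastive >= 0.0


def test_short_training_reduces_loss(synth_world):
    _, graph, records = synth_world
    m = px.ModelParams.init(dim=16, onehot_size=graph.relations.onehot_size,
                            kind="triattn", seed=1)
    _, logs = train(m, records, graph, TrainConfig(epochs=5, seed=1))
    assert logs[-1].total < logs[0].total


def test_split_dataset_is_seeded_partition(synth_world):
    _, _, records = synth_world
    tr1, va1 = split_dataset(records, 0.2, 3)
    tr2, va2 = split_dataset(records, 0.2, 3)
    assert [r.note_id for r in tr1] == [r.note_id for r in tr2]
    assert len(va1) == round(0.2 * len(records))
    ids = {r.note_id for r in tr1} | {r.note_id for r in va1}
    assert ids == {r.note_id for r in records}


def test_evaluate_recall_reports_corpus_means(synth_world, model):
    _, graph, records = synth_world
    out = evaluate_recall(records[:10], graph, model, top_n=4)
    assert 0.0 <= out["recall"] <= 1.0
    assert 0.0 <= out["precision"] <= 1.0
    assert out["n"] == 10
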