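"""Hop-by-hop exploration, oracle equivalence, serialization, prompts."""

from __future__ import annotations

import numpy as np
import pytest

import pathdx as px
from pathdx.inference import (
    HopConfig,
    PredictionResult,
    assemble_prompt,
    explore,
    infer,
    parse_structural,
    serialize_clause,
    serialize_structural,
)
from pathdx.nn import Tensor
from pathdx.ranker import PathState

from oracles import rank_paths_exhaustively


def _record(graph, encoder, sources, note_id="n0"):
    rec = px.CaseRecord(note_id=note_id, text="some note text",
                        source_cuis=list(sources))
    px.encode_case(rec, encoder, graph)
    return rec


def test_infer_is_deterministic(synth_world, model, encoder):
    _, graph, records = synth_world
    r1 = infer(records[0], graph, model, HopConfig())
    r2 = infer(records[0], graph, model, HopConfig())
    assert r1.selected_cuis == r2.selected_cuis
    assert r1.serialized_paths == r2.serialized_paths


def test_selected_count_never_exceeds_n(synth_world, model):
    _, graph, records = synth_world
    for rec in records[:8]:
        res = infer(rec, graph, model, HopConfig(top_n=3))
        assert len(res.selected_cuis) <= 3
        for cui, path in res.best_paths.items():
            assert path.terminal_cui == cui


def test_unknown_sources_flagged_no_paths(synth_world, model, encoder):
    _, graph, _ = synth_world
    rec = px.CaseRecord(note_id="x", text="t", source_cuis=["NOPE"])
    rec.text_embedding = encoder.encode("t")
    rec.cui_list_embedding = encoder.encode("t")
    res = infer(rec, graph, model, HopConfig())
    assert res.no_paths and res.selected_cuis == []


def test_max_hops_one_equals_single_pass_ranking(synth_world, model):
    _, graph, records = synth_world
    rec = records[0]
    traces = explore(rec, graph, model, HopConfig(max_hops=1, top_n=len(graph)))
    assert len(traces) == 1
    oracle = rank_paths_exhaustively(graph, rec, model, max_hops=1,
                                     top_n=len(graph))
    assert traces[0].selected == oracle


def test_sole_two_hop_descendant_is_always_selected(encoder):
    g = px.build_graph(
        [("S", "src"), ("M", "mid"), ("X", "target syndromic")],
        [("S", "r", "M"), ("M", "r", "X")],
        [("X", "T047")], ["r"])
    px.embed_concepts(g, encoder)
    for seed in (0, 1, 2):
        m = px.ModelParams.init(dim=16, onehot_size=g.relations.onehot_size,
                                kind="triattn", seed=seed)
        rec = _record(g, encoder, ["S"])
        res = infer(rec, g, m, HopConfig(max_hops=2, top_n=1))
        assert res.selected_cuis == ["X"]  # only 2-hop candidate exists


@pytest.mark.parametrize("kind", ["triattn", "multiattn"])
def test_hop_by_hop_with_full_beam_matches_exhaustive_oracle(encoder, kind):
    mismatches = 0
    for seed in range(25):
        cfg = px.SynthConfig(n_concepts=25, edge_density=0.08,
                             n_cases=2, sources_per_case=2,
                             gold_per_case=1, seed=seed)
        graph = px.generate_kg(cfg).build()
        px.embed_concepts(graph, encoder)
        try:
            records = px.generate_cases(graph, cfg)
        except RuntimeError:
            continue  # too sparse to plant; graph still usable elsewhere
        for rec in records:
            px.encode_case(rec, encoder, graph)
        model = px.ModelParams.init(dim=16,
                                    onehot_size=graph.relations.onehot_size,
                                    kind=kind, seed=seed)
        rec = records[0]
        traces = explore(rec, graph, model,
                         HopConfig(max_hops=2, top_n=len(graph)))
        got = traces[-1].selected[:4]
        expected = rank_paths_exhaustively(graph, rec, model, 2, 4)
        if got != expected:
            mismatches += 1
    assert mismatches == 0


def test_self_looped_terminal_survives_extra_hops(encoder):
    # L has no outgoing edge: it self-loops at hop 1 and must remain a
    # candidate at hop 2 regardless of beam pressure
    g = px.build_graph(
        [("S", "src"), ("L", "leaf"), ("A", "mid"), ("B", "deep")],
        [("S", "r", "L"), ("S", "r", "A"), ("A", "r", "B")],
        [], ["r"])
    px.embed_concepts(g, encoder)
    m = px.ModelParams.init(dim=16, onehot_size=g.relations.onehot_size,
                            kind="triattn", seed=0)
    rec = _record(g, encoder, ["S"])
    traces = explore(rec, g, m, HopConfig(max_hops=2, top_n=1))
    assert "L" in traces[-1].beta


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def _mkpath(hops):
    return PathState(hops=tuple(hops), embedding=Tensor(np.zeros(2)))


def test_structural_serialization_and_round_trip(tiny_graph):
    p = _mkpath([("A", None), ("B", 0), ("C", 1)])
    s = serialize_structural(p, tiny_graph)
    fields = parse_structural(s)
    assert len(fields) == 5
    assert fields[0] == "fever"
    assert fields[1] == "causative_agent_of"
    assert fields[4] == "sepsis syndrome"
    assert " → ".join(fields) == s


def test_structural_single_node_is_just_the_name(tiny_graph):
    assert serialize_structural(_mkpath([("A", None)]), tiny_graph) == "fever"


def test_structural_self_loop_renders_self(tiny_graph):
    sl = tiny_graph.relations.self_loop_id
    s = serialize_structural(_mkpath([("C", None), ("C", sl)]), tiny_graph)
    assert s == "sepsis syndrome → self → sepsis syndrome"


def test_clause_serialization_formats(tiny_graph):
    one = serialize_clause(_mkpath([("A", None), ("C", 2)]), tiny_graph)
    assert one == "fever associated_with sepsis syndrome"
    two = serialize_clause(_mkpath([("A", None), ("B", 0), ("C", 1)]),
                           tiny_graph)
    assert two == "fever causative_agent_of infection, which due_to " \
                  "sepsis syndrome"


# ----------------------------------------------------------------------
# prompts
# ----------------------------------------------------------------------

def test_prompt_with_paths_joins_with_semicolons(tiny_graph):
    rec = px.CaseRecord(note_id="n", text="NOTE BODY", source_cuis=["A"])
    res = PredictionResult(note_id="n", selected_cuis=["B", "C"],
                           serialized_paths={"B": "p1", "C": "p2"})
    prompt = assemble_prompt(rec, res)
    assert "NOTE BODY" in prompt
    assert "These are knowledge paths: p1; p2." in prompt
    assert prompt == assemble_prompt(rec, res)  # byte-identical


def test_empty_result_uses_pathless_template_verbatim(tiny_graph):
    rec = px.CaseRecord(note_id="n", text="NOTE BODY", source_cuis=["A"])
    prompt = assemble_prompt(rec, PredictionResult(note_id="n", no_paths=True))
    assert "knowledge paths" not in prompt
    assert prompt == ("Imagine you are a medical professional, and generate "
                      "the top three direct and indirect diagnoses from the "
                      "input note. NOTE BODY...")


def test_unknown_template_lists_available_ids():
    rec = px.CaseRecord(note_id="n", text="t", source_cuis=["A"])
    res = PredictionResult(note_id="n", selected_cuis=["B"],
                           serialized_paths={"B": "p"})
    with pytest.raises(KeyError, match="pathless"):
        assemble_prompt(rec, res, template_id="nope")
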