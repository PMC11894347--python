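"""Shared fixtures: hand-built tiny graphs and a small synthetic world."""

from __future__ import annotations

import numpy as np
import pytest

import pathdx as px


@pytest.fixture()
def tiny_graph() -> px.KnowledgeGraph:
    """A -> B -> C chain plus A -> C shortcut; D isolated; C is a disease."""
    concepts = [
        ("A", "fever"), ("B", "infection"), ("C", "sepsis syndrome"),
        ("C", "septicemia"), ("D", "recent"),
    ]
    relations = [
        ("A", "causative_agent_of", "B"),
        ("B", "due_to", "C"),
        ("A", "associated_with", "C"),
    ]
    types = [("A", "T184"), ("B", "T184"), ("C", "T047"), ("D", "T079")]
    whitelist = ["causative_agent_of", "due_to", "associated_with"]
    return px.build_graph(concepts, relations, types, whitelist)


@pytest.fixture(scope="session")
def encoder() -> px.ToyEncoder:
    return px.toy_encoder(vocab_size=300, dimension=16, seed=0)


@pytest.fixture(scope="session")
def synth_world(encoder):
    """Small generated KG + encoded corpus shared across tests (read-only)."""
    cfg = px.SynthConfig(n_concepts=30, n_cases=30, seed=11)
    graph = px.generate_kg(cfg).build()
    px.embed_concepts(graph, encoder)
    records = px.generate_cases(graph, cfg)
    for rec in records:
        px.encode_case(rec, encoder, graph)
    return cfg, graph, records


@pytest.fixture()
def model(synth_world) -> px.ModelParams:
    _, graph, _ = synth_world
    return px.ModelParams.init(dim=16, onehot_size=graph.relations.onehot_size,
                               kind="triattn", seed=3)
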