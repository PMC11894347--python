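"""Independent brute-force oracles used by several test modules.

The path-enumeration oracle rebuilds every complete path of at most J
hops one at a time through the single-path API (no batching, no beam)
and ranks terminals by exhaustive aggregation; it shares only the frozen
parameters with the hop-by-hop pipeline it checks.
"""

from __future__ import annotations

import numpy as np

import pathdx as px
from pathdx.nn import Tensor
from pathdx.ranker import score_multiattn, score_triattn
from pathdx.sgin import encode_subgraph


def _node_states(graph, cuis, model):
    sub = px.one_hop_subgraph(graph, cuis)
    base = {c: graph.node(c).base_embedding for c in sub.member_cuis}
    order, states = encode_subgraph(base, sub, model.sgin,
                                    model.include_in_neighbors)
    return {c: states.data[i] for c, i in order.items()}


def enumerate_all_paths(graph, sources, model, max_hops):
    """Every complete <=J-hop path (self-loop when a terminal is stuck),
    built recursively with the single-path API."""
    score_one = (score_triattn if model.kind == "triattn" else score_multiattn)
    states = _node_states(graph, sorted(sources), model)
    level = [px.init_path(s, Tensor(states[s])) for s in sorted(sources)]
    complete = []
    for hop in range(1, max_hops + 1):
        frontier = sorted({p.terminal_cui for p in level})
        if not frontier:
            break
        states = _node_states(graph, frontier, model)
        nxt = []
        for p in level:
            triples = [t for t in graph.out_triples(p.terminal_cui)
                       if t[2] not in p.visited]
            if not triples:
                triples = [(p.terminal_cui, graph.relations.self_loop_id,
                            p.terminal_cui)]
            for _, rel, tgt in triples:
                q = px.extend_path(p, rel, tgt, Tensor(states[tgt]),
                                   model.scorer)
                if q.terminated or hop == max_hops:
                    complete.append(q)
                else:
                    nxt.append(q)
        level = nxt
    return complete


def rank_paths_exhaustively(graph, record, model, max_hops, top_n,
                            aggregate="sum"):
    """Top-N terminals over ALL <=J-hop paths, scored one path at a time."""
    score_one = (score_triattn if model.kind == "triattn" else score_multiattn)
    sources = sorted({c for c in record.source_cuis if c in graph})
    paths = enumerate_all_paths(graph, sources, model, max_hops)
    beta: dict[str, list[float]] = {}
    for p in paths:
        s = score_one(record.text_embedding, record.cui_list_embedding,
                      p, model.scorer)
        beta.setdefault(p.terminal_cui, []).append(s)
    agg = {
        "sum": lambda v: float(np.sum(v)),
        "max": lambda v: float(np.max(v)),
        "mean": lambda v: float(np.mean(v)),
    }[aggregate]
    b = {c: agg(v) for c, v in beta.items()}
    return sorted(b, key=lambda c: (-b[c], c))[:top_n]


def depth_limited_reachable(graph, sources, max_hops):
    """Brute-force forward reachability by repeated full edge scans."""
    edges = graph.edge_triples()
    reach = {c for c in sources if c in graph}
    for _ in range(max_hops):
        new = {w for (u, _, w) in edges if u in reach}
        reach |= new
    return reach
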