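"""Multi-hop path exploration, top-N diagnosis selection and prompting.

The hop loop mirrors the training-time procedure: expand the frontier's
whitelisted out-edges (a node with no usable expansion takes a single
self-loop hop and is thereafter frozen), extend the path embeddings,
score every candidate path against the patient context, aggregate per
terminal node and keep the top-N terminals as the next frontier.
Terminated (self-loop) paths persist unchanged in the candidate pool of
every later hop — they are never dropped by the beam and never
re-extended.  A path never revisits a node it already contains.

Selected concepts are serialized either structurally
(``fever → causative agent of → infection``) or as clauses, and slotted
into the persona prompt template for a downstream language model; when
no path can be found the pathless persona template is used verbatim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np

from . import nn
from .encoding import CaseRecord, EncoderContract, encode_case
from .kg import KnowledgeGraph, SELF_LOOP_LABEL, one_hop_subgraph
from .model import ModelParams
from .nn import Tensor
from .ranker import (
    Aggregate,
    PathState,
    aggregate_scores,
    extend_paths_batch,
    score_paths_batch,
)
from .sgin import encode_subgraph

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HopConfig:
    """Exploration settings: beam width N, hop budget J, aggregation."""

    max_hops: int = 2
    top_n: int = 4
    aggregate: Aggregate = "sum"

    def __post_init__(self) -> None:
        if self.max_hops < 1 or self.top_n < 1:
            raise ValueError("max_hops and top_n must be >= 1")


@dataclass
class HopTrace:
    """Everything one hop produced (tensors kept for training losses)."""

    paths: list[PathState]
    P: Tensor                       # (n_paths, D) embeddings
    scores: Tensor                  # (n_paths, 1)
    beta: dict[str, float]
    selected: list[str]


@dataclass
class PredictionResult:
    note_id: str
    selected_cuis: list[str] = field(default_factory=list)
    best_paths: dict[str, PathState] = field(default_factory=dict)
    serialized_paths: dict[str, str] = field(default_factory=dict)
    no_paths: bool = False


# ----------------------------------------------------------------------
# hop-by-hop exploration
# ----------------------------------------------------------------------

def _base_states(graph: KnowledgeGraph, cuis: Sequence[str]) -> dict[str, np.ndarray]:
    out = {}
    for c in cuis:
        emb = graph.node(c).base_embedding
        if emb is None:
            raise ValueError(f"CUI {c} has no base embedding; run embed_concepts")
        out[c] = emb
    return out


def explore(record: CaseRecord, graph: KnowledgeGraph, model: ModelParams,
            config: HopConfig) -> list[HopTrace]:
    """Run the hop loop; returns one :class:`HopTrace` per hop (empty when
    no source CUI is present in the graph)."""
    sources = sorted({c for c in record.source_cuis if c in graph})
    missing = set(record.source_cuis) - set(sources)
    if missing:
        logger.warning("record %s: dropping unknown source CUIs %s",
                       record.note_id, sorted(missing))
    if not sources:
        return []
    if record.text_embedding is None or record.cui_list_embedding is None:
        raise ValueError(f"record {record.note_id} is not encoded")
    h_x = Tensor(record.text_embedding)
    h_v = Tensor(record.cui_list_embedding)

    traces: list[HopTrace] = []
    active: list[PathState] = []        # extendable paths, rows into P_prev
    frozen: list[PathState] = []        # self-loop terminated, embeddings fixed
    active_rows: list[int] = []
    frozen_embs: list[Tensor] = []
    P_prev: Tensor | None = None

    for hop in range(1, config.max_hops + 1):
        if hop == 1:
            sub = one_hop_subgraph(graph, sources)
            order, node_states = encode_subgraph(
                _base_states(graph, sub.member_cuis), sub, model.sgin,
                model.include_in_neighbors)
            P_prev = node_states
            active = [PathState(hops=((s, None),), embedding=node_states)
                      for s in sources]
            active_rows = [order[s] for s in sources]
        else:
            frontier = sorted({p.terminal_cui for p in active})
            if not frontier:
                break
            sub = one_hop_subgraph(graph, frontier)
            order, node_states = encode_subgraph(
                _base_states(graph, sub.member_cuis), sub, model.sgin,
                model.include_in_neighbors)

        # enumerate expansions of every active path
        expansions: list[tuple[int, int, int]] = []   # (path_row, rel, node_row)
        new_paths: list[PathState] = []
        new_terminated: list[bool] = []
        self_id = graph.relations.self_loop_id
        for p, row in zip(active, active_rows):
            triples = [t for t in graph.out_triples(p.terminal_cui)
                       if t[2] not in p.visited]
            if not triples:
                triples = [(p.terminal_cui, self_id, p.terminal_cui)]
            for _, rel, tgt in triples:
                expansions.append((row, rel, order[tgt]))
                new_paths.append(PathState(
                    hops=p.hops + ((tgt, rel),),
                    embedding=node_states,  # placeholder, replaced below
                    terminated=(rel == self_id),
                ))
                new_terminated.append(rel == self_id)

        newP = extend_paths_batch(P_prev, expansions, node_states, model.scorer)
        pool_paths = new_paths + frozen
        pool_P = nn.concat([newP] + [e.reshape(1, model.dim) for e in frozen_embs],
                           axis=0) if frozen_embs else newP
        scores = score_paths_batch(h_x, h_v, pool_P, model.scorer)
        beta = aggregate_scores(pool_paths, scores.data[:, 0], config.aggregate)
        selected = sorted(beta, key=lambda c: (-beta[c], c))[:config.top_n]
        traces.append(HopTrace(paths=pool_paths, P=pool_P, scores=scores,
                               beta=beta, selected=selected))

        # next frontier: extendable paths ending at a selected terminal;
        # terminated paths always persist
        active, active_rows = [], []
        frozen, frozen_embs = [], []
        for i, p in enumerate(pool_paths):
            if p.terminated:
                frozen.append(p)
                frozen_embs.append(pool_P.gather([i]).reshape(model.dim))
            elif p.terminal_cui in selected:
                active.append(p)
                active_rows.append(i)
        P_prev = pool_P
    return traces


def infer(record: CaseRecord, graph: KnowledgeGraph, model: ModelParams,
          config: HopConfig, encoder: EncoderContract | None = None,
          style: str = "structural") -> PredictionResult:
    """Top-N diagnosis concepts with their best (highest-scoring) paths.

    The record must carry ``h_x``/``h_v`` already, or an ``encoder`` must
    be supplied.  Deterministic for fixed parameters and config.
    """
    if record.text_embedding is None and encoder is not None:
        encode_case(record, encoder, graph)
    traces = explore(record, graph, model, config)
    if not traces:
        logger.warning("record %s: no paths (no known source CUIs)",
                       record.note_id)
        return PredictionResult(note_id=record.note_id, no_paths=True)
    last = traces[-1]
    serialize = serialize_structural if style == "structural" else serialize_clause
    best: dict[str, PathState] = {}
    scores = last.scores.data[:, 0]
    for cui in last.selected:
        idxs = [i for i, p in enumerate(last.paths) if p.terminal_cui == cui]
        top = max(idxs, key=lambda i: (scores[i], -i))
        best[cui] = PathState(hops=last.paths[top].hops,
                              embedding=Tensor(last.P.data[top]),
                              score=float(scores[top]),
                              terminated=last.paths[top].terminated)
    return PredictionResult(
        note_id=record.note_id,
        selected_cuis=list(last.selected),
        best_paths=best,
        serialized_paths={c: serialize(best[c], graph) for c in last.selected},
    )


# ----------------------------------------------------------------------
# serialization
# ----------------------------------------------------------------------

def _preferred_name(graph: KnowledgeGraph, cui: str) -> str:
    return graph.node(cui).names[0]


def serialize_structural(path: PathState, graph: KnowledgeGraph) -> str:
    """Arrow-joined rendering: ``name → relation → name → ...``; a
    self-loop hop renders as the relation ``self``."""
    if not path.hops:
        raise ValueError("cannot serialize an empty path")
    fields = [_preferred_name(graph, path.hops[0][0])]
    for cui, rel in path.hops[1:]:
        fields.append(graph.relations.label(rel))
        fields.append(_preferred_name(graph, cui))
    return " → ".join(fields)


def parse_structural(serialized: str) -> list[str]:
    """Recover the (name, relation, name, ...) field sequence."""
    return serialized.split(" → ")


def serialize_clause(path: PathState, graph: KnowledgeGraph) -> str:
    """Clause-style text: ``src rel tgt`` for the first hop, subsequent
    hops joined as ``, which rel tgt``."""
    if len(path.hops) < 2:
        return _preferred_name(graph, path.hops[0][0])
    clauses: list[str] = []
    prev = path.hops[0][0]
    for i, (cui, rel) in enumerate(path.hops[1:]):
        label = graph.relations.label(rel)
        assert label, "relation labels are non-empty by construction"
        if i == 0:
            clauses.append(f"{_preferred_name(graph, prev)} {label} "
                           f"{_preferred_name(graph, cui)}")
        else:
            clauses.append(f"{label} {_preferred_name(graph, cui)}")
        prev = cui
    return ", which ".join(clauses)


# ----------------------------------------------------------------------
# prompt assembly
# ----------------------------------------------------------------------

TEMPLATES = {
    "path": "path_prompt.txt",
    "pathless": "pathless_prompt.txt",
}


def _load_template(template_id: str) -> str:
    if template_id not in TEMPLATES:
        raise KeyError(
            f"unknown template {template_id!r}; available: {sorted(TEMPLATES)}"
        )
    ref = resources.files("pathdx") / "templates" / TEMPLATES[template_id]
    return ref.read_text().rstrip("\n")


def assemble_prompt(record: CaseRecord, result: PredictionResult,
                    template_id: str = "path") -> str:
    """Fill the persona template with the note and the serialized paths;
    an empty result falls back to the pathless template verbatim."""
    if not result.selected_cuis:
        return _load_template("pathless").format(note=record.text)
    paths = "; ".join(result.serialized_paths[c] for c in result.selected_cuis)
    return _load_template(template_id).format(note=record.text, paths=paths)
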