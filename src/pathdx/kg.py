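"""Directed typed concept graph built from RRF-style terminology tables.

Nodes are concept unique identifiers (CUIs); edges are semantic relations
(e.g. ``causative agent of``) restricted to a physician-curated whitelist.
Edges are directed as stated in the source table; inverse relations are
never added automatically.  A reserved *self-loop* relation index marks
path termination during exploration and is materialised lazily — the
stored graph holds only curated edges.

The graph container is a :class:`networkx.MultiDiGraph` (parallel edges
with distinct relations between the same CUI pair are all kept); the
module surface below is what the rest of the package uses.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SELF_LOOP_LABEL = "self"

#: column positions for the minimal pipe-delimited table subset; a full
#: UMLS installation is a superset — override e.g. ``{"rel": (0, 7, 4)}``
#: to point at the CUI1/RELA/CUI2 positions of a licensed MRREL file.
DEFAULT_COLUMNS: dict[str, tuple[int, ...]] = {
    "conso": (0, 1),   # CUI, STR
    "rel": (0, 1, 2),  # CUI1, RELA, CUI2
    "sty": (0, 1),     # CUI, TUI
}


@dataclass(frozen=True)
class RelationVocabulary:
    """Ordered semantic-relation labels plus the reserved self-loop index."""

    relation_names: tuple[str, ...]

    @property
    def self_loop_id(self) -> int:
        return len(self.relation_names)

    @property
    def onehot_size(self) -> int:
        """Length of a relation one-hot vector (whitelist + self-loop)."""
        return len(self.relation_names) + 1

    def index(self, label: str) -> int:
        return self.relation_names.index(label)

    def label(self, idx: int) -> str:
        if idx == self.self_loop_id:
            return SELF_LOOP_LABEL
        return self.relation_names[idx]

    @classmethod
    def from_whitelist(cls, labels: Iterable[str]) -> "RelationVocabulary":
        seen: dict[str, None] = {}
        for lab in labels:
            lab = lab.strip()
            if lab:
                seen.setdefault(lab)
        if not seen:
            raise ValueError("relation whitelist must be non-empty")
        return cls(tuple(seen))


@dataclass
class ConceptNode:
    """One CUI with its synonym list, semantic types and embedding."""

    cui: str
    names: list[str]
    semantic_types: set[str] = field(default_factory=set)
    base_embedding: np.ndarray | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not self.names:
            raise ValueError(f"concept {self.cui} has an empty name list")


@dataclass(frozen=True)
class Subgraph:
    """Centers plus their 1-hop out-neighborhood."""

    center_cuis: frozenset[str]
    member_cuis: tuple[str, ...]          # sorted, deterministic
    edges: frozenset[tuple[str, int, str]]


class KnowledgeGraph:
    """Concept graph G = (V, E) with typed directed edges."""

    def __init__(self, relations: RelationVocabulary):
        self.relations = relations
        self._g = nx.MultiDiGraph()

    # -- construction --------------------------------------------------
    def add_concept(self, node: ConceptNode) -> None:
        if node.cui in self._g:
            raise ValueError(f"duplicate CUI {node.cui}")
        self._g.add_node(node.cui, node=node)

    def add_edge(self, source: str, relation_index: int, target: str) -> None:
        if source not in self._g or target not in self._g:
            raise KeyError(f"edge endpoint missing: {source} or {target}")
        if not (0 <= relation_index < len(self.relations.relation_names)):
            raise ValueError(f"relation index {relation_index} not whitelisted")
        self._g.add_edge(source, target, key=relation_index)

    # -- queries -------------------------------------------------------
    def __contains__(self, cui: str) -> bool:
        return cui in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def node(self, cui: str) -> ConceptNode:
        try:
            return self._g.nodes[cui]["node"]
        except KeyError:
            raise KeyError(f"unknown CUI {cui}") from None

    def cuis(self) -> list[str]:
        return sorted(self._g.nodes)

    def nodes(self) -> Iterable[ConceptNode]:
        for cui in self.cuis():
            yield self.node(cui)

    def edge_triples(self) -> set[tuple[str, int, str]]:
        return {(u, k, v) for u, v, k in self._g.edges(keys=True)}

    def out_triples(self, cui: str) -> list[tuple[str, int, str]]:
        """Whitelisted outgoing edges of ``cui``, deterministically ordered."""
        if cui not in self._g:
            raise KeyError(f"unknown CUI {cui}")
        triples = [(cui, k, v) for _, v, k in self._g.out_edges(cui, keys=True)]
        return sorted(triples, key=lambda t: (t[2], t[1]))

    def in_neighbors(self, cui: str) -> list[str]:
        return sorted(set(self._g.predecessors(cui)))


# ----------------------------------------------------------------------
# construction from tables
# ----------------------------------------------------------------------

def _parse_rows(rows, n_fields: int, what: str):
    for i, row in enumerate(rows, start=1):
        row = tuple(row)
        if len(row) < n_fields or any(
            not isinstance(x, str) or not x.strip() for x in row[:n_fields]
        ):
            raise ValueError(f"malformed {what} row {i}: {row!r}")
        yield tuple(x.strip() for x in row[:n_fields])


def build_graph(
    concept_table: Iterable[Sequence[str]],
    relation_table: Iterable[Sequence[str]],
    type_table: Iterable[Sequence[str]],
    whitelist: Iterable[str],
) -> KnowledgeGraph:
    """Assemble a :class:`KnowledgeGraph` from (cui, name), (cui1, rel, cui2)
    and (cui, semantic_type) rows, keeping only whitelisted relations.

    Rows are deduplicated; edges whose endpoints are not in the concept
    table are dropped (counted, not fatal); malformed rows abort with the
    offending row number.
    """
    vocab = RelationVocabulary.from_whitelist(whitelist)
    graph = KnowledgeGraph(vocab)

    names: dict[str, list[str]] = {}
    for cui, name in _parse_rows(concept_table, 2, "concept"):
        bucket = names.setdefault(cui, [])
        if name not in bucket:
            bucket.append(name)

    types: dict[str, set[str]] = {}
    for cui, tui in _parse_rows(type_table, 2, "semantic-type"):
        types.setdefault(cui, set()).add(tui)

    for cui in sorted(names):
        graph.add_concept(
            ConceptNode(cui=cui, names=names[cui],
                        semantic_types=types.get(cui, set()))
        )

    whitelisted = set(vocab.relation_names)
    seen_edges: set[tuple[str, int, str]] = set()
    dropped_unknown = 0
    for cui1, rela, cui2 in _parse_rows(relation_table, 3, "relation"):
        if rela not in whitelisted:
            continue
        if cui1 not in graph or cui2 not in graph:
            dropped_unknown += 1
            continue
        triple = (cui1, vocab.index(rela), cui2)
        if triple in seen_edges:
            continue
        seen_edges.add(triple)
        graph.add_edge(*triple)
    if dropped_unknown:
        logger.warning("dropped %d relation rows with unknown CUIs",
                       dropped_unknown)
    return graph


def one_hop_subgraph(graph: KnowledgeGraph, centers: Iterable[str]) -> Subgraph:
    """Centers plus all out-neighbors reached by one whitelisted edge."""
    centers = set(centers)
    for c in centers:
        if c not in graph:
            raise KeyError(f"unknown center CUI {c}")
    members = set(centers)
    edges: set[tuple[str, int, str]] = set()
    for c in centers:
        for triple in graph.out_triples(c):
            edges.add(triple)
            members.add(triple[2])
    return Subgraph(center_cuis=frozenset(centers),
                    member_cuis=tuple(sorted(members)),
                    edges=frozenset(edges))


def candidate_expansions(
    graph: KnowledgeGraph, frontier: Iterable[str]
) -> list[tuple[str, int, str]]:
    """All whitelisted outgoing triples from the frontier; a node with no
    outgoing edge contributes a single self-loop triple (termination)."""
    out: list[tuple[str, int, str]] = []
    for cui in sorted(set(frontier)):
        if cui not in graph:
            raise KeyError(f"unknown frontier CUI {cui}")
        triples = graph.out_triples(cui)
        if triples:
            out.extend(triples)
        else:
            out.append((cui, graph.relations.self_loop_id, cui))
    return out


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_rrf(path: str | Path, columns: tuple[int, ...]) -> list[tuple[str, ...]]:
    """Read a pipe-delimited RRF-like table, keeping the given columns."""
    frame = pd.read_csv(path, sep="|", header=None, dtype=str,
                        keep_default_na=False, engine="python")
    max_col = max(columns)
    if frame.shape[1] <= max_col:
        raise ValueError(
            f"{path}: expected at least {max_col + 1} pipe-delimited columns, "
            f"found {frame.shape[1]}"
        )
    return [tuple(row[c] for c in columns) for row in frame.itertuples(index=False)]


def read_whitelist(path: str | Path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def load_graph_tables(
    conso: str | Path,
    rel: str | Path,
    sty: str | Path,
    whitelist: str | Path,
    columns: Mapping[str, tuple[int, ...]] | None = None,
) -> KnowledgeGraph:
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    return build_graph(
        read_rrf(conso, cols["conso"]),
        read_rrf(rel, cols["rel"]),
        read_rrf(sty, cols["sty"]),
        read_whitelist(whitelist),
    )


def save_graph(graph: KnowledgeGraph, out_dir: str | Path) -> None:
    """Snapshot as tab-separated node/edge tables plus a metadata file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "nodes.tsv", "w") as fh:
        for node in graph.nodes():
            fh.write("\t".join([
                node.cui,
                "|".join(node.names),
                ",".join(sorted(node.semantic_types)),
            ]) + "\n")
    with open(out / "edges.tsv", "w") as fh:
        for u, k, v in sorted(graph.edge_triples()):
            fh.write(f"{u}\t{k}\t{v}\n")
    with open(out / "relations.tsv", "w") as fh:
        for i, lab in enumerate(graph.relations.relation_names):
            fh.write(f"{i}\t{lab}\n")
    wl_hash = hashlib.sha256(
        "\n".join(graph.relations.relation_names).encode()
    ).hexdigest()
    meta = {
        "n_nodes": len(graph),
        "n_edges": graph.n_edges,
        "n_relations": len(graph.relations.relation_names),
        "whitelist_sha256": wl_hash,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_graph(in_dir: str | Path) -> KnowledgeGraph:
    src = Path(in_dir)
    labels: dict[int, str] = {}
    for line in (src / "relations.tsv").read_text().splitlines():
        idx, lab = line.split("\t")
        labels[int(idx)] = lab
    vocab = RelationVocabulary(tuple(labels[i] for i in sorted(labels)))
    graph = KnowledgeGraph(vocab)
    for line in (src / "nodes.tsv").read_text().splitlines():
        cui, names, tuis = (line.split("\t") + ["", ""])[:3]
        graph.add_concept(ConceptNode(
            cui=cui,
            names=names.split("|"),
            semantic_types={t for t in tuis.split(",") if t},
        ))
    for line in (src / "edges.tsv").read_text().splitlines():
        u, k, v = line.split("\t")
        graph.add_edge(u, int(k), v)
    meta = json.loads((src / "meta.json").read_text())
    if meta["n_edges"] != graph.n_edges or meta["n_nodes"] != len(graph):
        raise ValueError(f"{in_dir}: snapshot metadata does not match tables")
    return graph
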