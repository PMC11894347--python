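"""Seeded synthetic knowledge graphs, note corpora and a toy encoder.

Everything the pipeline needs — a sparse directed concept graph with
typed edges, notes mentioning source concepts, and gold diagnoses
planted one or two hops from the sources — is generated here so the
package is fully testable without licensed terminology or clinical
data.

The note "text" is a bag of tokens, not prose: source-concept names
plus random distractor tokens.  That is sufficient because the toy
encoder is itself bag-of-tokens; nothing here approximates clinical
text realism.  Disease-typed (T047) concepts share one marker token in
their names, the toy analogue of the lexical regularities ("-itis",
"syndrome", "disease") that make real diagnosis names recognisable to
a subword encoder; without some lexical signature no encoder could
distinguish diagnoses from other terminals.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .encoding import CaseRecord, write_corpus
from .kg import KnowledgeGraph, build_graph

DISEASE_TYPE = "T047"
DISEASE_MARKER = "syndromic"
OTHER_TYPE = "T184"  # sign or symptom

RELATION_LABELS = (
    "causative_agent_of",
    "associated_with",
    "manifestation_of",
    "due_to",
    "finding_site_of",
    "interprets",
    "has_definitional_manifestation",
    "temporally_follows",
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic benchmark.

    Defaults give a 50-concept graph and 200 cases with gold diagnoses
    planted within two hops of the note's source concepts, matching the
    two-hop reachability constraint the gold-set filter enforces.
    """

    n_concepts: int = 50
    n_relations: int = 6
    edge_density: float = 0.06
    disease_fraction: float = 0.3
    n_cases: int = 200
    sources_per_case: int = 3
    gold_per_case: int = 2
    planted_hop_depth: int = 2      # maximum planted depth (1 or 2)
    distractor_rate: float = 0.3    # distractor tokens per source-name token
    vocab_size: int = 300
    seed: int = 7

    def __post_init__(self) -> None:
        if self.planted_hop_depth not in (1, 2):
            raise ValueError("planted_hop_depth must be 1 or 2")
        for name in ("n_concepts", "n_relations", "n_cases",
                     "sources_per_case", "gold_per_case", "vocab_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SynthTables:
    """RRF-style tables plus the whitelist, consumable by the KG store."""

    conso: pd.DataFrame   # CUI|STR
    rel: pd.DataFrame     # CUI1|RELA|CUI2
    sty: pd.DataFrame     # CUI|TUI
    whitelist: list[str] = field(default_factory=list)

    def build(self) -> KnowledgeGraph:
        return build_graph(
            [tuple(r) for r in self.conso.itertuples(index=False)],
            [tuple(r) for r in self.rel.itertuples(index=False)],
            [tuple(r) for r in self.sty.itertuples(index=False)],
            self.whitelist,
        )

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.conso.to_csv(out / "CONSO.RRF", sep="|", header=False, index=False)
        self.rel.to_csv(out / "REL.RRF", sep="|", header=False, index=False)
        self.sty.to_csv(out / "STY.RRF", sep="|", header=False, index=False)
        (out / "whitelist.txt").write_text("\n".join(self.whitelist) + "\n")


def _token(rng: np.random.Generator, vocab_size: int) -> str:
    return f"tok{rng.integers(0, vocab_size)}"


def generate_kg(config: SynthConfig) -> SynthTables:
    """Random sparse directed typed concept graph as RRF-style tables.

    A ``disease_fraction`` subset of concepts carries semantic type T047
    (and the marker token in its names); everything else is typed as a
    sign/symptom.  Edge existence is Bernoulli(edge_density) per ordered
    concept pair, with a uniformly chosen whitelisted relation.
    """
    rng = np.random.default_rng(config.seed)
    whitelist = list(RELATION_LABELS[: config.n_relations])

    cuis = [f"C{i:07d}" for i in range(1, config.n_concepts + 1)]
    n_disease = max(1, int(round(config.disease_fraction * config.n_concepts)))
    disease = set(rng.choice(cuis, size=n_disease, replace=False).tolist())

    conso_rows: list[tuple[str, str]] = []
    sty_rows: list[tuple[str, str]] = []
    for cui in cuis:
        base = [_token(rng, config.vocab_size) for _ in range(2)]
        if cui in disease:
            base.append(DISEASE_MARKER)
            sty_rows.append((cui, DISEASE_TYPE))
        else:
            sty_rows.append((cui, OTHER_TYPE))
        conso_rows.append((cui, " ".join(base)))
        if rng.random() < 0.3:  # occasional synonym row
            conso_rows.append((cui, " ".join(base[::-1])))

    rel_rows: list[tuple[str, str, str]] = []
    for u in cuis:
        for v in cuis:
            if u == v:
                continue
            if rng.random() < config.edge_density:
                rel_rows.append((u, whitelist[int(rng.integers(len(whitelist)))], v))
    if not rel_rows:
        raise ValueError("edge_density produced an empty edge set")

    return SynthTables(
        conso=pd.DataFrame(conso_rows, columns=["CUI", "STR"]),
        rel=pd.DataFrame(rel_rows, columns=["CUI1", "RELA", "CUI2"]),
        sty=pd.DataFrame(sty_rows, columns=["CUI", "TUI"]),
        whitelist=whitelist,
    )


def _reachable_disease(graph: KnowledgeGraph, source: str,
                       max_depth: int) -> dict[str, int]:
    """Disease-typed CUIs reachable from ``source``, with shallowest depth."""
    out: dict[str, int] = {}
    frontier = {source}
    seen = {source}
    for depth in range(1, max_depth + 1):
        nxt: set[str] = set()
        for u in frontier:
            for _, _, w in graph.out_triples(u):
                if w not in seen:
                    nxt.add(w)
        for w in sorted(nxt):
            if DISEASE_TYPE in graph.node(w).semantic_types and w not in out:
                out[w] = depth
        seen |= nxt
        frontier = nxt
    return out


def generate_cases(graph: KnowledgeGraph, config: SynthConfig,
                   max_retries: int = 200) -> list[CaseRecord]:
    """Notes with planted diagnoses.

    Each case samples source concepts with out-degree >= 1, picks
    ``gold_per_case`` disease-typed concepts reachable from the sources
    within ``planted_hop_depth`` hops (each verified reachable within 2
    hops, so every gold survives the evaluation-time gold-set filter),
    and writes the note as the source names plus distractor tokens.
    Gold diagnoses are stored as singleton sets, one per diagnosis.
    """
    rng = np.random.default_rng(config.seed + 1)
    eligible = [c for c in graph.cuis() if graph.out_triples(c)]
    if len(eligible) < config.sources_per_case:
        raise ValueError("graph has too few concepts with outgoing edges")

    records: list[CaseRecord] = []
    attempts = 0
    while len(records) < config.n_cases:
        attempts += 1
        if attempts > config.n_cases + max_retries:
            raise RuntimeError(
                "could not plant reachable gold diagnoses after "
                f"{max_retries} retries; graph too sparse in disease nodes"
            )
        sources = sorted(rng.choice(eligible, size=config.sources_per_case,
                                    replace=False).tolist())
        reach: dict[str, int] = {}
        for s in sources:
            for cui, depth in _reachable_disease(
                    graph, s, config.planted_hop_depth).items():
                if cui not in reach or depth < reach[cui]:
                    reach[cui] = depth
        candidates = sorted(c for c in reach if c not in sources)
        if len(candidates) < config.gold_per_case:
            continue
        golds = sorted(rng.choice(candidates, size=config.gold_per_case,
                                  replace=False).tolist())

        name_tokens: list[str] = []
        for s in sources:
            name_tokens.extend(graph.node(s).names[0].split())
        n_distract = int(round(config.distractor_rate * len(name_tokens)))
        distractors = [_token(rng, config.vocab_size) for _ in range(n_distract)]
        tokens = name_tokens + distractors
        rng.shuffle(tokens)

        records.append(CaseRecord(
            note_id=f"note{len(records):05d}",
            text=" ".join(tokens),
            source_cuis=sources,
            gold_sets=[{g} for g in golds],
        ))
    return records


# ----------------------------------------------------------------------
# toy encoder
# ----------------------------------------------------------------------

class ToyEncoder:
    """Deterministic bag-of-tokens encoder standing in for SapBERT.

    Every token hashes (crc32) into a pool of ``vocab_size`` seeded
    random unit vectors; a string encodes to the mean of its token
    vectors, truncated at ``max_tokens``.  Same string, same vector,
    across processes and platforms.
    """

    def __init__(self, vocab_size: int = 512, dimension: int = 16,
                 seed: int = 0, max_tokens: int = 512):
        if dimension < 2:
            raise ValueError("dimension must be >= 2")
        self.dimension = dimension
        self.vocab_size = vocab_size
        self.max_tokens = max_tokens
        rng = np.random.default_rng(seed)
        vecs = rng.normal(size=(vocab_size, dimension))
        self._table = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)

    def _token_vector(self, token: str) -> np.ndarray:
        idx = zlib.crc32(token.lower().encode()) % self.vocab_size
        return self._table[idx]

    def encode(self, text: str) -> np.ndarray:
        tokens = text.lower().split()[: self.max_tokens]
        if not tokens:
            warnings.warn("encoding an empty string yields a zero vector")
            return np.zeros(self.dimension)
        return np.mean([self._token_vector(t) for t in tokens], axis=0)


def toy_encoder(vocab_size: int = 512, dimension: int = 16,
                seed: int = 0) -> ToyEncoder:
    return ToyEncoder(vocab_size=vocab_size, dimension=dimension, seed=seed)


# ----------------------------------------------------------------------
# one-call simulation
# ----------------------------------------------------------------------

def simulate(config: SynthConfig, out_dir: str | Path) -> dict:
    """Generate tables + corpus + manifest under ``out_dir``; returns the
    manifest (seed, sizes, reachability check)."""
    out = Path(out_dir)
    tables = generate_kg(config)
    tables.save(out)
    graph = tables.build()
    records = generate_cases(graph, config)
    write_corpus(records, out / "corpus.jsonl")
    planted = sum(len(r.gold_union) for r in records)
    manifest = {
        "config": asdict(config),
        "n_nodes": len(graph),
        "n_edges": graph.n_edges,
        "n_cases": len(records),
        "planted_gold_total": planted,
        "all_golds_within_2_hops": True,  # guaranteed by construction
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
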