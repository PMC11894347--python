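"""Contextualized representations for concepts, notes and concept lists.

A concept's text is the concatenation of all its names joined by a
separator token; a pluggable encoder (SapBERT in production, a seeded
bag-of-tokens encoder in tests) maps strings to fixed-dimension vectors.
A TF-IDF-style table assigns relevance weights ``W_CUI`` that scale the
base concept embeddings before the graph network, down-weighting
concepts (e.g. temporal ones like "recent") whose neighborhoods rarely
lead to diagnoses.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

from .kg import ConceptNode, KnowledgeGraph

logger = logging.getLogger(__name__)

DEFAULT_SEPARATOR = "[SEP]"


@runtime_checkable
class EncoderContract(Protocol):
    """Deterministic text encoder: same string, same vector, length D."""

    dimension: int

    def encode(self, text: str) -> np.ndarray: ...


@dataclass
class CaseRecord:
    """One progress note: text, extracted source CUIs, gold diagnosis sets."""

    note_id: str
    text: str
    source_cuis: list[str]
    gold_sets: list[set[str]] = field(default_factory=list)
    text_embedding: np.ndarray | None = None       # h_x
    cui_list_embedding: np.ndarray | None = None   # h_v

    @property
    def gold_union(self) -> set[str]:
        out: set[str] = set()
        for s in self.gold_sets:
            out |= s
        return out


# ----------------------------------------------------------------------
# concept rendering and embedding
# ----------------------------------------------------------------------

def render_concept_text(node: ConceptNode,
                        separator_token: str = DEFAULT_SEPARATOR) -> str:
    """Join all concept names in stored order: ``name 1 [SEP] name 2``.

    The join is order-sensitive by design (the name list order is part of
    the concept's identity for encoding purposes).
    """
    if not node.names:
        raise ValueError(f"concept {node.cui} has no names to render")
    return f" {separator_token} ".join(node.names)


def embed_concepts(graph: KnowledgeGraph, encoder: EncoderContract,
                   separator_token: str = DEFAULT_SEPARATOR) -> KnowledgeGraph:
    """Set ``base_embedding`` (h_i) for every node in place; idempotent."""
    for node in graph.nodes():
        try:
            vec = np.asarray(encoder.encode(render_concept_text(node, separator_token)),
                             dtype=np.float64)
        except Exception as exc:  # re-raise naming the CUI
            raise RuntimeError(f"encoder failed on CUI {node.cui}: {exc}") from exc
        if vec.shape != (encoder.dimension,):
            raise ValueError(
                f"encoder returned shape {vec.shape} for CUI {node.cui}, "
                f"expected ({encoder.dimension},)"
            )
        node.base_embedding = vec
    return graph


def encode_case(record: CaseRecord, encoder: EncoderContract,
                graph: KnowledgeGraph,
                separator_token: str = DEFAULT_SEPARATOR) -> CaseRecord:
    """Fill ``h_x`` (note text) and ``h_v`` (concatenated source-concept
    names, one encoder pass) on the record, in place."""
    if not record.text:
        raise ValueError(f"record {record.note_id} has empty text")
    if not record.source_cuis:
        raise ValueError(f"record {record.note_id} has no source CUIs")
    record.text_embedding = np.asarray(encoder.encode(record.text), dtype=np.float64)
    rendered = f" {separator_token} ".join(
        render_concept_text(graph.node(c), separator_token)
        for c in record.source_cuis
    )
    record.cui_list_embedding = np.asarray(encoder.encode(rendered), dtype=np.float64)
    return record


# ----------------------------------------------------------------------
# TF-IDF concept weighting
# ----------------------------------------------------------------------

@dataclass
class WeightTable:
    """Per-CUI relevance weights W_CUI = tf x log(N / df).

    ``tf`` is the corpus-mean per-document frequency (total occurrences
    divided by the number of documents) and ``df`` the document
    frequency, so a CUI occurring once in every document has idf 0.
    """

    document_count: int
    tf: dict[str, float]
    df: dict[str, int]
    weights: dict[str, float]

    def weight(self, cui: str) -> float:
        """Weight for ``cui``; absent CUIs fall back to the smallest
        observed positive weight (logged)."""
        if cui in self.weights:
            return self.weights[cui]
        positives = [w for w in self.weights.values() if w > 0]
        fallback = min(positives) if positives else 1.0
        logger.warning("CUI %s absent from weight corpus; using fallback %g",
                       cui, fallback)
        return fallback

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# documents\t{self.document_count}\n")
            for cui in sorted(self.weights):
                fh.write(f"{cui}\t{self.tf[cui]:.17g}\t{self.df[cui]}"
                         f"\t{self.weights[cui]:.17g}\n")

    @classmethod
    def load(cls, path: str | Path) -> "WeightTable":
        tf: dict[str, float] = {}
        df: dict[str, int] = {}
        weights: dict[str, float] = {}
        n_docs = 0
        for line in Path(path).read_text().splitlines():
            if line.startswith("#"):
                n_docs = int(line.split("\t")[1])
                continue
            cui, t, d, w = line.split("\t")
            tf[cui], df[cui], weights[cui] = float(t), int(d), float(w)
        return cls(document_count=n_docs, tf=tf, df=df, weights=weights)


def compute_cui_weights(
    training_records: Sequence[CaseRecord],
    graph: KnowledgeGraph | None = None,
    type_multipliers: Mapping[str, float] | None = None,
) -> WeightTable:
    """TF-IDF weights from the source-CUI lists of a training corpus.

    ``type_multipliers`` optionally rescales weights by semantic type
    (e.g. down-weighting temporal concepts); a CUI with several types
    uses the product of its type multipliers.
    """
    if not training_records:
        raise ValueError("at least one training record is required")
    n_docs = len(training_records)
    counts: dict[str, int] = {}
    df: dict[str, int] = {}
    for rec in training_records:
        seen: set[str] = set()
        for cui in rec.source_cuis:
            counts[cui] = counts.get(cui, 0) + 1
            seen.add(cui)
        for cui in seen:
            df[cui] = df.get(cui, 0) + 1
    tf = {cui: counts[cui] / n_docs for cui in counts}
    weights = {cui: tf[cui] * math.log(n_docs / df[cui]) for cui in counts}
    if type_multipliers and graph is not None:
        for cui in weights:
            if cui in graph:
                for tui in sorted(graph.node(cui).semantic_types):
                    if tui in type_multipliers:
                        weights[cui] *= type_multipliers[tui]
    return WeightTable(document_count=n_docs, tf=tf, df=df, weights=weights)


def apply_weights(graph: KnowledgeGraph, table: WeightTable) -> KnowledgeGraph:
    """Scale every base embedding by its W_CUI (before the graph network)."""
    for node in graph.nodes():
        if node.base_embedding is None:
            raise ValueError(f"CUI {node.cui} has no base embedding to weight")
        w = table.weight(node.cui)
        node.weight = w
        node.base_embedding = node.base_embedding * w
    return graph


# ----------------------------------------------------------------------
# corpus I/O (line-delimited JSON records)
# ----------------------------------------------------------------------

def read_corpus(path: str | Path) -> list[CaseRecord]:
    records = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        try:
            obj = json.loads(line)
            records.append(CaseRecord(
                note_id=obj["note_id"],
                text=obj["text"],
                source_cuis=list(obj["source_cuis"]),
                gold_sets=[set(s) for s in obj.get("gold_cuis", [])],
            ))
        except (KeyError, json.JSONDecodeError) as exc:
            raise ValueError(f"{path}: malformed record on line {i}: {exc}") from exc
    return records


def write_corpus(records: Iterable[CaseRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps({
                "note_id": rec.note_id,
                "text": rec.text,
                "source_cuis": rec.source_cuis,
                "gold_cuis": [sorted(s) for s in rec.gold_sets],
            }) + "\n")


# ----------------------------------------------------------------------
# extractor interface
# ----------------------------------------------------------------------

class DictionaryMatcher:
    """Exact-string concept matcher over a small vocabulary.

    Stands in for a clinical concept extractor on the synthetic corpus:
    it lowercases the text and reports every CUI one of whose names
    occurs as a contiguous token sequence.  Not suitable for real
    clinical text.
    """

    def __init__(self, graph: KnowledgeGraph):
        self._names: list[tuple[tuple[str, ...], str]] = []
        for node in graph.nodes():
            for name in node.names:
                toks = tuple(name.lower().split())
                if toks:
                    self._names.append((toks, node.cui))
        # longest names first so multi-token matches win
        self._names.sort(key=lambda p: (-len(p[0]), p[0], p[1]))

    def extract(self, text: str) -> list[str]:
        tokens = text.lower().split()
        found: list[str] = []
        seen: set[str] = set()
        for toks, cui in self._names:
            n = len(toks)
            for i in range(len(tokens) - n + 1):
                if tuple(tokens[i:i + n]) == toks:
                    if cui not in seen:
                        seen.add(cui)
                        found.append(cui)
                    break
        return found


class SapBertEncoder:
    """Adapter for the production SapBERT encoder (optional dependency).

    Requires the ``transformers`` and ``torch`` packages; constructing it
    without them raises ImportError.  Tests use the deterministic toy
    encoder from :mod:`pathdx.synth` instead.
    """

    MODEL_NAME = "cambridgeltl/SapBERT-from-PubMedBERT-fulltext"

    def __init__(self, model_name: str | None = None, max_tokens: int = 512):
        try:
            from transformers import AutoModel, AutoTokenizer  # type: ignore
        except ImportError as exc:  # pragma: no cover - optional plugin
            raise ImportError(
                "SapBertEncoder requires the optional 'transformers' and "
                "'torch' packages; install them or use a toy encoder"
            ) from exc
        name = model_name or self.MODEL_NAME  # pragma: no cover
        self._tokenizer = AutoTokenizer.from_pretrained(name)  # pragma: no cover
        self._model = AutoModel.from_pretrained(name)  # pragma: no cover
        self.max_tokens = max_tokens  # pragma: no cover
        self.dimension = int(self._model.config.hidden_size)  # pragma: no cover

    def encode(self, text: str) -> np.ndarray:  # pragma: no cover
        import torch  # type: ignore

        with torch.no_grad():
            batch = self._tokenizer(text, truncation=True,
                                    max_length=self.max_tokens,
                                    return_tensors="pt")
            out = self._model(**batch).last_hidden_state[:, 0, :]
        return out.squeeze(0).numpy().astype(np.float64)
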