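"""Gold-set construction and automated metrics.

The gold diagnosis set for a note keeps the plan-section concepts that
are (a) of semantic type T047 (disease or syndrome) and (b) reachable
from at least one of the note's source concepts by a whitelisted path
of at most two hops.  Retrieval quality is Recall@N / Precision@N / F
over CUI sets; generated text is scored with ROUGE-2 (bigram overlap)
and ROUGE-L (longest common subsequence), both as balanced F-measures
on lowercased whitespace tokens.  Uncertainty is reported as percentile
bootstrap confidence intervals over per-note values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .kg import KnowledgeGraph

logger = logging.getLogger(__name__)

DISEASE_TYPE = "T047"


# ----------------------------------------------------------------------
# gold-set construction
# ----------------------------------------------------------------------

def build_gold_cui_set(plan_cuis: Iterable[str], source_cuis: Iterable[str],
                       graph: KnowledgeGraph, max_hops: int = 2) -> set[str]:
    """Plan CUIs of type T047 reachable from >= 1 source within
    ``max_hops`` whitelisted directed hops (sources themselves count as
    depth 0)."""
    reachable: set[str] = {c for c in source_cuis if c in graph}
    frontier = set(reachable)
    for _ in range(max_hops):
        nxt: set[str] = set()
        for u in frontier:
            for _, _, w in graph.out_triples(u):
                if w not in reachable:
                    nxt.add(w)
        reachable |= nxt
        frontier = nxt
    gold = {
        c for c in plan_cuis
        if c in graph
        and DISEASE_TYPE in graph.node(c).semantic_types
        and c in reachable
    }
    if not gold:
        logger.debug("empty gold set (no reachable T047 plan concepts)")
    return gold


# ----------------------------------------------------------------------
# set metrics
# ----------------------------------------------------------------------

def recall_precision_f(predicted: set[str], gold: set[str]) -> dict[str, float]:
    """R = |pred ∩ gold| / |gold|, P = |pred ∩ gold| / |pred|, F harmonic.

    Empty gold makes recall undefined — callers skip (and count) such
    notes; here the entry is returned with NaN recall.
    """
    hit = len(predicted & gold)
    recall = hit / len(gold) if gold else float("nan")
    precision = hit / len(predicted) if predicted else 0.0
    if gold and precision + recall > 0:
        f = 2 * precision * recall / (precision + recall)
    else:
        f = 0.0
    return {"recall": recall, "precision": precision, "f_score": f}


@dataclass
class MetricReport:
    """Corpus-level means (x100 to mirror table conventions) with the
    per-note values they were computed from."""

    n: int
    per_note: list[dict[str, float]] = field(default_factory=list)
    skipped_empty_gold: int = 0

    def mean(self, key: str) -> float:
        vals = [m[key] for m in self.per_note]
        return float(np.mean(vals)) if vals else 0.0

    def summary(self, scale: float = 100.0) -> dict[str, float]:
        return {
            "recall": round(self.mean("recall") * scale, 2),
            "precision": round(self.mean("precision") * scale, 2),
            "f_score": round(self.mean("f_score") * scale, 2),
            "n": self.n,
            "skipped_empty_gold": self.skipped_empty_gold,
        }


def corpus_report(pairs: Iterable[tuple[set[str], set[str]]]) -> MetricReport:
    """Aggregate (predicted, gold) pairs; empty-gold notes are excluded
    from the averages and counted."""
    per_note: list[dict[str, float]] = []
    skipped = 0
    for predicted, gold in pairs:
        if not gold:
            skipped += 1
            continue
        per_note.append(recall_precision_f(predicted, gold))
    return MetricReport(n=len(per_note), per_note=per_note,
                        skipped_empty_gold=skipped)


# ----------------------------------------------------------------------
# ROUGE
# ----------------------------------------------------------------------

def tokenize(text: str) -> list[str]:
    """Lowercased whitespace tokenization (the documented convention)."""
    return text.lower().split()


def _lcs_length(a: Sequence[str], b: Sequence[str]) -> int:
    if not a or not b:
        return 0
    prev = [0] * (len(b) + 1)
    for x in a:
        cur = [0] * (len(b) + 1)
        for j, y in enumerate(b, start=1):
            cur[j] = prev[j - 1] + 1 if x == y else max(prev[j], cur[j - 1])
        prev = cur
    return prev[-1]


def _f_measure(hit: int, n_cand: int, n_ref: int) -> float:
    if n_ref == 0:
        warnings.warn("empty reference; ROUGE score is 0")
        return 0.0
    if n_cand == 0 or hit == 0:
        return 0.0
    r = hit / n_ref
    p = hit / n_cand
    return 2 * p * r / (p + r)


def rouge_l(candidate: Sequence[str], reference: Sequence[str]) -> float:
    """ROUGE-L: longest-common-subsequence F-measure (beta = 1)."""
    return _f_measure(_lcs_length(candidate, reference),
                      len(candidate), len(reference))


def rouge_2(candidate: Sequence[str], reference: Sequence[str]) -> float:
    """ROUGE-2: bigram-overlap F-measure (clipped counts)."""
    def bigrams(toks):
        out: dict[tuple[str, str], int] = {}
        for pair in zip(toks, toks[1:]):
            out[pair] = out.get(pair, 0) + 1
        return out

    cb, rb = bigrams(list(candidate)), bigrams(list(reference))
    hit = sum(min(c, rb.get(g, 0)) for g, c in cb.items())
    return _f_measure(hit, sum(cb.values()), sum(rb.values()))


# ----------------------------------------------------------------------
# bootstrap confidence intervals
# ----------------------------------------------------------------------

def bootstrap_ci(per_note_values: Sequence[float], reps: int = 1000,
                 seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile CI of the mean over ``reps`` bootstrap resamples."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    values = np.asarray(per_note_values, dtype=float)
    if values.size < 2:
        point = float(values[0]) if values.size else 0.0
        logger.warning("fewer than 2 values; degenerate CI at %g", point)
        return point, point
    rng = np.random.default_rng(seed)
    means = np.array([
        rng.choice(values, size=values.size, replace=True).mean()
        for _ in range(reps)
    ])
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
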