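"""Joint prediction + contrastive training of the path-ranking model.

The objective is ``L = L_pred + L_CL``: a binary cross-entropy over
candidate terminal concepts (is the node in the gold diagnosis set?)
plus a margin hinge over cosine similarities that pulls path embeddings
reaching gold concepts toward the patient anchor ``A = h_x * h_v`` and
pushes paths ending elsewhere away.  Training is hop-wise: each batch
encodes the case, ranks the 1-hop candidates, extends only the selected
top-N frontier to the next hop and ranks again — the model never scores
all n-hop paths in one pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np

from . import nn
from .encoding import CaseRecord, EncoderContract, encode_case
from .inference import HopConfig, HopTrace, explore, infer
from .kg import KnowledgeGraph
from .metrics import recall_precision_f
from .model import ModelParams
from .nn import Adam, Tensor, cosine

logger = logging.getLogger(__name__)

LabelMode = Literal["union", "per_set"]


@dataclass
class TrainConfig:
    """Optimization settings (conventional defaults for this model family)."""

    epochs: int = 20
    lr: float = 1e-3
    batch_size: int = 8
    margin: float = 0.5
    negatives_per_anchor: int = 4
    top_n: int = 4
    max_hops: int = 2
    train_beam: int = 8         # exploration width during training
    label_mode: LabelMode = "union"
    val_fraction: float = 0.2
    seed: int = 0


@dataclass
class LossBreakdown:
    """total = prediction + contrastive, exactly (float addition)."""

    total: float
    prediction: float
    contrastive: float
    margin: float


@dataclass
class ContrastiveBatch:
    """Anchor A = h_x * h_v with positive / negative path embeddings."""

    anchor: Tensor
    positives: list[Tensor] = field(default_factory=list)
    negatives: list[Tensor] = field(default_factory=list)


# ----------------------------------------------------------------------
# losses
# ----------------------------------------------------------------------

def prediction_loss(candidate_probs: Mapping[str, Tensor],
                    gold_sets: Sequence[set[str]],
                    mode: LabelMode = "per_set") -> Tensor:
    """Mean binary cross-entropy over candidate terminal nodes.

    ``per_set`` averages a full BCE pass over each of the M gold sets
    (labels from that set alone); ``union`` uses a single pass with the
    union of all gold sets as positives.  Probabilities must lie in
    (0, 1) — squash raw scores first.
    """
    if not candidate_probs:
        raise ValueError("no candidates to score")
    for cui, p in candidate_probs.items():
        v = float(p.data)
        if not (0.0 < v < 1.0):
            raise ValueError(f"probability for {cui} outside (0,1): {v}")
    label_sets: list[set[str]]
    if mode == "union":
        union: set[str] = set()
        for s in gold_sets:
            union |= s
        label_sets = [union]
    elif mode == "per_set":
        label_sets = [set(s) for s in gold_sets] or [set()]
    else:
        raise ValueError(f"unknown label mode {mode!r}")

    per_set_losses: list[Tensor] = []
    order = sorted(candidate_probs)
    for labels in label_sets:
        terms: list[Tensor] = []
        for cui in order:
            p = candidate_probs[cui]
            if cui in labels:
                terms.append(-(p.log()))
            else:
                terms.append(-((1.0 - p).log()))
        per_set_losses.append(
            nn.concat([t.reshape(1) for t in terms], axis=0).mean()
        )
    total = per_set_losses[0]
    for t in per_set_losses[1:]:
        total = total + t
    return total * (1.0 / len(per_set_losses))


def contrastive_loss(batch: ContrastiveBatch, margin: float) -> Tensor:
    """Hinge over cosine similarities, averaged over (positive, negative)
    pairs: mean max(0, margin - cos(A, f+) + cos(A, f-))."""
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if not batch.positives or not batch.negatives:
        return Tensor(0.0)
    terms: list[Tensor] = []
    for fp in batch.positives:
        cp = cosine(batch.anchor, fp)
        for fneg in batch.negatives:
            cn = cosine(batch.anchor, fneg)
            terms.append((margin - cp + cn).relu().reshape(1))
    return nn.concat(terms, axis=0).mean()


def mine_path_features(paths: Sequence, P: Tensor,
                       gold_sets: Sequence[set[str]], anchor: Tensor,
                       k_negatives: int, rng: np.random.Generator
                       ) -> ContrastiveBatch:
    """Split scored paths into positives (terminal in the gold union) and
    up to ``k_negatives`` seeded uniformly sampled negatives."""
    if not paths:
        raise ValueError("at least one scored path is required")
    union: set[str] = set()
    for s in gold_sets:
        union |= s
    pos_idx = [i for i, p in enumerate(paths) if p.terminal_cui in union]
    neg_idx = [i for i, p in enumerate(paths) if p.terminal_cui not in union]
    if not pos_idx:
        logger.debug("no positive paths; contrastive contribution is 0")
    if neg_idx and k_negatives < len(neg_idx):
        neg_idx = sorted(rng.choice(neg_idx, size=k_negatives,
                                    replace=False).tolist())
    dim = P.shape[1]
    return ContrastiveBatch(
        anchor=anchor,
        positives=[P.gather([i]).reshape(dim) for i in pos_idx],
        negatives=[P.gather([i]).reshape(dim) for i in neg_idx],
    )


# ----------------------------------------------------------------------
# per-case loss assembly
# ----------------------------------------------------------------------

def _hop_probabilities(trace: HopTrace) -> dict[str, Tensor]:
    """Logistic squashing of the aggregated per-terminal scores beta."""
    terminals = sorted(trace.beta)
    n_paths = len(trace.paths)
    G = np.zeros((len(terminals), n_paths))
    for j, p in enumerate(trace.paths):
        G[terminals.index(p.terminal_cui), j] = 1.0
    beta = Tensor(G) @ trace.scores          # (n_terminals, 1)
    probs = beta.sigmoid()
    return {c: probs.gather([i]).reshape(()) for i, c in enumerate(terminals)}


def _within_reach(graph: KnowledgeGraph, targets: set[str],
                  budget: int) -> set[str]:
    """Nodes from which some target is reachable in <= budget forward hops."""
    good = set(targets)
    frontier = set(targets)
    for _ in range(budget):
        prev: set[str] = set()
        for g in frontier:
            if g in graph:
                prev.update(graph.in_neighbors(g))
        good |= prev
        frontier = prev
    return good


def case_loss(record: CaseRecord, graph: KnowledgeGraph, model: ModelParams,
              config: TrainConfig, rng: np.random.Generator
              ) -> tuple[Tensor, LossBreakdown] | None:
    """L = L_pred + L_CL for one case; None when no sources are in the graph.

    L_pred averages a BCE over the candidate ranking of every hop.  At
    the final hop a candidate is positive iff it is a gold diagnosis; at
    intermediate hops it is positive iff a gold is still reachable from
    it within the remaining hop budget (the node lies on a gold-leading
    path), so the beam is not taught to discard the intermediates that
    two-hop gold paths run through.  L_CL is mined from the final hop's
    path pool.
    """
    traces = explore(record, graph, model,
                     HopConfig(max_hops=config.max_hops,
                               top_n=config.train_beam))
    if not traces:
        return None
    hop_losses = []
    for h, t in enumerate(traces, start=1):
        remaining = config.max_hops - h
        if remaining > 0:
            label_sets = [_within_reach(graph, set(s), remaining)
                          for s in record.gold_sets]
        else:
            label_sets = record.gold_sets
        hop_losses.append(
            prediction_loss(_hop_probabilities(t), label_sets,
                            mode=config.label_mode)
        )
    l_pred = nn.concat([h.reshape(1) for h in hop_losses], axis=0).mean()

    last = traces[-1]
    anchor = Tensor(record.text_embedding) * Tensor(record.cui_list_embedding)
    batch = mine_path_features(last.paths, last.P, record.gold_sets, anchor,
                               config.negatives_per_anchor, rng)
    l_cl = contrastive_loss(batch, config.margin)
    total = l_pred + l_cl
    breakdown = LossBreakdown(total=float(l_pred.data) + float(l_cl.data),
                              prediction=float(l_pred.data),
                              contrastive=float(l_cl.data),
                              margin=config.margin)
    return total, breakdown


# ----------------------------------------------------------------------
# evaluation helper
# ----------------------------------------------------------------------

def evaluate_recall(records: Sequence[CaseRecord], graph: KnowledgeGraph,
                    model: ModelParams, top_n: int, max_hops: int = 2
                    ) -> dict[str, float]:
    """Corpus-mean Recall/Precision/F @ top_n against the gold unions
    (records with empty gold sets are skipped and counted)."""
    rs, ps, fs = [], [], []
    skipped = 0
    for rec in records:
        gold = rec.gold_union
        if not gold:
            skipped += 1
            continue
        result = infer(rec, graph, model, HopConfig(max_hops=max_hops,
                                                    top_n=top_n))
        m = recall_precision_f(set(result.selected_cuis), gold)
        rs.append(m["recall"])
        ps.append(m["precision"])
        fs.append(m["f_score"])
    if not rs:
        return {"recall": 0.0, "precision": 0.0, "f_score": 0.0,
                "n": 0, "skipped": skipped}
    return {"recall": float(np.mean(rs)), "precision": float(np.mean(ps)),
            "f_score": float(np.mean(fs)), "n": len(rs), "skipped": skipped}


# ----------------------------------------------------------------------
# training loop
# ----------------------------------------------------------------------

@dataclass
class EpochLog:
    epoch: int
    total: float
    prediction: float
    contrastive: float
    val_recall: float
    val_precision: float
    val_f: float


def split_dataset(records: Sequence[CaseRecord], val_fraction: float,
                  seed: int) -> tuple[list[CaseRecord], list[CaseRecord]]:
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(records))
    n_val = int(round(val_fraction * len(records)))
    val = [records[i] for i in idx[:n_val]]
    tr = [records[i] for i in idx[n_val:]]
    return tr, val


def train(model: ModelParams, records: Sequence[CaseRecord],
          graph: KnowledgeGraph, config: TrainConfig,
          encoder: EncoderContract | None = None
          ) -> tuple[ModelParams, list[EpochLog]]:
    """Optimize all parameters with Adam; fully seeded and deterministic.

    Records are encoded on the fly when an encoder is given.  Returns the
    trained model and a per-epoch log (losses + held-out Recall@N).
    """
    records = list(records)
    if encoder is not None:
        for rec in records:
            if rec.text_embedding is None:
                encode_case(rec, encoder, graph)
    train_recs, val_recs = split_dataset(records, config.val_fraction,
                                         config.seed)
    rng = np.random.default_rng(config.seed + 1)
    opt = Adam(model.parameters(), lr=config.lr)
    logs: list[EpochLog] = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_recs))
        tot = pred = cl = 0.0
        n_seen = 0
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start:start + config.batch_size]
            losses: list[Tensor] = []
            for i in batch_idx:
                out = case_loss(train_recs[i], graph, model, config, rng)
                if out is None:
                    continue
                loss, breakdown = out
                if not np.isfinite(breakdown.total):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, record "
                        f"{train_recs[i].note_id}: {breakdown}"
                    )
                losses.append(loss)
                tot += breakdown.total
                pred += breakdown.prediction
                cl += breakdown.contrastive
                n_seen += 1
            if not losses:
                continue
            opt.zero_grad()
            batch_loss = nn.concat([l.reshape(1) for l in losses], axis=0).mean()
            batch_loss.backward()
            opt.step()
        val = evaluate_recall(val_recs, graph, model, config.top_n,
                              config.max_hops)
        logs.append(EpochLog(
            epoch=epoch,
            total=tot / max(n_seen, 1),
            prediction=pred / max(n_seen, 1),
            contrastive=cl / max(n_seen, 1),
            val_recall=val["recall"],
            val_precision=val["precision"],
            val_f=val["f_score"],
        ))
        logger.info("epoch %d: loss %.4f (pred %.4f, cl %.4f) val R@%d %.3f",
                    epoch, logs[-1].total, logs[-1].prediction,
                    logs[-1].contrastive, config.top_n, logs[-1].val_recall)
    return model, logs


def write_epoch_log(logs: Sequence[EpochLog], path) -> None:
    with open(path, "w") as fh:
        fh.write("epoch\ttotal\tprediction\tcontrastive"
                 "\tval_recall\tval_precision\tval_f\n")
        for log in logs:
            fh.write(f"{log.epoch}\t{log.total:.6f}\t{log.prediction:.6f}"
                     f"\t{log.contrastive:.6f}\t{log.val_recall:.6f}"
                     f"\t{log.val_precision:.6f}\t{log.val_f:.6f}\n")
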