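# Methods

This note documents the model implemented by `pathdx`, the choices made
where the design was genuinely open, what the synthetic benchmark does
and does not show, and the numerical conventions that make runs
reproducible.

## Problem setting

A daily progress note mentions a set of medical concepts (CUIs). The
task is to propose the diagnoses a physician would list in the plan
section, by reasoning over a curated concept graph: starting from the
note's concepts, follow semantic relations for up to two hops and rank
the concepts reached by how well the path leading to them matches the
patient context. Two hops cover the clinically interesting indirect
patterns (symptom → finding → disease) while keeping the candidate
space small; the gold-set filter used in evaluation applies the same
two-hop reachability constraint, so model and metric agree on the
search horizon.

## Graph store

The graph is built from pipe-delimited RRF-style tables (concept names,
CUI–CUI relations, semantic types) restricted to a relation whitelist —
in production a physician-curated list of diagnosis-relevant relations;
a demo whitelist ships in `examples/`. Edges are directed exactly as
stated in the table; no inverse edges are added (inverse relations are
deliberately excluded from the whitelist model). Parallel edges with
different relations between the same CUI pair are all kept. The
self-loop used to terminate path exploration is a *reserved relation
index*, not a stored edge: the persisted graph equals the curated KG,
and self-loops are materialized lazily at expansion time.

Traversal is forward-only (along stored edge direction). Whether the
original system also walked edges backwards is not recoverable; forward
traversal matches the directed "leads to diagnosis" reading of the
whitelisted relations.

## Node representation

A concept's text is all of its names joined by a separator token
(`[SEP]` by default, configurable per encoder). Any deterministic
string-to-vector encoder satisfying `EncoderContract` can be plugged
in; the production adapter targets SapBERT (a BERT variant contrastively
pretrained to align biomedical synonyms), while tests use a seeded
bag-of-tokens encoder (below).

TF-IDF weighting (`W_CUI = tf · log(N/df)`, `tf` the corpus-mean
per-document frequency, `df` the document frequency) can scale each
base embedding before the graph network, down-weighting
corpus-ubiquitous concepts — e.g. temporal qualifiers like "recent" —
whose neighborhoods rarely lead anywhere diagnostic. An optional
per-semantic-type multiplier table (config) composes with it. The
standard tf·idf form was adopted; nothing in the package depends on the
exact variant, and it is off by default.

The SGIN uses sum aggregation over **out-neighbors** within the
retrieved subgraph (a flag adds in-neighbors), matching forward path
traversal. The MLP in each layer is two linear maps with a ReLU
(D→D→D), standard GIN practice. Relation types are *not* consumed by
the GIN; they enter through the path encoder's one-hot slot. The
stacked K·D output is reduced to D by a learned linear projection
before any scorer sees it — the stacking and the D-dimensional scorers
have to be reconciled somewhere, and a trainable projection is the
least-committal bridge.

## Path construction and termination

A path starts as a single source node whose embedding is the node state
itself; each hop maps `[previous path embedding ; relation one-hot ;
next node state]` through a two-layer feedforward network back to D.
The one-hot has length |whitelist|+1; the extra slot is the self-loop.

Termination semantics: a path whose terminal has no usable expansion
(no outgoing edge, or all targets already on the path — paths never
revisit their own nodes) takes exactly one self-loop hop *through the
FFN*, is marked terminated, and thereafter persists unchanged in the
candidate pool of every later hop: never re-extended, never dropped by
the beam. This keeps hop-1 dead ends competitive with hop-2 candidates
in the final ranking, and makes hop-by-hop exploration with an
unrestricted beam exactly equivalent to exhaustive enumeration of all
complete ≤J-hop paths (a property the test suite checks on 100 random
graphs).

## Scoring

Both scorers map (h_x, h_v, p) to a scalar through the same head
`φ(ReLU(σ(α)))`:

* **TriAttn**: `α = Σ_abc (h_x)_a (h_v)_b (p)_c W_abc`, a D×D×D tensor
  contraction. `σ` is a learned linear map from the scalar α to a
  hidden vector (size D by default) and `φ` a linear map to a scalar.
  Reading σ as the logistic function instead would be monotone-redundant
  immediately before a ReLU, so the projection reading was chosen.
* **MultiAttn**: relevancy matrices `H = [h_x; p; h_x−p; h_x⊙p]` and
  `Z = [h_v; p; h_v−p; h_v⊙p]` (concatenation / difference / product
  mirror the neutrality / contradiction / entailment constructions of
  natural-language-inference models); standard multihead self-attention
  (4 heads, hidden size D) runs over the four blocks of `H ⊙ Z` treated
  as a length-4 sequence, the output is mean-pooled over positions, then
  σ (D→hidden), ReLU, φ. Head count, sequence layout and pooling are
  implementation choices; nothing downstream depends on them.

Per-terminal aggregation `β` defaults to the sum over all paths ending
at the node (max and mean are config options), across paths from *all*
source concepts. Ties in top-N selection break lexicographically by CUI
everywhere, for reproducibility. Paths terminating at a source concept
compete normally.

## Training

`L = L_pred + L_CL`.

* `L_pred` is a mean binary cross-entropy over candidate terminals,
  probabilities obtained by a logistic squashing of β. With M gold sets
  per note, either per-set averaging or union labels can be used; the
  training loop defaults to **union** because the synthetic corpus
  stores one singleton set per diagnosis, and per-set averaging would
  make every gold a negative for every other set, capping its
  achievable probability.
* A BCE is applied at *every* hop. At the final hop a candidate is
  positive iff it is a gold diagnosis. At intermediate hops a candidate
  is positive iff a gold is still reachable from it within the
  remaining hop budget — i.e. it lies on a gold-leading path. Labeling
  intermediate hops with the final-hop rule instead demonstrably
  teaches the beam to discard the very nodes two-hop gold paths run
  through (held-out recall stalls near the untrained baseline).
* `L_CL` is a margin hinge over cosine similarities between the anchor
  `A = h_x ⊙ h_v` and path embeddings: positives reach a gold concept,
  negatives (4 per anchor, uniformly sampled, seeded) do not. Margin
  defaults to 0.5. Averaging is over (positive, negative) pairs; a note
  with no positives or no negatives contributes 0.
* Hop-wise exploration during training uses a wider beam (8) than the
  evaluation cutoff (N=4), so gold-leading intermediates survive the
  frontier while the parameters are still random. Inference always uses
  beam = N, faithful to the method. Training still never ranks all
  n-hop paths in one pass.
* Optimizer: Adam, lr 1e-3, batch size 8, fully seeded. At desk scale
  (D=16, 160 training notes) 1e-4 converges too slowly to be useful
  within 20 epochs — the trilinear tensor receives its gradient through
  a scalar bottleneck — so 1e-3 is the package default.

All parameters live on a compact reverse-mode autodiff engine
(`pathdx.nn`) over float64 numpy arrays: gradients are verified against
central finite differences in the test suite, and single-threaded
numpy keeps two same-seed runs bit-identical end to end.

## Synthetic benchmark

`generate_kg` draws a directed Erdős–Rényi graph (default: 50 concepts,
edge probability 0.06 per ordered pair, 6 relation labels); 30 % of
concepts carry the disease semantic type T047. `generate_cases`
(default 200 notes) samples 3 source concepts per note, plants 2 gold
diseases reachable within 1–2 hops of the sources, and writes the note
text as the source-concept names plus 30 % distractor tokens, shuffled.
Gold sets are stored as singleton sets, one per diagnosis, and every
planted gold provably passes the evaluation-time two-hop T047 filter.

Two deliberate simplifications, stated loudly:

* Note "text" is a **token bag**, not prose. That suffices because the
  toy encoder is itself bag-of-tokens (each token hashes to a fixed
  seeded unit vector; a string encodes to the mean of its token
  vectors, truncated at the token budget). Nothing here approximates
  clinical language, negation, or section structure.
* Disease-typed concepts share one marker token ("syndromic") in their
  names — the toy analogue of the lexical regularities ("-itis",
  "syndrome", "disease") that make real diagnosis names recognisable to
  a subword encoder. Without some lexical signature no encoder could
  tell diagnoses from other terminals, and nothing would be learnable.

Consequently, passing the benchmark shows that the machinery works: the
graph walk enumerates the right candidates, gradients flow everywhere,
and training separates gold-leading from stray paths when a signal
exists. It says nothing about performance on clinical text with a real
encoder and a licensed UMLS graph.

Benchmark scale was chosen so the full pipeline (generate → build →
train 20 epochs → infer → evaluate) completes in well under a minute on
one CPU: 50 concepts keep ≤2-hop candidate sets in the tens, and 200
notes give the trilinear tensor (4096 parameters) enough signal to fit.

## Numerical conventions and degenerate inputs

* Metrics are reported ×100 with 2 decimals, mirroring the field's
  table conventions. Notes with empty gold sets are excluded from
  averages and counted separately (recall is undefined there).
* ROUGE-L uses the canonical longest common **subsequence** (the LCS
  F-measure, β=1), on lowercased whitespace tokens.
* Bootstrap CIs are percentile intervals over resampled means (default
  1000 reps, seeded); fewer than two values collapse to a degenerate
  point interval.
* Cosine of a zero-norm vector is an error, not a silent 0; encoding an
  empty string warns and returns a zero vector; a BCE probability
  outside (0,1) is an error; a NaN loss aborts training with a
  diagnostic naming the record.
* Checkpoints serialize parameters as JSON (Python's shortest-repr
  floats round-trip float64 exactly), with a shape manifest checked on
  load.

## Known limitations

* No real concept extractor: source CUIs arrive in the record; the
  bundled exact-string dictionary matcher only serves the synthetic
  vocabulary.
* The SapBERT adapter requires the optional `transformers`/`torch`
  stack and is untested offline.
* Path exploration is greedy beam search; nothing probabilistic, no
  backtracking, no cross-hop score normalization.
* The artifact ends at prompt text — no language model is invoked, and
  no perplexity-based prompt selection is performed.
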