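# Methods

This note documents the matching semantics, voting rule, simulator design and
numerical conventions implemented in `bioevents`, together with the design
choices that were genuinely open and the package's known limitations.

## Data model

A corpus is a set of documents, each a raw text string (`.txt`) with a fixed
layer of protein mentions (`.a1`). Every annotation source — the gold
standard or one extraction system — contributes, per document, an `.a2`
fragment: trigger text-bounds, events, `M` modification lines and `*` Equiv
lines. Character offsets are 0-based and half-open, and a text-bound's
surface string must equal the addressed text slice; both are enforced at
parse time. Event argument graphs are checked acyclic, every event must
carry at least one `Theme`, triggers must carry the event's own type, and
only regulation-family events (`Regulation`, `Positive_regulation`,
`Negative_regulation`) may take events as `Theme`/`Cause` arguments.

Numbered roles (`Theme2`, `Theme3`, ...) are treated as an unordered `Theme`
multiset: `Binding` argument order carries no meaning. `M` lines
(`Negation`/`Speculation`) are parsed and preserved through round-trips but
excluded from all scoring, which covers core events only.

Serialization is deterministic: triggers ordered by offset, events emitted in
a Kahn topological order with offset/structure tie-breaking, ids renumbered.
`parse(write(x))` is annotation-equal to `x` (equality up to id renaming) and
a second write reproduces the first byte for byte — this round-trip is the
main correctness oracle for the I/O layer.

## Event equality

Two events are equal when (1) their types match, (2) their triggers match as
spans, and (3) their scored arguments admit a one-to-one correspondence, with
protein arguments compared as spans and event arguments compared recursively.
Acyclicity guarantees termination; the correspondence is found by
backtracking within each role group (argument lists are tiny, so exhaustive
search is cheap and exact).

Two axes are configurable via `MatchMode`:

- **Span mode.** *Strict*: identical `(start, end)` and type. *Approximate*:
  same type, candidate span contained in the reference span extended by one
  word on each side. Words are maximal alphanumeric runs; the left edge of
  the window is the start of the last token lying entirely before the
  reference span (so a reference boundary inside a token also admits the
  remainder of that token — "expression" matches "overexpression"), the
  right edge symmetrically. The window is anchored on the *reference* span,
  which makes approximate matching asymmetric; the evaluation anchors on the
  gold side in both the recall and the precision direction. The exact
  extension rule is a convention, isolated behind `MatchMode` so a different
  rule can be substituted; every strict match is an approximate match by
  construction.
- **Recursive mode.** *Strict*: nested event arguments are compared with the
  full scored-role set. *Approximate*: nested events are compared on their
  `Theme` arguments only (span matching still applies at every level). One
  consequence, exercised in the tests: a parent regulation event can be equal
  across systems while its own sub-events differ on `Cause`.

Scored roles default to `{Theme, Cause}` (core-task scoring);
`Site`/`CSite`/`AtLoc`/`ToLoc` are excluded from equality unless opted in.
With `use_equiv` enabled, a protein argument matches any member of its
reference-side Equiv group. Equiv lines are parsed unconditionally but ignored
by matching by default, since typical inputs do not carry them.

## Scores

Matching between two annotation sets is **existential** in both directions: a
reference event is recalled if *any* equal candidate exists, a candidate is
precise if *any* equal reference exists. This mirrors the voting rule's
"equal event exists in service *i*" semantics; a maximum-bipartite variant is
deliberately out of scope. Counts are kept per event type and pooled
(micro-averaged) into the Total row; `F1 = 2PR/(P+R)`, defined as 0 when
`P + R = 0`. All arithmetic is done at full precision; rounding (2 decimals,
half-up) happens only when rendering reports. Self-comparison scores 100
everywhere, approximate scores dominate strict scores, and under strict
matching swapping the two sets swaps precision and recall — all asserted as
properties in the test suite, alongside exact agreement with an independent
brute-force comparator on randomized fixtures.

Published score tables of this evaluation style are reproduced by the same
arithmetic: recomputing F1 from printed precision/recall pairs matches the
printed F1 at 2 decimals for self-consistent rows; a few printed rows were
evidently computed from unrounded counts and recomputation from the rounded
pair lands up to 0.03 away (documented in the acceptance tests as a property
of the printed data, not a tolerance of the implementation).

## Ensembling

Every event instance of every included system is a candidate. For candidate
`c` and system `i`, `b_i = 1` iff system `i` contains an event equal to `c`
under the configured mode (a candidate always supports itself); the weighted
score is `sum_i w_i * b_i`, unit weights by default ("averaged ensemble").
Acceptance is **strictly** `score > threshold` — with K unit-weight systems
the meaningful thresholds are the integers 0..K−1, and threshold 0 yields the
deduplicated union of the inputs.

Approximate equality is not transitive, so candidates are not clustered into
equivalence classes; votes are computed per candidate and deduplication is a
greedy scan in deterministic order (document id, source rank, event id),
dropping any candidate equal to an already-emitted consensus event. The
representative of a group of mutually equal candidates is therefore the
instance from the highest-ranked system — deterministic, and plausibly the
best span quality. A consensus event's triggers and protein arguments are
copied from its representative. If an accepted parent's `Theme` sub-event was
itself rejected by the vote, the representative's own sub-event is
force-emitted (and logged) so the consensus is always a valid, serialisable
annotation set; conservation holds — every consensus event is equal to at
least one input event.

`sweep_thresholds` computes votes once and evaluates the consensus against
gold for every threshold on the grid (integers 0..K−1 for unit weights; 0
plus the sorted distinct achievable scores for weighted voting — any other
grid would only repeat consensus sets). The best row maximizes F1, ties
resolved toward the lower threshold. `top_n_ensemble` restricts voting to
the n systems ranked highest by total approximate F1 against gold (ranking
uses the micro-averaged Total row, ties broken lexicographically by source
id) and reports the best row per n. Optimizing the threshold on the same
evaluation set is reproduced as-is — it measures the potential of the
ensemble, not a fair head-to-head against systems tuned elsewhere.

## Synthetic corpora and simulated systems

The generator emits template sentences ("In human cells , `<P1>` activates
the phosphorylation of `<P2>` .") over a pool of human gene symbols. Triggers
are deterministic words, offsets are computable, and the nine-type grammar is
respected by construction; regulation events take an event `Theme` with
probability `nesting_prob`, recursing as noun phrases up to
`max_nesting_depth` chained events, and may carry a protein `Cause`.
Defaults: 20 documents × 10 sentences, 3 candidate proteins per sentence, a
type mix loosely shaped like the GENIA event distribution (expression and
positive regulation dominant, catabolism rare), `nesting_prob` 0.4, depth 3.
One random stream per spec, split per document by counter: identical specs
give byte-identical corpora.

`simulate_system` derives an imperfect extractor from gold:

- each event is kept with probability `target_recall`; a parent whose `Theme`
  event was dropped is dropped in cascade, mimicking error propagation from
  physical-event prediction into regulatory-event prediction. On nested
  corpora effective recall is therefore *below* the per-event target by
  design; rate-recovery checks use nesting-free mixes.
- kept triggers are jittered with probability `span_jitter_prob` by extending
  the span within its own one-word window — breaking strict but never
  approximate matching.
- spurious but grammar-valid events are added, anchored on a decoy token
  ("human") planted in every sentence at least two words away from any true
  trigger, so they can never match a gold event even approximately. The
  spurious count follows the running total `kept·(1−p)/p`, so corpus-level
  precision matches `target_precision` up to integer rounding.

What the simulator does *not* emulate: real lexical variation in triggers,
boundary disagreements beyond the one-word window, type confusions,
partially-correct argument structures, or the correlated error profiles of
real systems (spurious events across simulated systems are independent draws,
which makes voting unrealistically effective — synthetic ensemble gains are
direction-valid but not magnitude-comparable to published ones). Passing
tests demonstrate the correctness of the metric and voting machinery, not
extraction quality on real text.

## Numerical and procedural conventions

- Tokenization: maximal `[0-9A-Za-z]+` runs; everything else is a boundary.
- Rounding: half-up to 2 decimals, only at rendering (`round2`).
- Determinism: all orderings (trigger/event serialization, candidate pooling,
  deduplication, ranking ties) are explicitly specified; identical inputs
  give byte-identical outputs everywhere, including the CLI.
- Degenerate inputs: empty annotation sets score 0 (not NaN); an empty
  threshold-0 consensus of one system equals that system; comparing events
  across documents is a usage error, as is a document-id mismatch between
  sets.
- Validation failures (spans, dangling references, cycles, missing `Theme`,
  unknown types/roles) raise immediately with the offending line; a lenient
  mode downgrades unknown types/roles to warnings and drops the records,
  cascading over anything left dangling.

## Problem sizes in the checks

The test suite and acceptance script run at desk scale, chosen to make every
stochastic check statistically meaningful: oracle-equivalence on 200
randomized fixtures of ≤ 50 events; voting enumeration on ≤ 10-event,
3-system fixtures; monotonicity across 20 seeds; rate recovery on 500-event
nesting-free corpora against 99% binomial intervals; the acceptance script's
synthetic study uses a ~230-event nested corpus with nine simulated systems
mirroring the published per-system operating points.

## Known limitations

- Exact parity with the official BioNLP'09 shared-task scorer is not claimed;
  the approximate-span and nested-comparison rules are stated conventions of
  this implementation, isolated behind `MatchMode`.
- Existential matching can count one candidate against several reference
  events (and vice versa); no bipartite assignment is performed.
- Only the unit-weight ensemble is exercised end to end; weighted voting is
  fully supported but no particular weighting scheme is endorsed.
- Speculation/negation (`M` lines) are preserved, never scored.
- No statistical significance testing between systems.
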