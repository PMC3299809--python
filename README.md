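# bioevents

Comparison, evaluation and majority-vote ensembling of biomolecular **event
extraction** outputs in the BioNLP shared-task standoff format.

Event extraction systems read biomedical text with known protein mentions and
produce typed events — `Phosphorylation`, `Binding`, `Gene_expression`, the
regulation family, and so on — each anchored to a trigger span and carrying
role-labelled arguments (`Theme`, `Cause`, ...) that may point to proteins or,
for regulation events, to other events. Different systems have different
strengths, and combining several of them by voting usually beats the best
single one. This package provides the computational machinery for that kind
of meta-analysis:

- **standoff I/O** (`bioevents.standoff`): read/write `.txt` / `.a1` / `.a2`
  files, with validation (offsets, reference resolution, acyclicity, event
  grammar) and deterministic, round-trip-faithful serialization.
- **event matching** (`bioevents.matching`): strict and approximate recursive
  event equality, and per-type + micro-averaged total precision/recall/F1
  between two annotation sets. Approximate matching accepts a candidate span
  inside the reference span extended by one word on each side, and compares
  nested event arguments on their `Theme` arguments only.
- **evaluation** (`bioevents.evaluation`): all-pairs comparison of N sources
  (gold-anchored pairs are evaluations, others measure inter-system
  similarity) and F1 ranking.
- **ensemble** (`bioevents.ensemble`): (weighted) majority voting. A candidate
  event is accepted when `sum_i w_i * b_i > threshold`, where `b_i = 1` iff an
  equal event exists in system *i*; includes threshold sweeps and top-n system
  selection.
- **synthetic corpora** (`bioevents.synthetic`): template-sentence corpora
  with gold events (including nested regulation chains) and simulated
  extractors with configurable recall, precision and trigger-span jitter —
  so every pipeline stage can be exercised and checked end to end without any
  restricted dataset.

The scores are the shared-task style metrics: for a reference (gold) set *G*
and candidate set *S*,

    recall    = 100 * |{g in G : exists s in S, s == g}| / |G|
    precision = 100 * |{s in S : exists g in G, g == s}| / |S|
    F1        = 2 * P * R / (P + R)

with `==` the strict or approximate recursive event equality, counted per
event type and pooled (micro-averaged) for the Total row.

## Worked example

```sh
# 1. a synthetic corpus with three imperfect extractors
bioevents simulate --out demo --seed 7 --n-docs 2 --sentences 6 \
    --system s1:0.8:0.9:0.1 --system s2:0.5:0.8:0.1 --system s3:0.3:0.7:0.1

# 2. evaluate them against the generated gold standard
bioevents evaluate --root demo --systems s1,s2,s3

# 3. sweep the majority-vote threshold
bioevents sweep --root demo --systems s1,s2,s3
```

The evaluation report (step 2) begins:

```
Type	Metric	s1	s2	s3
Rank	#	1	2	3
Total	F1	78.57	56.00	43.48
Total	PR	91.67	77.78	71.43
Total	RC	68.75	43.75	31.25
```

`s1` was simulated with the highest recall/precision targets and ranks first;
each printed F1 is the harmonic mean of the printed precision (PR) and recall
(RC). The threshold sweep (step 3) prints:

```
threshold	F1	PR	RC
0	76.47	72.22	81.25
1	60.87	100.00	43.75
2	31.58	100.00	18.75
```

Raising the threshold trades recall for precision: the deduplicated union of
all three systems (`threshold 0`, i.e. vote score > 0) recovers the most gold
events, while accepting only events at least two systems agree on
(`threshold 1`) already makes precision perfect on this tiny corpus at a
heavy recall cost. The same machinery is available as library functions
(`compute_metrics`, `pairwise_compare`, `sweep_thresholds`, `top_n_ensemble`).

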