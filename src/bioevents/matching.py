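"""Strict and approximate event matching with per-type precision/recall/F1.

Two events are equal when their types match, their triggers match as spans,
and their scored arguments (Theme and Cause by default) can be put into a
one-to-one correspondence — protein arguments compared as spans, event
arguments compared recursively.  The strict variant requires exact spans and
full recursive structure; the approximate variant follows the shared-task
convention: a candidate span may lie anywhere within the reference span
extended by one word on each side, and nested event arguments are compared on
their Theme arguments only.

Between two annotation sets, matching is existential in both directions: a
reference event counts as recalled if *any* equal candidate event exists, and
a candidate event counts as precise if *any* equal reference event exists.
Scores are micro-averaged: per-type counts are pooled before computing the
Total row.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from functools import lru_cache

from .model import (
    AnnotationSet,
    DocAnnotations,
    Event,
    TextBound,
    role_base,
)

STRICT = "strict"
APPROXIMATE = "approximate"

#: Roles counted in event equality under core-task scoring.
DEFAULT_SCORED_ROLES: frozenset[str] = frozenset({"Theme", "Cause"})

_TOKEN_RE = re.compile(r"[0-9A-Za-z]+")


class MatchModeError(ValueError):
    pass


@dataclass(frozen=True)
class MatchMode:
    """Configuration of the event-equality relation.

    ``span_mode`` / ``recursive_mode`` select strict or approximate span and
    nested-argument comparison; strict+strict is exact structural equality.
    ``scored_roles`` lists the role bases that participate in equality
    (Site/CSite/AtLoc/ToLoc are excluded under core-task scoring).
    ``use_equiv`` lets a protein argument match any member of its
    reference-side Equiv group.
    """

    span_mode: str = APPROXIMATE
    recursive_mode: str = APPROXIMATE
    scored_roles: frozenset[str] = DEFAULT_SCORED_ROLES
    use_equiv: bool = False

    def __post_init__(self) -> None:
        for m in (self.span_mode, self.recursive_mode):
            if m not in (STRICT, APPROXIMATE):
                raise MatchModeError(f"unknown match mode {m!r}")


#: Exact structural equality.
STRICT_MODE = MatchMode(span_mode=STRICT, recursive_mode=STRICT)
#: The relaxed shared-task-style metric (the headline metric).
APPROX_MODE = MatchMode(span_mode=APPROXIMATE, recursive_mode=APPROXIMATE)


@lru_cache(maxsize=512)
def _token_spans(text: str) -> tuple[tuple[int, int], ...]:
    """Maximal alphanumeric runs; everything else is a boundary."""
    return tuple(m.span() for m in _TOKEN_RE.finditer(text))


def extension_window(text: str, start: int, end: int) -> tuple[int, int]:
    """The span ``[start, end)`` extended by one word on each side.

    The left edge moves to the start of the last token lying entirely before
    ``start`` (or 0), the right edge to the end of the first token beginning
    at or after ``end`` (or the text length).  A span boundary falling inside
    a token therefore also admits the remainder of that token.
    """
    tokens = _token_spans(text)
    ext_start = 0
    for s, e in tokens:
        if e <= start:
            ext_start = s
        else:
            break
    ext_end = len(text)
    for s, e in tokens:
        if s >= end:
            ext_end = e
            break
    return ext_start, ext_end


def span_match(
    reference: TextBound,
    candidate: TextBound,
    span_mode: str,
    text: str,
) -> bool:
    """Span equality: exact under strict, one-word window under approximate.

    The window is anchored on the *reference* span; approximate matching is
    therefore not symmetric in its arguments.
    """
    if reference.ann_type != candidate.ann_type:
        return False
    if (reference.start, reference.end) == (candidate.start, candidate.end):
        return True
    if span_mode == STRICT:
        return False
    ext_start, ext_end = extension_window(text, reference.start, reference.end)
    return ext_start <= candidate.start and candidate.end <= ext_end


def _protein_match(
    ref: TextBound,
    cand: TextBound,
    mode: MatchMode,
    ref_doc: DocAnnotations,
) -> bool:
    if mode.use_equiv:
        return any(
            span_match(m, cand, mode.span_mode, ref_doc.text)
            for m in ref_doc.equiv_members(ref)
        )
    return span_match(ref, cand, mode.span_mode, ref_doc.text)


def _match_multiset(refs: list, cands: list, compat) -> bool:
    """Perfect one-to-one correspondence via backtracking (lists are tiny)."""
    if len(refs) != len(cands):
        return False
    if not refs:
        return True
    head = refs[0]
    for i, c in enumerate(cands):
        if compat(head, c) and _match_multiset(
            refs[1:], cands[:i] + cands[i + 1 :], compat
        ):
            return True
    return False


def event_equal(
    reference: Event,
    candidate: Event,
    mode: MatchMode,
    ref_doc: DocAnnotations,
    cand_doc: DocAnnotations,
    _nested: bool = False,
) -> bool:
    """Recursive event equality under the given mode.

    Argument graphs are acyclic, so recursion terminates.  When
    ``recursive_mode`` is approximate, nested event arguments are compared on
    their Theme arguments only (span matching still applies at every level).
    """
    if ref_doc.doc_id != cand_doc.doc_id:
        raise MatchModeError(
            f"cannot compare events across documents "
            f"({ref_doc.doc_id} vs {cand_doc.doc_id})"
        )
    if reference.ev_type != candidate.ev_type:
        return False
    if not span_match(
        ref_doc.trigger_of(reference),
        cand_doc.trigger_of(candidate),
        mode.span_mode,
        ref_doc.text,
    ):
        return False

    if _nested and mode.recursive_mode == APPROXIMATE:
        scored = frozenset({"Theme"})
    else:
        scored = mode.scored_roles

    ref_by_role: dict[str, list] = {}
    cand_by_role: dict[str, list] = {}
    for ev, doc, bucket in (
        (reference, ref_doc, ref_by_role),
        (candidate, cand_doc, cand_by_role),
    ):
        for role, target in ev.args:
            base = role_base(role)
            if base in scored:
                bucket.setdefault(base, []).append(doc.resolve(target))
    if set(ref_by_role) != set(cand_by_role):
        return False

    def compat(r, c) -> bool:
        if isinstance(r, Event) and isinstance(c, Event):
            return event_equal(r, c, mode, ref_doc, cand_doc, _nested=True)
        if isinstance(r, TextBound) and isinstance(c, TextBound):
            return _protein_match(r, c, mode, ref_doc)
        return False

    return all(
        _match_multiset(ref_by_role[role], cand_by_role[role], compat)
        for role in ref_by_role
    )


# ---------------------------------------------------------------------------
# Scores

def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (percentages); 0 when both are 0."""
    if not (0 <= precision <= 100 and 0 <= recall <= 100):
        raise ValueError(f"precision/recall out of [0,100]: {precision}, {recall}")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def round2(value: float) -> float:
    """Half-up rounding to 2 decimals, applied only when rendering reports."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))


@dataclass
class TypeCounts:
    """Match bookkeeping for one event type (or the pooled Total)."""

    n_gold: int = 0
    n_pred: int = 0
    tp_gold: int = 0  # reference events for which an equal candidate exists
    tp_pred: int = 0  # candidate events for which an equal reference exists

    @property
    def recall(self) -> float:
        return 100.0 * self.tp_gold / self.n_gold if self.n_gold else 0.0

    @property
    def precision(self) -> float:
        return 100.0 * self.tp_pred / self.n_pred if self.n_pred else 0.0

    @property
    def f1(self) -> float:
        return f1(self.precision, self.recall)

    def add(self, other: "TypeCounts") -> None:
        self.n_gold += other.n_gold
        self.n_pred += other.n_pred
        self.tp_gold += other.tp_gold
        self.tp_pred += other.tp_pred


@dataclass
class MetricReport:
    """Per-type and micro-averaged total scores for one (reference, candidate)
    pair of annotation sets, with the matched instance pairs retained for
    reports and diffing."""

    reference_id: str
    candidate_id: str
    per_type: dict[str, TypeCounts] = field(default_factory=dict)
    matched_pairs: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def total(self) -> TypeCounts:
        tot = TypeCounts()
        for counts in self.per_type.values():
            tot.add(counts)
        return tot


def compute_metrics(
    reference: AnnotationSet,
    candidate: AnnotationSet,
    mode: MatchMode = APPROX_MODE,
) -> MetricReport:
    """Score ``candidate`` against ``reference`` under ``mode``.

    Recall counts reference events with an equal candidate event; precision
    counts candidate events with an equal reference event (both existential).
    ``matched_pairs`` records, per recalled reference event, the first equal
    candidate instance in id order.
    """
    if reference.doc_ids() != candidate.doc_ids():
        raise MatchModeError(
            f"document ID mismatch between {reference.source_id!r} and "
            f"{candidate.source_id!r}"
        )
    report = MetricReport(reference.source_id, candidate.source_id)

    def counts_for(ev_type: str) -> TypeCounts:
        return report.per_type.setdefault(ev_type, TypeCounts())

    for doc_id in reference.doc_ids():
        ref_doc = reference.docs[doc_id]
        cand_doc = candidate.docs[doc_id]
        ref_events = [ref_doc.events[i] for i in sorted(ref_doc.events)]
        cand_events = [cand_doc.events[i] for i in sorted(cand_doc.events)]
        for rev in ref_events:
            c = counts_for(rev.ev_type)
            c.n_gold += 1
            for cev in cand_events:
                if event_equal(rev, cev, mode, ref_doc, cand_doc):
                    c.tp_gold += 1
                    report.matched_pairs.append((doc_id, rev.ev_id, cev.ev_id))
                    break
        for cev in cand_events:
            c = counts_for(cev.ev_type)
            c.n_pred += 1
            if any(
                event_equal(rev, cev, mode, ref_doc, cand_doc)
                for rev in ref_events
            ):
                c.tp_pred += 1
    return report
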