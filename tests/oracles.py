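"""Independent brute-force reference implementations used only by tests.

These deliberately re-derive span matching, recursive event equality, the
existential precision/recall counts and the voting sweep from first
principles — character scanning instead of regexes, full permutation search
instead of role-grouped backtracking — so they share no code path with the
package under test.
"""

from __future__ import annotations

import itertools

from bioevents.model import DocAnnotations, Event, TextBound, role_base


def oracle_tokens(text: str) -> list[tuple[int, int]]:
    """Alphanumeric word spans via explicit character scanning."""
    spans: list[tuple[int, int]] = []
    cur = None
    for i, ch in enumerate(text):
        if ch.isascii() and ch.isalnum():
            if cur is None:
                cur = i
        elif cur is not None:
            spans.append((cur, i))
            cur = None
    if cur is not None:
        spans.append((cur, len(text)))
    return spans


def oracle_window(text: str, start: int, end: int) -> tuple[int, int]:
    """One-word extension window, rebuilt by scanning the token list twice."""
    toks = oracle_tokens(text)
    left = [s for s, e in toks if e <= start]
    right = [e for s, e in toks if s >= end]
    return (left[-1] if left else 0, right[0] if right else len(text))


def oracle_span_match(ref: TextBound, cand: TextBound, strict: bool,
                      text: str) -> bool:
    if ref.ann_type != cand.ann_type:
        return False
    if (ref.start, ref.end) == (cand.start, cand.end):
        return True
    if strict:
        return False
    lo, hi = oracle_window(text, ref.start, ref.end)
    return lo <= cand.start and cand.end <= hi


def oracle_event_equal(ref: Event, cand: Event, ref_doc: DocAnnotations,
                       cand_doc: DocAnnotations, strict: bool,
                       nested: bool = False,
                       scored_roles: frozenset = frozenset({"Theme", "Cause"}),
                       ) -> bool:
    """Recursive equality by exhaustive permutation search over arguments."""
    if ref.ev_type != cand.ev_type:
        return False
    if not oracle_span_match(ref_doc.trigger_of(ref), cand_doc.trigger_of(cand),
                             strict, ref_doc.text):
        return False
    scored = frozenset({"Theme"}) if (nested and not strict) else scored_roles
    rargs = [(role_base(r), ref_doc.resolve(t))
             for r, t in ref.args if role_base(r) in scored]
    cargs = [(role_base(r), cand_doc.resolve(t))
             for r, t in cand.args if role_base(r) in scored]
    if len(rargs) != len(cargs):
        return False
    for perm in itertools.permutations(range(len(cargs))):
        ok = True
        for (r_role, r_obj), idx in zip(rargs, perm):
            c_role, c_obj = cargs[idx]
            if r_role != c_role:
                ok = False
            elif isinstance(r_obj, Event) and isinstance(c_obj, Event):
                ok = oracle_event_equal(r_obj, c_obj, ref_doc, cand_doc,
                                        strict, nested=True,
                                        scored_roles=scored_roles)
            elif isinstance(r_obj, TextBound) and isinstance(c_obj, TextBound):
                ok = oracle_span_match(r_obj, c_obj, strict, ref_doc.text)
            else:
                ok = False
            if not ok:
                break
        if ok:
            return True
    return False


def oracle_counts(gold, system, strict: bool) -> dict[str, list[int]]:
    """Per-type [n_gold, n_pred, tp_gold, tp_pred] by all-pairs comparison."""
    counts: dict[str, list[int]] = {}

    def c(t: str) -> list[int]:
        return counts.setdefault(t, [0, 0, 0, 0])

    for doc_id in sorted(gold.docs):
        gdoc, sdoc = gold.docs[doc_id], system.docs[doc_id]
        gevs = [gdoc.events[i] for i in sorted(gdoc.events)]
        sevs = [sdoc.events[i] for i in sorted(sdoc.events)]
        for ge in gevs:
            c(ge.ev_type)[0] += 1
            if any(oracle_event_equal(ge, se, gdoc, sdoc, strict) for se in sevs):
                c(ge.ev_type)[2] += 1
        for se in sevs:
            c(se.ev_type)[1] += 1
            if any(oracle_event_equal(ge, se, gdoc, sdoc, strict) for ge in gevs):
                c(se.ev_type)[3] += 1
    return counts


def oracle_prf(counts: dict[str, list[int]]) -> tuple[float, float, float]:
    n_gold = sum(v[0] for v in counts.values())
    n_pred = sum(v[1] for v in counts.values())
    tp_gold = sum(v[2] for v in counts.values())
    tp_pred = sum(v[3] for v in counts.values())
    p = 100.0 * tp_pred / n_pred if n_pred else 0.0
    r = 100.0 * tp_gold / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f


def oracle_sweep(gold, systems, strict: bool = False
                 ) -> list[tuple[float, float, float, float]]:
    """Hand enumeration of the sum_i(b_i) > threshold voting rule.

    Candidates are pooled per document in (source order, event id) order; a
    candidate's b_i is 1 iff system i holds an equal event; accepted
    candidates are deduplicated greedily against those already accepted.
    The surviving instances are then scored against gold existentially.
    Assumes fixtures without nested events (no forced sub-event emission).
    """
    rows = []
    for threshold in range(len(systems)):
        accepted: dict[str, list[tuple[Event, DocAnnotations]]] = {}
        for doc_id in sorted(gold.docs):
            acc: list[tuple[Event, DocAnnotations]] = []
            for aset in systems:
                sdoc = aset.docs[doc_id]
                for ev_id in sorted(sdoc.events):
                    ev = sdoc.events[ev_id]
                    score = sum(
                        int(any(
                            oracle_event_equal(ev, other, sdoc, o.docs[doc_id],
                                               strict)
                            for other in o.docs[doc_id].events.values()))
                        for o in systems
                    )
                    if score > threshold and not any(
                        oracle_event_equal(ev, prev, sdoc, pdoc, strict)
                        for prev, pdoc in acc
                    ):
                        acc.append((ev, sdoc))
            accepted[doc_id] = acc

        n_gold = n_pred = tp_gold = tp_pred = 0
        for doc_id in sorted(gold.docs):
            gdoc = gold.docs[doc_id]
            gevs = list(gdoc.events.values())
            acc = accepted[doc_id]
            n_gold += len(gevs)
            n_pred += len(acc)
            for ge in gevs:
                if any(oracle_event_equal(ge, ev, gdoc, sdoc, strict)
                       for ev, sdoc in acc):
                    tp_gold += 1
            for ev, sdoc in acc:
                if any(oracle_event_equal(ge, ev, gdoc, sdoc, strict)
                       for ge in gevs):
                    tp_pred += 1
        p = 100.0 * tp_pred / n_pred if n_pred else 0.0
        r = 100.0 * tp_gold / n_gold if n_gold else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        rows.append((float(threshold), p, r, f))
    return rows
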