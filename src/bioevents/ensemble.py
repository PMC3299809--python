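"""Majority-vote ensembling of event extraction outputs.

Every event instance produced by any included system is a candidate.  For a
candidate ``c`` and system ``i``, the support bit is ``b_i = 1`` iff an event
equal to ``c`` (under the configured match mode) exists in system ``i``'s
output, and the candidate is accepted iff

    sum_i  w_i * b_i  >  threshold

with strict inequality, unit weights by default (the averaged ensemble).
Accepted candidates are deduplicated greedily in deterministic order (document
id, source rank, event id): a candidate equal to an already-emitted consensus
event is dropped.  Approximate equality is not transitive, so votes are
computed per candidate rather than per equivalence class.

Because a regulation event's argument may itself be an event that was not
accepted on its own, emission copies the representative instance's full
sub-event closure so that the consensus remains a valid, serialisable
annotation set; force-emitted sub-events are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .evaluation import Ranking
from .matching import APPROX_MODE, MatchMode, compute_metrics, f1
from .model import AnnotationSet, DocAnnotations, Event, TextBound

logger = logging.getLogger("bioevents.ensemble")


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class EnsembleConfig:
    """Voting configuration.

    ``weights`` maps source id to a non-negative vote weight; ``None`` means
    unit weights for all systems.  Acceptance is strictly ``score >
    threshold``: with K unit-weight systems the meaningful thresholds are the
    integers 0..K-1 (K or more accepts nothing).
    """

    mode: MatchMode = APPROX_MODE
    weights: dict[str, float] | None = None
    threshold: float = 0.0

    def weight(self, source_id: str) -> float:
        if self.weights is None:
            return 1.0
        try:
            w = self.weights[source_id]
        except KeyError:
            raise EnsembleError(f"no weight for source {source_id!r}") from None
        if w < 0:
            raise EnsembleError(f"negative weight for {source_id!r}: {w}")
        return w


@dataclass
class VoteRecord:
    """A candidate event with its per-system support vector and score."""

    doc_id: str
    source_id: str
    source_rank: int
    ev_id: str
    event: Event
    doc: DocAnnotations
    support: dict[str, int] = field(default_factory=dict)
    score: float = 0.0


def pool_candidates(systems: list[AnnotationSet]) -> list[VoteRecord]:
    """One candidate per event instance across all systems, in deterministic
    order: document id, then source rank (list order), then event id."""
    if not systems:
        raise EnsembleError("no systems to pool")
    records: list[VoteRecord] = []
    doc_ids = systems[0].doc_ids()
    for aset in systems[1:]:
        if aset.doc_ids() != doc_ids:
            raise EnsembleError(
                f"document ID mismatch between {systems[0].source_id!r} and "
                f"{aset.source_id!r}"
            )
    for doc_id in doc_ids:
        for rank, aset in enumerate(systems):
            doc = aset.docs[doc_id]
            for ev_id in sorted(doc.events):
                records.append(
                    VoteRecord(doc_id, aset.source_id, rank, ev_id,
                               doc.events[ev_id], doc)
                )
    return records


def vote(
    candidates: list[VoteRecord],
    systems: list[AnnotationSet],
    config: EnsembleConfig,
) -> list[VoteRecord]:
    """Fill in each candidate's support vector and weighted score."""
    from .matching import event_equal

    for rec in candidates:
        rec.support = {}
        rec.score = 0.0
        for aset in systems:
            sys_doc = aset.docs[rec.doc_id]
            if aset.source_id == rec.source_id:
                b = 1  # a candidate always matches its own source
            else:
                b = int(
                    any(
                        event_equal(rec.event, ev, config.mode, rec.doc, sys_doc)
                        for ev in sys_doc.events.values()
                    )
                )
            rec.support[aset.source_id] = b
            rec.score += config.weight(aset.source_id) * b
    return candidates


def build_consensus(
    voted: list[VoteRecord],
    config: EnsembleConfig,
    source_id: str = "ensemble",
) -> AnnotationSet:
    """Accept candidates with ``score > threshold``, deduplicate, emit.

    Candidates are scanned in their pooled (deterministic) order, so the
    representative of a group of mutually equal candidates is the instance
    from the highest-ranked system.  Emission copies the representative's
    triggers and protein arguments; sub-events needed by an accepted parent
    are force-emitted even when rejected on their own score.
    """
    from .matching import event_equal

    consensus = AnnotationSet(source_id=source_id)
    by_doc: dict[str, list[VoteRecord]] = {}
    for rec in voted:
        by_doc.setdefault(rec.doc_id, []).append(rec)

    for doc_id, records in by_doc.items():
        out = DocAnnotations(doc_id, records[0].doc.text,
                             proteins=dict(records[0].doc.proteins))
        emitted: list[Event] = []
        counter = {"t": 0, "e": 0}
        # (source_id, original ev_id) -> consensus ev_id, for sub-event reuse
        id_map: dict[tuple[str, str], str] = {}

        def emit(rec_source: str, ev: Event, src_doc: DocAnnotations) -> str:
            key = (rec_source, ev.ev_id)
            if key in id_map:
                return id_map[key]
            args: list[tuple[str, str]] = []
            for role, target in ev.args:
                obj = src_doc.resolve(target)
                if isinstance(obj, Event):
                    sub_id = emit(rec_source, obj, src_doc)
                    args.append((role, sub_id))
                else:
                    if target in src_doc.proteins:
                        args.append((role, target))
                    else:  # Entity-typed span from the source's own a2
                        args.append((role, copy_tb(obj)))
            trig = src_doc.trigger_of(ev)
            counter["e"] += 1
            new_id = f"E{counter['e']}"
            out.events[new_id] = Event(new_id, ev.ev_type, copy_tb(trig),
                                       tuple(args))
            id_map[key] = new_id
            emitted.append(out.events[new_id])
            return new_id

        def copy_tb(tb: TextBound) -> str:
            counter["t"] += 1
            new_id = f"TX{counter['t']}"
            out.triggers[new_id] = TextBound(
                new_id, tb.ann_type, tb.start, tb.end, tb.surface
            )
            return new_id

        for rec in records:
            if rec.score <= config.threshold:
                continue
            if (rec.source_id, rec.ev_id) in id_map:
                continue  # already force-emitted as someone's sub-event
            if any(
                event_equal(rec.event, prev, config.mode, rec.doc, out)
                for prev in emitted
            ):
                continue
            before = len(out.events)
            emit(rec.source_id, rec.event, rec.doc)
            if len(out.events) - before > 1:
                logger.info(
                    "%s: force-emitted %d sub-event(s) of %s/%s",
                    doc_id, len(out.events) - before - 1, rec.source_id,
                    rec.ev_id,
                )
        consensus.docs[doc_id] = out
    return consensus


@dataclass
class SweepResult:
    """Threshold sweep rows (threshold, precision, recall, F1 — percentages)
    and the best row by F1, ties resolved toward the lowest threshold."""

    rows: list[tuple[float, float, float, float]]

    @property
    def best(self) -> tuple[float, float, float, float]:
        return max(self.rows, key=lambda r: (r[3], -r[0]))


def threshold_grid(
    voted: list[VoteRecord], systems: list[AnnotationSet], config: EnsembleConfig
) -> list[float]:
    """Thresholds worth evaluating: integers 0..K-1 under unit weights, else
    0 plus the sorted distinct achievable scores (any other grid would only
    repeat consensus sets)."""
    if config.weights is None:
        return [float(t) for t in range(len(systems))]
    return sorted({0.0} | {rec.score for rec in voted})


def sweep_thresholds(
    gold: AnnotationSet,
    systems: list[AnnotationSet],
    config: EnsembleConfig = EnsembleConfig(),
) -> SweepResult:
    """Evaluate the consensus against gold across the threshold grid.

    Votes are computed once; only acceptance changes with the threshold.
    Recall is non-increasing in the threshold (accepted sets shrink).
    """
    if not systems:
        raise EnsembleError("no systems to ensemble")
    candidates = pool_candidates(systems)
    voted = vote(candidates, systems, config)
    rows = []
    for threshold in threshold_grid(voted, systems, config):
        cfg = EnsembleConfig(config.mode, config.weights, threshold)
        consensus = build_consensus(voted, cfg)
        report = compute_metrics(gold, consensus, config.mode)
        tot = report.total
        rows.append((threshold, tot.precision, tot.recall,
                     f1(tot.precision, tot.recall)))
    return SweepResult(rows=rows)


def top_n_ensemble(
    gold: AnnotationSet,
    systems: list[AnnotationSet],
    ranking: Ranking,
    ns: list[int] | None = None,
    config: EnsembleConfig = EnsembleConfig(),
) -> list[tuple[int, float, float, float, float]]:
    """Best sweep row per ensemble size n.

    For each n, voting is restricted to the n systems ranked highest against
    gold; returns rows ``(n, best threshold, precision, recall, F1)``.
    """
    by_id = {s.source_id: s for s in systems}
    if ns is None:
        ns = list(range(2, len(systems) + 1))
    rows = []
    for n in ns:
        if not (2 <= n <= len(systems)):
            raise EnsembleError(f"top-n out of range: {n}")
        subset = [by_id[s] for s in ranking.top(n)]
        sweep = sweep_thresholds(gold, subset, config)
        thr, p, r, f = sweep.best
        rows.append((n, thr, p, r, f))
    return rows


def render_sweep_tsv(sweep: SweepResult) -> str:
    from .matching import round2

    lines = ["threshold\tF1\tPR\tRC"]
    for thr, p, r, f in sweep.rows:
        lines.append(
            f"{thr:g}\t{round2(f):.2f}\t{round2(p):.2f}\t{round2(r):.2f}"
        )
    return "".join(line + "\n" for line in lines)


def render_top_n_tsv(rows: list[tuple[int, float, float, float, float]]) -> str:
    """Table in the classic ensemble-report layout: one row per n."""
    from .matching import round2

    lines = ["Ensemble\tF1\tPR\tRC"]
    for n, _thr, p, r, f in rows:
        lines.append(f"Top {n}\t{round2(f):.2f}\t{round2(p):.2f}\t{round2(r):.2f}")
    return "".join(line + "\n" for line in lines)
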