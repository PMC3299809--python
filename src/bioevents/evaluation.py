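"""All-pairs comparison of annotation sets and F1 ranking.

Comparing a system against the gold reader is an evaluation; comparing two
systems quantifies their similarity.  The full matrix over N sources holds a
:class:`~bioevents.matching.MetricReport` for every ordered pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .matching import APPROX_MODE, MatchMode, MetricReport, compute_metrics, round2
from .model import EVENT_TYPES, AnnotationSet


class EvaluationError(ValueError):
    pass


@dataclass
class ComparisonMatrix:
    sources: list[str]
    mode: MatchMode
    cells: dict[tuple[str, str], MetricReport] = field(default_factory=dict)

    def cell(self, reference_id: str, candidate_id: str) -> MetricReport:
        try:
            return self.cells[(reference_id, candidate_id)]
        except KeyError:
            raise EvaluationError(
                f"no cell for ({reference_id}, {candidate_id})"
            ) from None


@dataclass
class Ranking:
    """Sources ordered by total F1 against gold, best first (rank 1)."""

    entries: list[tuple[str, float]]

    def sources(self) -> list[str]:
        return [s for s, _ in self.entries]

    def top(self, n: int) -> list[str]:
        if not (1 <= n <= len(self.entries)):
            raise EvaluationError(f"top-n out of range: {n}")
        return self.sources()[:n]


def pairwise_compare(
    sets: list[AnnotationSet],
    mode: MatchMode = APPROX_MODE,
    include_diagonal: bool = False,
) -> ComparisonMatrix:
    """Compute metric reports for every ordered pair of sets.

    Diagonal cells are skipped by default (they are all-100 by construction)
    but can be computed as a sanity check.
    """
    if len(sets) < 2:
        raise EvaluationError("pairwise comparison needs at least 2 sets")
    ids = [s.source_id for s in sets]
    if len(set(ids)) != len(ids):
        raise EvaluationError(f"duplicate source ids: {ids}")
    matrix = ComparisonMatrix(sources=ids, mode=mode)
    for a in sets:
        for b in sets:
            if a.source_id == b.source_id and not include_diagonal:
                continue
            matrix.cells[(a.source_id, b.source_id)] = compute_metrics(a, b, mode)
    return matrix


def rank_by_f1(matrix: ComparisonMatrix, gold_id: str) -> Ranking:
    """Rank the non-gold sources by micro-averaged total F1 against gold.

    Ties are broken by source id, lexicographically.
    """
    if gold_id not in matrix.sources:
        raise EvaluationError(f"gold source {gold_id!r} not in matrix")
    scores = []
    for source in matrix.sources:
        if source == gold_id:
            continue
        report = matrix.cell(gold_id, source)
        scores.append((source, report.total.f1))
    scores.sort(key=lambda item: (-item[1], item[0]))
    return Ranking(entries=scores)


# ---------------------------------------------------------------------------
# Rendering

_ROW_KINDS = (("F1", "f1"), ("PR", "precision"), ("RC", "recall"))


def render_evaluation_table(
    matrix: ComparisonMatrix, gold_id: str, ranking: Ranking | None = None
) -> str:
    """Tab-separated evaluation report, one column per system.

    Layout mirrors the classic shared-task summary: a Total block with F1,
    precision (PR) and recall (RC) rows, then one block per event type, with
    systems ordered by rank.
    """
    if ranking is None:
        ranking = rank_by_f1(matrix, gold_id)
    order = ranking.sources()
    reports = {s: matrix.cell(gold_id, s) for s in order}
    lines = ["\t".join(["Type", "Metric"] + order)]
    lines.append(
        "\t".join(["Rank", "#"] + [str(i + 1) for i in range(len(order))])
    )
    for label, attr in _ROW_KINDS:
        row = [f"{round2(getattr(reports[s].total, attr)):.2f}" for s in order]
        lines.append("\t".join(["Total", label] + row))
    for ev_type in EVENT_TYPES:
        if not any(ev_type in reports[s].per_type for s in order):
            continue
        for label, attr in _ROW_KINDS:
            row = []
            for s in order:
                counts = reports[s].per_type.get(ev_type)
                row.append(
                    f"{round2(getattr(counts, attr)):.2f}" if counts else "-"
                )
            lines.append("\t".join([ev_type, label] + row))
    return "".join(line + "\n" for line in lines)


def render_matrix_tsv(matrix: ComparisonMatrix) -> str:
    """Total-F1 grid over all ordered pairs (reference rows, candidate cols)."""
    lines = ["\t".join(["reference\\candidate"] + matrix.sources)]
    for a in matrix.sources:
        row = [a]
        for b in matrix.sources:
            cell = matrix.cells.get((a, b))
            row.append(f"{round2(cell.total.f1):.2f}" if cell else "-")
        lines.append("\t".join(row))
    return "".join(line + "\n" for line in lines)
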