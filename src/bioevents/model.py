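"""In-memory data model for BioNLP shared-task style event annotations.

The model mirrors the standoff file layout: a document's raw text lives in a
:class:`Document`, protein mentions come from the ``.a1`` file, and each
annotation source (the gold standard or one extraction system) contributes one
``.a2`` fragment per document holding event triggers, events, modifications
and Equiv groups.  Events form a DAG: regulation-family events may take other
events as Theme/Cause arguments.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Union

#: The nine core event types of the BioNLP'09 shared task.
EVENT_TYPES: tuple[str, ...] = (
    "Gene_expression",
    "Transcription",
    "Protein_catabolism",
    "Phosphorylation",
    "Localization",
    "Binding",
    "Regulation",
    "Positive_regulation",
    "Negative_regulation",
)

#: Event types whose Theme (and Cause) may itself be an event.
REGULATION_TYPES: frozenset[str] = frozenset(
    {"Regulation", "Positive_regulation", "Negative_regulation"}
)

#: Argument roles understood by the parser.  Numbered variants (Theme2,
#: Site3, ...) are accepted and normalised via :func:`role_base`.
KNOWN_ROLES: frozenset[str] = frozenset(
    {"Theme", "Cause", "Site", "CSite", "AtLoc", "ToLoc"}
)

_ROLE_RE = re.compile(r"^([A-Za-z]+?)\d*$")


def role_base(role: str) -> str:
    """Strip the numbering suffix from a role label (``Theme2`` -> ``Theme``)."""
    m = _ROLE_RE.match(role)
    return m.group(1) if m else role


class AnnotationError(ValueError):
    """Malformed, unresolvable or grammar-violating annotation input."""


@dataclass(frozen=True)
class Document:
    doc_id: str
    text: str


@dataclass(frozen=True)
class TextBound:
    """A typed character span: a protein mention or an event trigger.

    Offsets are 0-based, half-open; ``surface`` always equals
    ``text[start:end]`` of the owning document.
    """

    tb_id: str
    ann_type: str
    start: int
    end: int
    surface: str

    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class Event:
    """A typed event anchored at a trigger with role-labelled arguments.

    ``args`` holds ``(role, target_id)`` pairs; a target id is either a
    T-prefixed id (protein or trigger text-bound) or an E-prefixed id of
    another event in the same document fragment.
    """

    ev_id: str
    ev_type: str
    trigger_id: str
    args: tuple[tuple[str, str], ...]

    def themes(self) -> tuple[str, ...]:
        return tuple(t for r, t in self.args if role_base(r) == "Theme")


@dataclass(frozen=True)
class Modification:
    """Negation/Speculation marker on an event; preserved but never scored."""

    mod_id: str
    mod_type: str  # Negation | Speculation
    target_id: str


Target = Union[TextBound, Event]


@dataclass
class DocAnnotations:
    """One source's annotations over one document.

    ``proteins`` holds the shared ``.a1`` text-bounds; ``triggers`` the
    source's own ``.a2`` ``T`` lines.  Reference resolution looks T ids up in
    both (``.a2`` trigger ids never clash with ``.a1`` ids in valid input).
    """

    doc_id: str
    text: str
    proteins: dict[str, TextBound] = field(default_factory=dict)
    triggers: dict[str, TextBound] = field(default_factory=dict)
    events: dict[str, Event] = field(default_factory=dict)
    modifications: dict[str, Modification] = field(default_factory=dict)
    equiv_groups: list[frozenset[str]] = field(default_factory=list)

    def resolve(self, ref_id: str) -> Target:
        if ref_id in self.events:
            return self.events[ref_id]
        if ref_id in self.triggers:
            return self.triggers[ref_id]
        if ref_id in self.proteins:
            return self.proteins[ref_id]
        raise AnnotationError(f"{self.doc_id}: dangling reference {ref_id!r}")

    def trigger_of(self, event: Event) -> TextBound:
        tb = self.triggers.get(event.trigger_id) or self.proteins.get(event.trigger_id)
        if tb is None:
            raise AnnotationError(
                f"{self.doc_id}: event {event.ev_id} has dangling trigger "
                f"{event.trigger_id!r}"
            )
        return tb

    def equiv_members(self, tb: TextBound) -> tuple[TextBound, ...]:
        """All text-bounds declared interchangeable with ``tb`` (incl. itself)."""
        for group in self.equiv_groups:
            if tb.tb_id in group:
                return tuple(self.proteins[m] for m in sorted(group))
        return (tb,)

    def topological_events(self) -> list[Event]:
        """Events ordered children-before-parents (argument DAG order)."""
        order: list[Event] = []
        seen: set[str] = set()

        def visit(ev: Event) -> None:
            if ev.ev_id in seen:
                return
            seen.add(ev.ev_id)
            for _, target in ev.args:
                if target in self.events:
                    visit(self.events[target])
            order.append(ev)

        for ev_id in sorted(self.events):
            visit(self.events[ev_id])
        return order

    def validate(self) -> None:
        """Check span/reference/grammar invariants; raise AnnotationError."""
        n = len(self.text)
        for tb in list(self.proteins.values()) + list(self.triggers.values()):
            if not (0 <= tb.start < tb.end <= n):
                raise AnnotationError(
                    f"{self.doc_id}: {tb.tb_id} span {tb.span()} outside text"
                )
            if self.text[tb.start : tb.end] != tb.surface:
                raise AnnotationError(
                    f"{self.doc_id}: {tb.tb_id} surface {tb.surface!r} != "
                    f"text slice {self.text[tb.start:tb.end]!r}"
                )
        _check_acyclic(self)
        for ev in self.events.values():
            trig = self.trigger_of(ev)
            if trig.ann_type != ev.ev_type:
                raise AnnotationError(
                    f"{self.doc_id}: {ev.ev_id} type {ev.ev_type} != trigger "
                    f"type {trig.ann_type}"
                )
            if not ev.themes():
                raise AnnotationError(
                    f"{self.doc_id}: {ev.ev_id} has no Theme argument"
                )
            for role, target in ev.args:
                obj = self.resolve(target)
                if (
                    isinstance(obj, Event)
                    and role_base(role) in ("Theme", "Cause")
                    and ev.ev_type not in REGULATION_TYPES
                ):
                    raise AnnotationError(
                        f"{self.doc_id}: non-regulation event {ev.ev_id} takes "
                        f"event argument {target}"
                    )
        for mod in self.modifications.values():
            if mod.target_id not in self.events:
                raise AnnotationError(
                    f"{self.doc_id}: modification {mod.mod_id} targets unknown "
                    f"event {mod.target_id!r}"
                )
        for group in self.equiv_groups:
            if len(group) < 2:
                raise AnnotationError(f"{self.doc_id}: Equiv group of size < 2")
            for m in group:
                if m not in self.proteins:
                    raise AnnotationError(
                        f"{self.doc_id}: Equiv member {m!r} is not a protein"
                    )


def _check_acyclic(doc: DocAnnotations) -> None:
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {ev_id: WHITE for ev_id in doc.events}

    def visit(ev_id: str) -> None:
        colour[ev_id] = GREY
        for _, target in doc.events[ev_id].args:
            if target in doc.events:
                if colour[target] == GREY:
                    raise AnnotationError(
                        f"{doc.doc_id}: cycle through event {target}"
                    )
                if colour[target] == WHITE:
                    visit(target)
        colour[ev_id] = BLACK

    for ev_id in doc.events:
        if colour[ev_id] == WHITE:
            visit(ev_id)


@dataclass
class AnnotationSet:
    """All annotations of one source (gold or one system) over a corpus."""

    source_id: str
    docs: dict[str, DocAnnotations] = field(default_factory=dict)

    def doc_ids(self) -> list[str]:
        return sorted(self.docs)

    def n_events(self) -> int:
        return sum(len(d.events) for d in self.docs.values())

    def iter_events(self) -> Iterator[tuple[DocAnnotations, Event]]:
        for doc_id in self.doc_ids():
            doc = self.docs[doc_id]
            for ev_id in sorted(doc.events):
                yield doc, doc.events[ev_id]

    def validate(self) -> None:
        for doc in self.docs.values():
            doc.validate()


@dataclass
class Corpus:
    """Documents plus shared protein annotations; sources attach a2 fragments."""

    documents: dict[str, Document] = field(default_factory=dict)
    proteins: dict[str, dict[str, TextBound]] = field(default_factory=dict)

    def doc_ids(self) -> list[str]:
        return sorted(self.documents)


# ---------------------------------------------------------------------------
# Structural (id-independent) equality, used by round-trip tests and docs.

def canonical_event(doc: DocAnnotations, ev: Event) -> tuple:
    """Canonical nested representation of an event, independent of ids."""
    trig = doc.trigger_of(ev)
    args = []
    for role, target in ev.args:
        obj = doc.resolve(target)
        if isinstance(obj, Event):
            args.append((role_base(role), canonical_event(doc, obj)))
        else:
            args.append((role_base(role), (obj.ann_type, obj.start, obj.end)))
    return (ev.ev_type, trig.span(), tuple(sorted(args, key=repr)))


def canonical_doc(doc: DocAnnotations) -> tuple:
    """Canonical multiset form of a document fragment (events, mods, equivs)."""
    events = sorted(canonical_event(doc, ev) for ev in doc.events.values())
    mods = sorted(
        (m.mod_type, canonical_event(doc, doc.events[m.target_id]))
        for m in doc.modifications.values()
    )
    equivs = sorted(
        tuple(sorted(doc.proteins[m].span() for m in g)) for g in doc.equiv_groups
    )
    return (tuple(events), tuple(mods), tuple(equivs))


def annotation_equal(a: AnnotationSet, b: AnnotationSet) -> bool:
    """True iff the two sets carry the same annotations up to id renaming."""
    if a.doc_ids() != b.doc_ids():
        return False
    return all(
        canonical_doc(a.docs[d]) == canonical_doc(b.docs[d]) for d in a.doc_ids()
    )
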