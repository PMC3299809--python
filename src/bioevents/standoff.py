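"""Reading and writing BioNLP shared-task standoff files (txt / a1 / a2).

File grammar (tab-separated, newline-terminated):

* ``.a1`` — ``T`` lines only: ``T1<TAB>Protein 0 4<TAB>TP53``
* ``.a2`` — ``T`` lines (event triggers / Entity spans), ``E`` lines
  (``E1<TAB>Binding:T3 Theme:T1 Theme2:T2``), ``M`` lines
  (``M1<TAB>Negation E1``) and Equiv lines (``*<TAB>Equiv T1 T2``).

Offsets are 0-based half-open character offsets into the ``.txt`` file.
Writing is deterministic: triggers ordered by offset, events topologically
(children first), ids renumbered; ``parse(write(x))`` is annotation-equal to
``x`` and a second write reproduces the bytes exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

from .model import (
    AnnotationError,
    AnnotationSet,
    Corpus,
    DocAnnotations,
    Document,
    Event,
    EVENT_TYPES,
    KNOWN_ROLES,
    Modification,
    TextBound,
    canonical_event,
    role_base,
)

logger = logging.getLogger("bioevents.standoff")

#: Types accepted on a2 ``T`` lines: the nine event types plus the generic
#: ``Entity`` label used for Site/Loc argument spans.
TRIGGER_TYPES: frozenset[str] = frozenset(EVENT_TYPES) | {"Entity"}


def _parse_textbound(line: str, lineno: int, doc: Document) -> TextBound:
    parts = line.split("\t")
    if len(parts) != 3:
        raise AnnotationError(
            f"{doc.doc_id} line {lineno}: expected 3 tab-separated fields, "
            f"got {len(parts)}: {line!r}"
        )
    tb_id, type_span, surface = parts
    bits = type_span.split(" ")
    if len(bits) != 3:
        raise AnnotationError(
            f"{doc.doc_id} line {lineno}: bad type/span field {type_span!r}"
        )
    ann_type, s_start, s_end = bits
    try:
        start, end = int(s_start), int(s_end)
    except ValueError as exc:
        raise AnnotationError(
            f"{doc.doc_id} line {lineno}: non-integer offsets in {type_span!r}"
        ) from exc
    if not (0 <= start < end <= len(doc.text)):
        raise AnnotationError(
            f"{doc.doc_id} line {lineno}: span [{start},{end}) outside text "
            f"of length {len(doc.text)}"
        )
    if doc.text[start:end] != surface:
        raise AnnotationError(
            f"{doc.doc_id} line {lineno}: surface {surface!r} does not match "
            f"text slice {doc.text[start:end]!r}"
        )
    return TextBound(tb_id, ann_type, start, end, surface)


def parse_a1(document: Document, a1_content: str) -> dict[str, TextBound]:
    """Parse ``.a1`` content into protein text-bounds keyed by id."""
    proteins: dict[str, TextBound] = {}
    for lineno, line in enumerate(a1_content.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith("T"):
            raise AnnotationError(
                f"{document.doc_id} a1 line {lineno}: unexpected record {line!r}"
            )
        tb = _parse_textbound(line, lineno, document)
        if tb.tb_id in proteins:
            raise AnnotationError(
                f"{document.doc_id} a1 line {lineno}: duplicate id {tb.tb_id}"
            )
        proteins[tb.tb_id] = tb
    return proteins


def parse_a2(
    document: Document,
    a2_content: str,
    proteins: dict[str, TextBound],
    lenient: bool = False,
) -> DocAnnotations:
    """Parse ``.a2`` content against its sibling ``.a1`` proteins.

    With ``lenient=True``, records with unknown event types or roles are
    dropped with a warning (and events left dangling by a drop are dropped in
    cascade); otherwise they raise :class:`AnnotationError`.
    """
    doc = DocAnnotations(document.doc_id, document.text, proteins=dict(proteins))
    for lineno, line in enumerate(a2_content.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith("T"):
            tb = _parse_textbound(line, lineno, document)
            if tb.ann_type not in TRIGGER_TYPES:
                if lenient:
                    logger.warning(
                        "%s a2 line %d: dropping unknown trigger type %r",
                        document.doc_id, lineno, tb.ann_type,
                    )
                    continue
                raise AnnotationError(
                    f"{document.doc_id} a2 line {lineno}: unknown trigger type "
                    f"{tb.ann_type!r}"
                )
            if tb.tb_id in doc.triggers or tb.tb_id in doc.proteins:
                raise AnnotationError(
                    f"{document.doc_id} a2 line {lineno}: duplicate id {tb.tb_id}"
                )
            doc.triggers[tb.tb_id] = tb
        elif line.startswith("E"):
            ev = _parse_event(line, lineno, document, lenient)
            if ev is None:
                continue
            if ev.ev_id in doc.events:
                raise AnnotationError(
                    f"{document.doc_id} a2 line {lineno}: duplicate id {ev.ev_id}"
                )
            doc.events[ev.ev_id] = ev
        elif line.startswith("M"):
            parts = line.split("\t")
            if len(parts) != 2 or len(parts[1].split(" ")) != 2:
                raise AnnotationError(
                    f"{document.doc_id} a2 line {lineno}: bad M record {line!r}"
                )
            mod_type, target = parts[1].split(" ")
            if mod_type not in ("Negation", "Speculation"):
                raise AnnotationError(
                    f"{document.doc_id} a2 line {lineno}: unknown modification "
                    f"type {mod_type!r}"
                )
            doc.modifications[parts[0]] = Modification(parts[0], mod_type, target)
        elif line.startswith("*"):
            parts = line.split("\t")
            bits = parts[1].split(" ") if len(parts) == 2 else []
            if len(bits) < 3 or bits[0] != "Equiv":
                raise AnnotationError(
                    f"{document.doc_id} a2 line {lineno}: bad Equiv record {line!r}"
                )
            doc.equiv_groups.append(frozenset(bits[1:]))
        else:
            raise AnnotationError(
                f"{document.doc_id} a2 line {lineno}: unexpected record {line!r}"
            )
    if lenient:
        _drop_dangling(doc)
    doc.validate()
    return doc


def _parse_event(
    line: str, lineno: int, document: Document, lenient: bool
) -> Event | None:
    parts = line.split("\t")
    if len(parts) != 2:
        raise AnnotationError(
            f"{document.doc_id} a2 line {lineno}: expected 2 tab-separated "
            f"fields: {line!r}"
        )
    ev_id, body = parts
    bits = [b for b in body.split(" ") if b]
    head = bits[0].split(":")
    if len(head) != 2:
        raise AnnotationError(
            f"{document.doc_id} a2 line {lineno}: bad event head {bits[0]!r}"
        )
    ev_type, trigger_id = head
    if ev_type not in EVENT_TYPES:
        if lenient:
            logger.warning(
                "%s a2 line %d: dropping unknown event type %r",
                document.doc_id, lineno, ev_type,
            )
            return None
        raise AnnotationError(
            f"{document.doc_id} a2 line {lineno}: unknown event type {ev_type!r}"
        )
    args: list[tuple[str, str]] = []
    for bit in bits[1:]:
        pair = bit.split(":")
        if len(pair) != 2:
            raise AnnotationError(
                f"{document.doc_id} a2 line {lineno}: bad argument {bit!r}"
            )
        role, target = pair
        if role_base(role) not in KNOWN_ROLES:
            if lenient:
                logger.warning(
                    "%s a2 line %d: dropping unknown role %r",
                    document.doc_id, lineno, role,
                )
                continue
            raise AnnotationError(
                f"{document.doc_id} a2 line {lineno}: unknown role {role!r}"
            )
        args.append((role, target))
    return Event(ev_id, ev_type, trigger_id, tuple(args))


def _drop_dangling(doc: DocAnnotations) -> None:
    """Cascade-drop events whose references no longer resolve (lenient mode)."""
    changed = True
    while changed:
        changed = False
        known = set(doc.proteins) | set(doc.triggers) | set(doc.events)
        for ev_id, ev in list(doc.events.items()):
            refs = [ev.trigger_id] + [t for _, t in ev.args]
            if any(r not in known for r in refs) or not ev.themes():
                logger.warning("%s: dropping dangling event %s", doc.doc_id, ev_id)
                del doc.events[ev_id]
                changed = True
    known = set(doc.events)
    for mod_id, mod in list(doc.modifications.items()):
        if mod.target_id not in known:
            del doc.modifications[mod_id]


# ---------------------------------------------------------------------------
# Writing

def write_a1(proteins: dict[str, TextBound]) -> str:
    """Serialize ``.a1`` proteins, ordered by offset; ids are kept."""
    lines = []
    for tb in sorted(proteins.values(), key=lambda t: (t.start, t.end, t.tb_id)):
        lines.append(f"{tb.tb_id}\t{tb.ann_type} {tb.start} {tb.end}\t{tb.surface}")
    return "".join(line + "\n" for line in lines)


def _numeric_suffix(tb_id: str) -> int:
    try:
        return int(tb_id[1:])
    except ValueError:
        return 0


def write_a2(doc: DocAnnotations) -> str:
    """Serialize a ``.a2`` fragment deterministically.

    Trigger ids restart after the highest ``.a1`` id; triggers are ordered by
    offset, events topologically (children before parents, ties broken by
    trigger offset then structure), modifications and Equiv lines last.
    """
    doc.validate()
    next_t = max((_numeric_suffix(i) for i in doc.proteins), default=0) + 1
    trig_order = sorted(
        doc.triggers.values(), key=lambda t: (t.start, t.end, t.ann_type, t.tb_id)
    )
    t_map: dict[str, str] = {}
    lines: list[str] = []
    for tb in trig_order:
        t_map[tb.tb_id] = f"T{next_t}"
        lines.append(
            f"T{next_t}\t{tb.ann_type} {tb.start} {tb.end}\t{tb.surface}"
        )
        next_t += 1

    def ev_key(ev: Event) -> tuple:
        trig = doc.trigger_of(ev)
        return (trig.start, trig.end, ev.ev_type, repr(canonical_event(doc, ev)))

    # Kahn's algorithm with sorted tie-breaking: deterministic topological order.
    remaining = dict(doc.events)
    e_map: dict[str, str] = {}
    next_e = 1
    while remaining:
        ready = [
            ev
            for ev in remaining.values()
            if all(t not in remaining for _, t in ev.args)
        ]
        if not ready:
            raise AnnotationError(f"{doc.doc_id}: cycle among events")
        for ev in sorted(ready, key=ev_key):
            e_map[ev.ev_id] = f"E{next_e}"
            next_e += 1
            del remaining[ev.ev_id]
            body = [f"{ev.ev_type}:{t_map.get(ev.trigger_id, ev.trigger_id)}"]
            for role, target in ev.args:
                mapped = e_map.get(target) or t_map.get(target) or target
                body.append(f"{role}:{mapped}")
            lines.append(f"{e_map[ev.ev_id]}\t{' '.join(body)}")

    mods = sorted(
        doc.modifications.values(),
        key=lambda m: (m.mod_type, _numeric_suffix(e_map[m.target_id])),
    )
    for i, mod in enumerate(mods, start=1):
        lines.append(f"M{i}\t{mod.mod_type} {e_map[mod.target_id]}")

    equiv_lines = sorted(
        " ".join(sorted(g, key=_numeric_suffix)) for g in doc.equiv_groups
    )
    for members in equiv_lines:
        lines.append(f"*\tEquiv {members}")
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# Corpus-level I/O

def load_corpus(
    root: str | Path,
    sources: list[str],
    lenient: bool = False,
) -> tuple[Corpus, dict[str, AnnotationSet]]:
    """Load a corpus directory and the a2 annotations of the named sources.

    Layout: ``<root>/<docid>.txt`` and ``<root>/<docid>.a1`` for every
    document; ``<root>/<source>/<docid>.a2`` per source.  A missing ``.a2``
    means "no events extracted" for that document and is logged; a missing
    ``.txt`` or ``.a1`` is fatal.
    """
    root = Path(root)
    txt_files = sorted(root.glob("*.txt"))
    if not txt_files:
        raise FileNotFoundError(f"no .txt documents under {root}")
    corpus = Corpus()
    for txt in txt_files:
        doc_id = txt.stem
        a1 = root / f"{doc_id}.a1"
        if not a1.exists():
            raise FileNotFoundError(f"missing {a1}")
        document = Document(doc_id, txt.read_text(encoding="utf-8"))
        corpus.documents[doc_id] = document
        corpus.proteins[doc_id] = parse_a1(document, a1.read_text(encoding="utf-8"))

    sets: dict[str, AnnotationSet] = {}
    for source in sources:
        aset = AnnotationSet(source_id=source)
        src_dir = root / source
        if not src_dir.is_dir():
            raise FileNotFoundError(f"missing source directory {src_dir}")
        for doc_id, document in corpus.documents.items():
            a2 = src_dir / f"{doc_id}.a2"
            if a2.exists():
                content = a2.read_text(encoding="utf-8")
            else:
                logger.info("%s: no a2 for %s; treating as empty", source, doc_id)
                content = ""
            aset.docs[doc_id] = parse_a2(
                document, content, corpus.proteins[doc_id], lenient=lenient
            )
        sets[source] = aset
    return corpus, sets


def write_corpus(
    corpus: Corpus,
    sets: dict[str, AnnotationSet],
    root: str | Path,
) -> None:
    """Write txt/a1 files plus one ``<source>/<docid>.a2`` tree per set."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    for doc_id in corpus.doc_ids():
        (root / f"{doc_id}.txt").write_text(
            corpus.documents[doc_id].text, encoding="utf-8"
        )
        (root / f"{doc_id}.a1").write_text(
            write_a1(corpus.proteins[doc_id]), encoding="utf-8"
        )
    for source, aset in sets.items():
        src_dir = root / source
        src_dir.mkdir(parents=True, exist_ok=True)
        for doc_id in corpus.doc_ids():
            doc = aset.docs.get(doc_id)
            content = write_a2(doc) if doc is not None else ""
            (src_dir / f"{doc_id}.a2").write_text(content, encoding="utf-8")
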