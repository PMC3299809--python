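"""Synthetic corpora and simulated extractor outputs.

The generator emulates the shared-task setting at desk scale: documents of
template sentences over a pool of gene/protein symbols, a ``.a1``-style layer
of protein mentions, and a gold event layer drawn from the nine-type grammar,
with regulation-family events optionally nesting to a configurable depth.
Sentences are template-based on purpose — the evaluator never reads
semantics, only offsets and structure, so deterministic trigger words with
computable offsets are exactly what is needed.

``simulate_system`` then derives an imperfect "system" output from gold:
events are kept independently with the target recall (a parent whose Theme
event was dropped is dropped in cascade, mimicking error propagation through
regulatory-event pipelines), kept triggers are jittered within the one-word
approximate-match window with a configured probability, and spurious
grammar-valid events are added on decoy tokens to hit the target precision in
expectation.

Everything is driven by one random stream per spec, split per document by
counter, so identical specs give byte-identical corpora.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .matching import extension_window
from .model import (
    AnnotationSet,
    Corpus,
    DocAnnotations,
    Document,
    Event,
    EVENT_TYPES,
    REGULATION_TYPES,
    TextBound,
)


class ConfigError(ValueError):
    pass


#: Default event-type mix, loosely shaped like the GENIA event distribution:
#: expression and positive regulation dominate, catabolism is rare.
DEFAULT_MIX: dict[str, float] = {
    "Gene_expression": 0.22,
    "Binding": 0.13,
    "Phosphorylation": 0.10,
    "Transcription": 0.06,
    "Localization": 0.06,
    "Protein_catabolism": 0.03,
    "Regulation": 0.10,
    "Positive_regulation": 0.18,
    "Negative_regulation": 0.12,
}

_PROTEIN_POOL = (
    "TP53 MDM2 STAT3 AKT1 EGFR BRCA1 MYC JUN FOS NFKB1 IL2 TNF CDK2 RB1 "
    "PTEN GATA1 SPI1 RELA MAPK1 SRC SMAD4 NOTCH1 WNT1 GSK3B FOXO1"
).split()

#: Decoy word planted in every sentence, kept at least two tokens away from
#: any real trigger; spurious events anchor their triggers here.
DECOY_WORD = "human"

_VERB = {
    "Regulation": "regulates",
    "Positive_regulation": "activates",
    "Negative_regulation": "inhibits",
}
_NOUN = {
    "Regulation": "modulation",
    "Positive_regulation": "activation",
    "Negative_regulation": "inhibition",
    "Gene_expression": "expression",
    "Transcription": "transcription",
    "Protein_catabolism": "degradation",
    "Phosphorylation": "phosphorylation",
    "Localization": "localization",
    "Binding": "binding",
}


@dataclass(frozen=True)
class CorpusSpec:
    """Shape of a generated corpus; same spec and seed → byte-identical files."""

    n_docs: int = 20
    sentences_per_doc: int = 10
    proteins_per_sentence: int = 3
    event_type_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MIX)
    )
    nesting_prob: float = 0.4
    max_nesting_depth: int = 3
    seed: int = 0

    def validate(self) -> None:
        if self.n_docs < 0 or self.sentences_per_doc < 0:
            raise ConfigError("negative corpus dimensions")
        if self.proteins_per_sentence < 1 and self.sentences_per_doc:
            raise ConfigError("need at least one protein per sentence")
        if self.max_nesting_depth < 1:
            raise ConfigError("max_nesting_depth must be >= 1")
        total = sum(self.event_type_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"event_type_mix sums to {total}, not 1")
        unknown = set(self.event_type_mix) - set(EVENT_TYPES)
        if unknown:
            raise ConfigError(f"unknown event types in mix: {sorted(unknown)}")
        reg_mass = sum(
            self.event_type_mix.get(t, 0.0) for t in REGULATION_TYPES
        )
        if self.nesting_prob > 0 and reg_mass == 0:
            raise ConfigError(
                "nesting requested but the mix has no regulation-family mass"
            )


@dataclass(frozen=True)
class SystemSpec:
    """Error profile of a simulated extractor.

    ``target_recall`` is the per-event keep probability; ``target_precision``
    sets the spurious-event count as kept*(1-p)/p; ``span_jitter_prob`` is the
    chance a kept trigger span is extended within the one-word window (breaking
    strict but not approximate matching).
    """

    source_id: str
    target_recall: float = 0.8
    target_precision: float = 0.8
    span_jitter_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.target_recall <= 1.0):
            raise ConfigError(f"target_recall out of [0,1]: {self.target_recall}")
        if not (0.0 < self.target_precision <= 1.0):
            raise ConfigError(
                f"target_precision out of (0,1]: {self.target_precision}"
            )
        if not (0.0 <= self.span_jitter_prob <= 1.0):
            raise ConfigError(
                f"span_jitter_prob out of [0,1]: {self.span_jitter_prob}"
            )


class _SentenceBuilder:
    """Accumulates sentence text and annotation objects at document offsets."""

    def __init__(self, doc_offset: int, doc: DocAnnotations, a1: dict):
        self.parts: list[str] = []
        self.pos = doc_offset
        self.doc = doc
        self.a1 = a1

    def add(self, word: str) -> tuple[int, int]:
        if self.parts:
            self.parts.append(" ")
            self.pos += 1
        start = self.pos
        self.parts.append(word)
        self.pos += len(word)
        return start, self.pos

    def add_protein(self, name: str) -> str:
        start, end = self.add(name)
        tb_id = f"T{len(self.a1) + 1}"
        self.a1[tb_id] = TextBound(tb_id, "Protein", start, end, name)
        return tb_id

    def add_trigger(self, word: str, ev_type: str) -> str:
        start, end = self.add(word)
        tb_id = f"TR{len(self.doc.triggers) + 1}"
        self.doc.triggers[tb_id] = TextBound(tb_id, ev_type, start, end, word)
        return tb_id

    def add_event(self, ev_type: str, trigger_id: str,
                  args: list[tuple[str, str]]) -> str:
        ev_id = f"E{len(self.doc.events) + 1}"
        self.doc.events[ev_id] = Event(ev_id, ev_type, trigger_id, tuple(args))
        return ev_id

    def text(self) -> str:
        return "".join(self.parts)


def _pick_type(rng: random.Random, mix: dict[str, float],
               allowed: set[str] | None = None) -> str:
    items = [
        (t, w) for t, w in sorted(mix.items())
        if w > 0 and (allowed is None or t in allowed)
    ]
    total = sum(w for _, w in items)
    x = rng.random() * total
    for t, w in items:
        x -= w
        if x <= 0:
            return t
    return items[-1][0]


def _simple_clause(sb: _SentenceBuilder, rng: random.Random, ev_type: str,
                   proteins: list[str]) -> str:
    """Verb-form clause for a non-regulation event; returns the event id."""
    if ev_type == "Binding" and len(proteins) >= 2:
        p1, p2 = rng.sample(proteins, 2)
        t1 = sb.add_protein(p1)
        trig = sb.add_trigger("binds", "Binding")
        t2 = sb.add_protein(p2)
        return sb.add_event("Binding", trig, [("Theme", t1), ("Theme2", t2)])
    p = rng.choice(proteins)
    if ev_type == "Localization":
        t1 = sb.add_protein(p)
        trig = sb.add_trigger("localizes", ev_type)
        for w in ("to", "the", "nucleus"):
            sb.add(w)
    else:
        verb = {
            "Gene_expression": "expressed",
            "Transcription": "transcribed",
            "Protein_catabolism": "degraded",
            "Phosphorylation": "phosphorylated",
            "Binding": "bound",
        }[ev_type]
        t1 = sb.add_protein(p)
        sb.add("is")
        trig = sb.add_trigger(verb, ev_type)
    return sb.add_event(ev_type, trig, [("Theme", t1)])


def _noun_phrase(sb: _SentenceBuilder, rng: random.Random, ev_type: str,
                 proteins: list[str], spec: CorpusSpec, depth_left: int) -> str:
    """Noun-phrase form usable as a nested event Theme; returns the event id."""
    trig = sb.add_trigger(_NOUN[ev_type], ev_type)
    sb.add("of")
    if ev_type in REGULATION_TYPES and depth_left > 1 and (
        rng.random() < spec.nesting_prob
    ):
        sb.add("the")
        inner_type = _pick_type(rng, spec.event_type_mix)
        inner = _noun_phrase(sb, rng, inner_type, proteins, spec, depth_left - 1)
        return sb.add_event(ev_type, trig, [("Theme", inner)])
    if ev_type == "Binding" and len(proteins) >= 2:
        p1, p2 = rng.sample(proteins, 2)
        t1 = sb.add_protein(p1)
        sb.add("and")
        t2 = sb.add_protein(p2)
        return sb.add_event(ev_type, trig, [("Theme", t1), ("Theme2", t2)])
    t1 = sb.add_protein(rng.choice(proteins))
    return sb.add_event(ev_type, trig, [("Theme", t1)])


def _sentence(sb: _SentenceBuilder, rng: random.Random,
              spec: CorpusSpec) -> None:
    names = rng.sample(_PROTEIN_POOL, min(spec.proteins_per_sentence + 1,
                                          len(_PROTEIN_POOL)))
    proteins = names[: max(1, spec.proteins_per_sentence - 1)]
    sb.add("In")
    sb.add(DECOY_WORD)
    sb.add("cells")
    sb.add(",")
    ev_type = _pick_type(rng, spec.event_type_mix)
    if ev_type in REGULATION_TYPES:
        cause = sb.add_protein(names[-1])
        trig = sb.add_trigger(_VERB[ev_type], ev_type)
        if spec.max_nesting_depth > 1 and rng.random() < spec.nesting_prob:
            sb.add("the")
            inner_type = _pick_type(rng, spec.event_type_mix)
            theme = _noun_phrase(sb, rng, inner_type, proteins, spec,
                                 spec.max_nesting_depth - 1)
        else:
            theme = sb.add_protein(rng.choice(proteins))
        sb.add_event(ev_type, trig, [("Theme", theme), ("Cause", cause)])
    else:
        _simple_clause(sb, rng, ev_type, proteins)
    sb.add(".")


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, AnnotationSet]:
    """Generate documents, protein annotations and a gold event layer."""
    spec.validate()
    corpus = Corpus()
    gold = AnnotationSet(source_id="gold")
    for i in range(spec.n_docs):
        rng = random.Random((spec.seed << 20) + i)
        doc_id = f"D{i:04d}"
        a1: dict[str, TextBound] = {}
        doc = DocAnnotations(doc_id, "", proteins=a1)
        parts: list[str] = []
        offset = 0
        for _ in range(spec.sentences_per_doc):
            sb = _SentenceBuilder(offset, doc, a1)
            _sentence(sb, rng, spec)
            parts.append(sb.text())
            offset += len(sb.text()) + 1  # sentences joined by a space
        text = " ".join(parts)
        doc.text = text
        corpus.documents[doc_id] = Document(doc_id, text)
        corpus.proteins[doc_id] = a1
        doc.validate()
        gold.docs[doc_id] = doc
    return corpus, gold


# ---------------------------------------------------------------------------
# System simulation

def _jitter_trigger(rng: random.Random, tb: TextBound, text: str) -> TextBound:
    """Extend the trigger span within its own one-word window (strict match
    breaks, approximate anchored on the original span still holds)."""
    ext_start, ext_end = extension_window(text, tb.start, tb.end)
    options = []
    if ext_start < tb.start:
        options.append((ext_start, tb.end))
    if ext_end > tb.end:
        options.append((tb.start, ext_end))
    if not options:
        return tb
    start, end = rng.choice(options)
    return TextBound(tb.tb_id, tb.ann_type, start, end, text[start:end])


def _decoy_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    start = 0
    needle = DECOY_WORD
    while True:
        idx = text.find(needle, start)
        if idx < 0:
            return spans
        spans.append((idx, idx + len(needle)))
        start = idx + 1


def simulate_system(corpus: Corpus, gold: AnnotationSet,
                    spec: SystemSpec) -> AnnotationSet:
    """Derive an imperfect extractor output from the gold annotation.

    Keep/drop draws, jitter draws and spurious-event placement all come from
    a per-document stream seeded by the spec; the spurious count follows the
    running total kept*(1-p)/p so the corpus-level precision matches the
    target up to integer rounding.
    """
    spec.validate()
    out = AnnotationSet(source_id=spec.source_id)
    kept_cum = 0
    spur_cum = 0
    for di, doc_id in enumerate(gold.doc_ids()):
        rng = random.Random((spec.seed << 21) + 1_000_003 + di)
        gdoc = gold.docs[doc_id]
        sdoc = DocAnnotations(doc_id, gdoc.text, proteins=dict(gdoc.proteins))
        kept: dict[str, str] = {}  # gold ev_id -> new ev_id
        next_t = 0
        next_e = 0
        for ev in gdoc.topological_events():
            coin = rng.random() < spec.target_recall
            deps = [t for _, t in ev.args if t in gdoc.events]
            if not coin or any(d not in kept for d in deps):
                continue
            trig = gdoc.trigger_of(ev)
            if rng.random() < spec.span_jitter_prob:
                trig = _jitter_trigger(rng, trig, gdoc.text)
            next_t += 1
            t_id = f"TS{next_t}"
            sdoc.triggers[t_id] = TextBound(t_id, trig.ann_type, trig.start,
                                            trig.end, trig.surface)
            args = [
                (role, kept[t] if t in gdoc.events else t)
                for role, t in ev.args
            ]
            next_e += 1
            e_id = f"E{next_e}"
            sdoc.events[e_id] = Event(e_id, ev.ev_type, t_id, tuple(args))
            kept[ev.ev_id] = e_id
        kept_cum += len(kept)

        p = spec.target_precision
        target_spur = round(kept_cum * (1 - p) / p)
        n_spur = max(0, target_spur - spur_cum)
        spur_cum += n_spur
        decoys = _decoy_spans(gdoc.text)
        protein_ids = sorted(sdoc.proteins)
        for _ in range(n_spur):
            if not decoys or not protein_ids:
                break
            start, end = decoys[rng.randrange(len(decoys))]
            ev_type = rng.choice(EVENT_TYPES)
            next_t += 1
            t_id = f"TS{next_t}"
            sdoc.triggers[t_id] = TextBound(t_id, ev_type, start, end,
                                            gdoc.text[start:end])
            theme = protein_ids[rng.randrange(len(protein_ids))]
            next_e += 1
            e_id = f"E{next_e}"
            sdoc.events[e_id] = Event(e_id, ev_type, t_id,
                                      (("Theme", theme),))
        sdoc.validate()
        out.docs[doc_id] = sdoc
    return out


def simulate_systems(corpus: Corpus, gold: AnnotationSet,
                     specs: list[SystemSpec]) -> list[AnnotationSet]:
    return [simulate_system(corpus, gold, s) for s in specs]
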