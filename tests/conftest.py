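import copy

import pytest

from bioevents.model import AnnotationSet, Document
from bioevents.standoff import parse_a1, parse_a2
from bioevents.synthetic import (
    DEFAULT_MIX,
    CorpusSpec,
    SystemSpec,
    generate_corpus,
    simulate_system,
)

#: A nesting-free type mix for tests that need clean binomial behaviour or
#: fixtures without forced sub-event emission.
FLAT_MIX = {
    "Gene_expression": 0.3,
    "Binding": 0.2,
    "Phosphorylation": 0.2,
    "Transcription": 0.1,
    "Localization": 0.1,
    "Protein_catabolism": 0.1,
}


def build_doc(text: str, a1: str = "", a2: str = "", doc_id: str = "doc",
              lenient: bool = False):
    """Hand fixture helper: parse literal standoff content over ``text``."""
    document = Document(doc_id, text)
    proteins = parse_a1(document, a1)
    return document, proteins, parse_a2(document, a2, proteins, lenient=lenient)


def single_doc_set(source_id: str, doc_ann) -> AnnotationSet:
    return AnnotationSet(source_id=source_id, docs={doc_ann.doc_id: doc_ann})


def clone_as(aset: AnnotationSet, source_id: str) -> AnnotationSet:
    out = copy.deepcopy(aset)
    out.source_id = source_id
    return out


def small_corpus(seed: int, n_docs: int = 2, sentences: int = 6,
                 mix=None, nesting_prob: float = 0.4):
    spec = CorpusSpec(
        n_docs=n_docs,
        sentences_per_doc=sentences,
        event_type_mix=dict(mix or DEFAULT_MIX),
        nesting_prob=nesting_prob if mix is None else 0.0,
        seed=seed,
    )
    return generate_corpus(spec)


def noisy_system(corpus, gold, source_id: str, recall: float, precision: float,
                 jitter: float, seed: int):
    spec = SystemSpec(source_id, recall, precision, jitter, seed=seed)
    return simulate_system(corpus, gold, spec)


@pytest.fixture
def nested_fixture():
    """A 3-level regulation chain plus a sibling leaf event."""
    text = "BRCA1 inhibits the activation of the expression of TP53 and MDM2 is phosphorylated ."
    a1 = (
        "T1\tProtein 0 5\tBRCA1\n"
        "T2\tProtein 51 55\tTP53\n"
        "T3\tProtein 60 64\tMDM2\n"
    )
    a2 = (
        "T4\tNegative_regulation 6 14\tinhibits\n"
        "T5\tPositive_regulation 19 29\tactivation\n"
        "T6\tGene_expression 37 47\texpression\n"
        "T7\tPhosphorylation 68 82\tphosphorylated\n"
        "E1\tGene_expression:T6 Theme:T2\n"
        "E2\tPositive_regulation:T5 Theme:E1\n"
        "E3\tNegative_regulation:T4 Theme:E2 Cause:T1\n"
        "E4\tPhosphorylation:T7 Theme:T3\n"
    )
    return build_doc(text, a1, a2)
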