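"""Span matching, recursive event equality and P/R/F1 computation."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bioevents.matching import (
    APPROX_MODE,
    APPROXIMATE,
    STRICT,
    STRICT_MODE,
    MatchMode,
    MatchModeError,
    compute_metrics,
    event_equal,
    extension_window,
    f1,
    round2,
    span_match,
)
from bioevents.model import Document, TextBound
from bioevents.standoff import parse_a2

from conftest import FLAT_MIX, build_doc, noisy_system, single_doc_set, small_corpus
from oracles import oracle_counts, oracle_event_equal, oracle_span_match


def tb(ann_type, start, end, text):
    return TextBound("T0", ann_type, start, end, text[start:end])


class TestSpanMatch:
    TEXT = "High overexpression of p53 was seen"

    def test_identical_spans_match_under_both_modes(self):
        a = tb("Binding", 5, 19, self.TEXT)
        for mode in (STRICT, APPROXIMATE):
            assert span_match(a, a, mode, self.TEXT)

    def test_type_mismatch_fails_both_modes(self):
        a = tb("Protein", 5, 19, self.TEXT)
        b = tb("Binding", 5, 19, self.TEXT)
        for mode in (STRICT, APPROXIMATE):
            assert not span_match(a, b, mode, self.TEXT)

    def test_prefix_extension_matches_approximately_only(self):
        # reference "expression" inside "overexpression": the candidate span
        # covering the whole token sits inside the one-word window.
        ref = tb("Gene_expression", 9, 19, self.TEXT)
        assert self.TEXT[9:19] == "expression"
        cand = tb("Gene_expression", 5, 19, self.TEXT)
        assert self.TEXT[5:19] == "overexpression"
        assert not span_match(ref, cand, STRICT, self.TEXT)
        assert span_match(ref, cand, APPROXIMATE, self.TEXT)

    def test_two_words_away_is_no_match(self):
        ref = tb("Gene_expression", 5, 19, self.TEXT)  # overexpression
        cand = tb("Gene_expression", 5, 26, self.TEXT)  # ... of p53
        assert not span_match(ref, cand, APPROXIMATE, self.TEXT)

    def test_all_subspans_agree_with_independent_window_rule(self):
        """Brute force: every candidate sub-span verdict equals the oracle's."""
        text = self.TEXT
        for start, end in [(0, 4), (5, 19), (9, 19), (23, 26), (31, 35)]:
            ref = tb("Binding", start, end, text)
            for cs, ce in itertools.combinations(range(len(text) + 1), 2):
                cand = tb("Binding", cs, ce, text)
                assert span_match(ref, cand, APPROXIMATE, text) == \
                    oracle_span_match(ref, cand, False, text)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_strict_match_implies_approximate(self, data):
        text = "STAT3 activates the expression of IL2 in T cells"
        s1 = data.draw(st.integers(0, len(text) - 1))
        e1 = data.draw(st.integers(s1 + 1, len(text)))
        s2 = data.draw(st.integers(0, len(text) - 1))
        e2 = data.draw(st.integers(s2 + 1, len(text)))
        a, b = tb("Binding", s1, e1, text), tb("Binding", s2, e2, text)
        if span_match(a, b, STRICT, text):
            assert span_match(a, b, APPROXIMATE, text)

    def test_window_at_text_edges(self):
        text = "TP53 binds MDM2"
        assert extension_window(text, 0, 4) == (0, 10)
        assert extension_window(text, 11, 15) == (5, 15)


class TestEventEqual:
    def test_identical_events_equal(self, nested_fixture):
        _, _, ann = nested_fixture
        for mode in (STRICT_MODE, APPROX_MODE):
            assert event_equal(ann.events["E4"], ann.events["E4"], mode, ann, ann)

    def test_binding_theme_order_is_irrelevant(self):
        text = "TP53 binds MDM2"
        a1 = "T1\tProtein 0 4\tTP53\nT2\tProtein 11 15\tMDM2\n"
        _, _, ann1 = build_doc(
            text, a1, "T3\tBinding 5 10\tbinds\nE1\tBinding:T3 Theme:T1 Theme2:T2\n"
        )
        _, _, ann2 = build_doc(
            text, a1, "T3\tBinding 5 10\tbinds\nE1\tBinding:T3 Theme:T2 Theme2:T1\n"
        )
        for mode in (STRICT_MODE, APPROX_MODE):
            assert event_equal(ann1.events["E1"], ann2.events["E1"], mode, ann1, ann2)

    def test_theme_count_mismatch_is_unequal(self):
        text = "TP53 binds MDM2"
        a1 = "T1\tProtein 0 4\tTP53\nT2\tProtein 11 15\tMDM2\n"
        _, _, two = build_doc(
            text, a1, "T3\tBinding 5 10\tbinds\nE1\tBinding:T3 Theme:T1 Theme2:T2\n"
        )
        _, _, one = build_doc(
            text, a1, "T3\tBinding 5 10\tbinds\nE1\tBinding:T3 Theme:T1\n"
        )
        assert not event_equal(two.events["E1"], one.events["E1"], APPROX_MODE, two, one)

    def test_cross_document_comparison_is_a_usage_error(self, nested_fixture):
        _, _, ann = nested_fixture
        _, _, other = build_doc(
            "TP53 binds MDM2",
            "T1\tProtein 0 4\tTP53\nT2\tProtein 11 15\tMDM2\n",
            "T3\tBinding 5 10\tbinds\nE1\tBinding:T3 Theme:T1\n",
            doc_id="other",
        )
        with pytest.raises(MatchModeError, match="documents"):
            event_equal(ann.events["E4"], other.events["E1"], APPROX_MODE, ann, other)

    def test_nested_perturbations_match_brute_force_verdicts(self, nested_fixture):
        """All 2^3 leaf/trigger perturbations of a 3-level regulation chain
        agree with the exhaustive permutation-search comparator."""
        doc, proteins, ref = nested_fixture
        text = ref.text
        for leaf_theme, mid_trigger, outer_cause in itertools.product(
            ["T2", "T3"], [(19, 29), (15, 29)], ["T1", "T2"]
        ):
            a2 = (
                "T4\tNegative_regulation 6 14\tinhibits\n"
                f"T5\tPositive_regulation {mid_trigger[0]} {mid_trigger[1]}\t"
                f"{text[mid_trigger[0]:mid_trigger[1]]}\n"
                "T6\tGene_expression 37 47\texpression\n"
                f"E1\tGene_expression:T6 Theme:{leaf_theme}\n"
                "E2\tPositive_regulation:T5 Theme:E1\n"
                f"E3\tNegative_regulation:T4 Theme:E2 Cause:{outer_cause}\n"
            )
            cand = parse_a2(doc, a2, proteins)
            for mode, strict in ((STRICT_MODE, True), (APPROX_MODE, False)):
                got = event_equal(ref.events["E3"], cand.events["E3"], mode, ref, cand)
                want = oracle_event_equal(
                    ref.events["E3"], cand.events["E3"], ref, cand, strict
                )
                assert got == want

    def test_nested_cause_ignored_only_under_approximate_recursion(self):
        """A Cause on a nested event breaks strict equality but not the
        approximate Theme-only recursive comparison."""
        text = "BRCA1 inhibits the activation of TP53 now"
        a1 = "T1\tProtein 0 5\tBRCA1\nT2\tProtein 33 37\tTP53\n"
        base = (
            "T4\tNegative_regulation 6 14\tinhibits\n"
            "T5\tPositive_regulation 19 29\tactivation\n"
        )
        _, _, with_cause = build_doc(
            text, a1, base + "E1\tPositive_regulation:T5 Theme:T2 Cause:T1\n"
            "E2\tNegative_regulation:T4 Theme:E1\n"
        )
        _, _, without = build_doc(
            text, a1, base + "E1\tPositive_regulation:T5 Theme:T2\n"
            "E2\tNegative_regulation:T4 Theme:E1\n"
        )
        a, b = with_cause.events["E2"], without.events["E2"]
        assert not event_equal(a, b, STRICT_MODE, with_cause, without)
        assert event_equal(a, b, APPROX_MODE, with_cause, without)
        # at top level the Cause difference matters even approximately
        assert not event_equal(
            with_cause.events["E1"], without.events["E1"], APPROX_MODE,
            with_cause, without,
        )

    def test_equiv_group_member_matches_when_enabled(self):
        text = "TP53 p53 is phosphorylated"
        a1 = "T1\tProtein 0 4\tTP53\nT2\tProtein 5 8\tp53\n"
        a2_base = "T3\tPhosphorylation 12 26\tphosphorylated\n"
        _, _, ref = build_doc(
            text, a1, a2_base + "E1\tPhosphorylation:T3 Theme:T1\n*\tEquiv T1 T2\n"
        )
        _, _, cand = build_doc(text, a1, a2_base + "E1\tPhosphorylation:T3 Theme:T2\n")
        plain = MatchMode(span_mode=STRICT, recursive_mode=STRICT)
        with_equiv = MatchMode(span_mode=STRICT, recursive_mode=STRICT, use_equiv=True)
        assert not event_equal(ref.events["E1"], cand.events["E1"], plain, ref, cand)
        assert event_equal(ref.events["E1"], cand.events["E1"], with_equiv, ref, cand)


class TestF1:
    @pytest.mark.parametrize(
        "precision, recall, expected",
        [
            (57.69, 45.85, 51.09),
            (48.88, 55.69, 52.06),
            (73.21, 42.52, 53.80),
            (70.38, 47.11, 56.44),
            (67.17, 49.37, 56.91),
            (63.39, 51.19, 56.64),
            (57.60, 53.02, 55.21),
            (68.31, 45.85, 54.87),
            (67.57, 46.10, 54.81),
        ],
    )
    def test_harmonic_mean_matches_published_score_tables(
        self, precision, recall, expected
    ):
        # inputs are themselves rounded to 2 decimals, which can shift the
        # harmonic mean by one unit in the last printed digit
        assert abs(round2(f1(precision, recall)) - expected) <= 0.01

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=100, derandomize=True)
    def test_bounded_by_min_and_max_of_inputs(self, p, r):
        value = f1(p, r)
        assert 0 <= value <= 100
        assert value <= max(p, r) + 1e-9
        assert min(p, r) - 1e-9 <= value or value == 0.0

    @given(st.floats(0, 100))
    @settings(max_examples=50, derandomize=True)
    def test_identities(self, x):
        assert f1(x, x) == pytest.approx(x)
        assert f1(0, x) == 0.0

    @pytest.mark.parametrize("p, r", [(-1, 50), (101, 50), (50, -0.5)])
    def test_out_of_range_rejected(self, p, r):
        with pytest.raises(ValueError):
            f1(p, r)


class TestComputeMetrics:
    def test_self_comparison_is_all_100(self):
        corpus, gold = small_corpus(seed=7)
        report = compute_metrics(gold, gold, APPROX_MODE)
        tot = report.total
        assert (tot.precision, tot.recall, tot.f1) == (100.0, 100.0, 100.0)
        for counts in report.per_type.values():
            assert counts.f1 == 100.0

    def test_half_overlap_counts(self):
        text = "TP53 is expressed and MDM2 is phosphorylated"
        a1 = "T1\tProtein 0 4\tTP53\nT2\tProtein 22 26\tMDM2\n"
        _, _, ref = build_doc(
            text, a1,
            "T3\tGene_expression 8 17\texpressed\n"
            "T4\tPhosphorylation 30 44\tphosphorylated\n"
            "E1\tGene_expression:T3 Theme:T1\nE2\tPhosphorylation:T4 Theme:T2\n",
        )
        _, _, cand = build_doc(
            text, a1,
            "T3\tGene_expression 8 17\texpressed\n"
            "T4\tPhosphorylation 30 44\tphosphorylated\n"
            "E1\tGene_expression:T3 Theme:T1\nE2\tPhosphorylation:T4 Theme:T1\n",
        )
        report = compute_metrics(
            single_doc_set("gold", ref), single_doc_set("sys", cand), STRICT_MODE
        )
        tot = report.total
        assert (tot.precision, tot.recall, tot.f1) == (50.0, 50.0, 50.0)

    def test_document_mismatch_is_a_usage_error(self):
        corpus, gold = small_corpus(seed=1, n_docs=2)
        partial = single_doc_set("sys", gold.docs[gold.doc_ids()[0]])
        with pytest.raises(MatchModeError, match="document ID"):
            compute_metrics(gold, partial)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_counts_equal_brute_force_comparator(self, seed):
        corpus, gold = small_corpus(seed, n_docs=2, sentences=8)
        system = noisy_system(corpus, gold, "s", 0.6, 0.7, 0.4, seed=seed + 50)
        for mode, strict in ((STRICT_MODE, True), (APPROX_MODE, False)):
            report = compute_metrics(gold, system, mode)
            expected = oracle_counts(gold, system, strict)
            got = {
                t: [c.n_gold, c.n_pred, c.tp_gold, c.tp_pred]
                for t, c in report.per_type.items()
            }
            assert got == expected

    def test_total_counts_are_sums_of_per_type(self):
        corpus, gold = small_corpus(seed=4, mix=FLAT_MIX)
        system = noisy_system(corpus, gold, "s", 0.5, 0.5, 0.2, seed=9)
        report = compute_metrics(gold, system)
        tot = report.total
        assert tot.n_gold == sum(c.n_gold for c in report.per_type.values())
        assert tot.tp_pred == sum(c.tp_pred for c in report.per_type.values())
        assert tot.tp_gold <= tot.n_gold and tot.tp_pred <= tot.n_pred

    @pytest.mark.parametrize("seed", [21, 22])
    def test_approximate_scores_dominate_strict(self, seed):
        corpus, gold = small_corpus(seed)
        system = noisy_system(corpus, gold, "s", 0.7, 0.8, 0.5, seed=seed)
        strict = compute_metrics(gold, system, STRICT_MODE).total
        approx = compute_metrics(gold, system, APPROX_MODE).total
        assert approx.precision >= strict.precision
        assert approx.recall >= strict.recall
        assert approx.f1 >= strict.f1

    def test_strict_symmetry_swaps_precision_and_recall(self):
        corpus, gold = small_corpus(seed=5)
        system = noisy_system(corpus, gold, "s", 0.6, 0.7, 0.0, seed=6)
        fwd = compute_metrics(gold, system, STRICT_MODE).total
        rev = compute_metrics(system, gold, STRICT_MODE).total
        assert fwd.precision == pytest.approx(rev.recall)
        assert fwd.recall == pytest.approx(rev.precision)
        assert fwd.f1 == pytest.approx(rev.f1)
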