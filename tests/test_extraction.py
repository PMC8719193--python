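"""Quote-span finding, cleaning, counting and span-level evaluation."""

from __future__ import annotations

from dataclasses import replace
from datetime import datetime

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quotedtext.extraction import (
    ClinicalNote,
    GoldAnnotation,
    QuoteDialect,
    build_quote_database,
    clean_quotes,
    count_words,
    evaluate_extraction,
    find_quote_spans,
    summary_stats,
    word_length_histogram,
)


class TestFindQuoteSpans:
    def test_simple_straight_pair(self):
        spans = find_quote_spans('He said "terrible" twice.')
        assert len(spans) == 1
        assert spans[0].cleaned_text == "terrible"
        assert spans[0].delimiter_kind == "straight_double"

    def test_apostrophe_is_not_a_quote(self):
        assert find_quote_spans("the patient's mood improved") == []

    def test_mixed_curly_and_straight(self):
        spans = find_quote_spans('“I feel low” she said, then "fine"')
        assert [s.cleaned_text for s in spans] == ["I feel low", "fine"]
        assert [s.delimiter_kind for s in spans] == ["curly_double", "straight_double"]

    def test_unmatched_trailing_opener_yields_no_span(self):
        assert find_quote_spans('she said "never mind') == []
        assert find_quote_spans("only an opener “ here") == []

    def test_span_does_not_cross_paragraph_break(self):
        # one opener before the break, one closer after: neither paragraph
        # holds a balanced pair, so no span may bridge the blank line
        assert find_quote_spans('a "one\n\ntwo" b') == []
        # pairing restarts cleanly in the second paragraph
        spans = find_quote_spans('a "one\n\ntwo "whole" b')
        assert [s.cleaned_text for s in spans] == ["whole"]

    def test_single_quotes_opt_in_with_apostrophe_guard(self):
        dialect = QuoteDialect(single=True)
        spans = find_quote_spans("felt 'low' but the patient's family didn't", dialect)
        assert [s.cleaned_text for s in spans] == ["low"]

    def test_offsets_are_code_points_and_raw_matches_slice(self):
        text = 'café “déjà vu” again'
        (span,) = find_quote_spans(text)
        assert text[span.start_offset : span.end_offset] == span.raw_text
        assert span.cleaned_text == "déjà vu"

    def test_empty_text(self):
        assert find_quote_spans("") == []

    def test_dialect_requires_a_delimiter(self):
        with pytest.raises(ValueError):
            QuoteDialect(straight_double=False, curly_double=False, single=False)

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet='ab "“”\'\n.', max_size=80))
    def test_spans_ordered_nonoverlapping_and_slice_consistent(self, text):
        spans = find_quote_spans(text, QuoteDialect(single=True))
        last_end = 0
        for s in spans:
            assert s.start_offset >= last_end
            assert s.end_offset <= len(text)
            assert text[s.start_offset : s.end_offset] == s.raw_text
            last_end = s.end_offset

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="abc xyz.,!", max_size=60))
    def test_no_delimiters_no_spans(self, text):
        assert find_quote_spans(text, QuoteDialect(single=True)) == []


class TestCountWords:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("terrible", 1),
            ("!!", 0),
            ("I am fine", 3),
            ("don't", 1),
            ("", 0),
            ("  ...  ", 0),
            ("a-b c", 3),  # hyphen splits tokens
            ("one2three 4", 2),
        ],
    )
    def test_examples(self, text, expected):
        assert count_words(text) == expected


class TestCleanQuotes:
    def _span(self, cleaned):
        (s,) = find_quote_spans(f'"{cleaned}"')
        return s

    def test_blank_removed(self):
        kept, counts = clean_quotes([self._span(""), self._span("   ")])
        assert kept == [] and counts["blank"] == 2

    def test_html_tag_removed(self):
        kept, counts = clean_quotes(
            [self._span("<br>"), self._span("</div> <p>"), self._span("&nbsp;")]
        )
        assert kept == [] and counts["html"] == 3

    def test_real_content_retained(self):
        spans = [self._span("terrible"), self._span("!!"), self._span("I am fine")]
        kept, counts = clean_quotes(spans)
        assert kept == spans
        assert counts == {"blank": 0, "html": 0}

    def test_punctuation_only_is_not_blank(self):
        kept, _ = clean_quotes([self._span("!!")])
        assert len(kept) == 1 and kept[0].word_count == 0


class TestBuildDatabase:
    def _note(self, nid, pid, day, text):
        return ClinicalNote(nid, pid, datetime(2019, 1, day), text)

    def test_empty_input(self):
        db = build_quote_database([])
        assert len(db) == 0 and db.index_dates == {}

    def test_index_date_is_earliest_span(self):
        notes = [
            self._note("n1", "p1", 7, 'said "later"'),
            self._note("n2", "p1", 3, 'said "earlier"'),
        ]
        db = build_quote_database(notes)
        assert db.index_dates["p1"] == datetime(2019, 1, 3)

    def test_duplicate_note_id_rejected(self):
        notes = [self._note("n1", "p1", 1, "x"), self._note("n1", "p2", 2, "y")]
        with pytest.raises(ValueError, match="duplicate note_id"):
            build_quote_database(notes)

    def test_matches_gold_on_clean_synthetic_corpus(self, clean_bundle):
        notes, gold = clean_bundle
        db = build_quote_database(notes)
        predicted = {(s.note_id, s.start_offset, s.end_offset) for s in db.spans}
        expected = {(g.note_id, s, e) for g in gold for (s, e, _t) in g.spans}
        assert predicted == expected


class TestHistogramAndStats:
    def _db_with_counts(self, counts):
        notes = [
            ClinicalNote(f"n{i}", "p", datetime(2019, 1, 1), '"' + " ".join(["w"] * c) + '"')
            for i, c in enumerate(counts)
        ]
        return build_quote_database(notes)

    def test_histogram_small_counts(self):
        db = self._db_with_counts([1, 1, 3])
        h = word_length_histogram(db).set_index("bin")
        assert h.loc["1", "count"] == 2
        assert h.loc["3", "count"] == 1
        assert h.loc["1", "percent"] == pytest.approx(66.6667, abs=1e-3)
        assert h["count"].sum() == 3

    @pytest.mark.parametrize("wc,bin_label", [(12, "10–14"), (250, "200+"), (0, "0"), (9, "9"), (74, "55–74")])
    def test_bin_assignment(self, wc, bin_label):
        db = self._db_with_counts([wc]) if wc else None
        if wc == 0:
            notes = [ClinicalNote("n", "p", datetime(2019, 1, 1), '"!!"')]
            db = build_quote_database(notes)
        h = word_length_histogram(db).set_index("bin")
        assert h.loc[bin_label, "count"] == 1
        assert h["count"].sum() == 1

    def test_summary_stats_hand_computed(self):
        db = self._db_with_counts([1, 3, 5])
        s = summary_stats(db)
        assert s["mean"] == 3 and s["median"] == 3
        assert s["sd"] == pytest.approx((8 / 3) ** 0.5)
        assert (s["min"], s["max"]) == (1, 5)

    def test_summary_stats_zero_spread(self):
        s = summary_stats(self._db_with_counts([2, 2, 2, 2]))
        assert s["sd"] == 0

    def test_summary_stats_empty_errors(self):
        with pytest.raises(ValueError):
            summary_stats(build_quote_database([]))


class TestEvaluate:
    def _pred(self, nid, start, end):
        return replace(
            find_quote_spans('"' + "x" * (end - start - 2) + '"')[0],
            note_id=nid,
            start_offset=start,
            end_offset=end,
        )

    def test_identity(self):
        gold = [GoldAnnotation("n1", (((0, 5, '"abc"')),))]
        pred = [self._pred("n1", 0, 5)]
        m = evaluate_extraction(pred, gold)
        assert (m.precision, m.recall) == (1.0, 1.0)

    def test_empty_predictions(self):
        gold = [GoldAnnotation("n1", ((0, 5, '"abc"'),))]
        m = evaluate_extraction([], gold)
        assert m.recall == 0.0
        assert m.precision == 0.0 and m.precision_undefined

    def test_counting_oracle(self):
        gold = [GoldAnnotation("n1", ((0, 5, "a"), (10, 15, "b"), (20, 25, "c"), (30, 35, "d")))]
        pred = [self._pred("n1", 0, 5), self._pred("n1", 10, 15), self._pred("n1", 50, 55)]
        m = evaluate_extraction(pred, gold)
        assert m.true_positives == 2 and m.false_positives == 1 and m.false_negatives == 2
        assert m.precision == pytest.approx(2 / 3)
        assert m.recall == pytest.approx(1 / 2)

    def test_unknown_note_id_rejected(self):
        gold = [GoldAnnotation("n1", ())]
        with pytest.raises(ValueError, match="unknown note_id"):
            evaluate_extraction([self._pred("nX", 0, 5)], gold)

    def test_text_overlap_matching(self):
        gold = [GoldAnnotation("n1", ((0, 10, "x"),))]
        pred = [self._pred("n1", 2, 8)]
        assert evaluate_extraction(pred, gold, matching="exact-offset").true_positives == 0
        assert evaluate_extraction(pred, gold, matching="text-overlap").true_positives == 1
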