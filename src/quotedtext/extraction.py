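"""Quoted-span extraction from clinical note text.

Clinicians often record verbatim patient (or third-party) speech inside
quotation marks.  This module finds those spans with a rule-based matcher,
cleans out blank and html-artefact quotes, counts words, and assembles a
quotation database with per-patient index dates (the date of each patient's
first quotation).  Extraction quality is measured against gold annotations
with span-level precision and recall.

Offsets are 0-based half-open over Unicode code points and never cross a
note boundary.  Candidate spans are found independently within each
blank-line-delimited paragraph, so a stray unbalanced delimiter can only
damage pairing inside its own paragraph.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from datetime import datetime
from typing import Iterable, Literal, Sequence

__all__ = [
    "ClinicalNote",
    "QuoteSpan",
    "QuotationDatabase",
    "ExtractionMetrics",
    "QuoteDialect",
    "GoldAnnotation",
    "find_quote_spans",
    "clean_quotes",
    "count_words",
    "build_quote_database",
    "word_length_histogram",
    "summary_stats",
    "evaluate_extraction",
]


@dataclass(frozen=True)
class ClinicalNote:
    """One free-text clinical document tied to a patient and a timestamp."""

    note_id: str
    patient_id: str
    timestamp: datetime
    text: str


@dataclass(frozen=True)
class GoldAnnotation:
    """Reference quotation spans for one note (offsets include delimiters)."""

    note_id: str
    spans: tuple[tuple[int, int, str], ...]  # (start, end, raw_text)


@dataclass(frozen=True)
class QuoteSpan:
    """One extracted quotation.

    ``raw_text`` includes the enclosing delimiters; ``cleaned_text`` is the
    content between them with surrounding whitespace stripped.
    """

    note_id: str
    patient_id: str
    timestamp: datetime | None
    start_offset: int
    end_offset: int
    raw_text: str
    cleaned_text: str
    word_count: int
    delimiter_kind: Literal["straight_double", "curly_double", "single"]


@dataclass
class QuotationDatabase:
    spans: list[QuoteSpan]
    index_dates: dict[str, datetime]
    removal_counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.spans)


@dataclass(frozen=True)
class ExtractionMetrics:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    precision_undefined: bool = False
    recall_undefined: bool = False


@dataclass(frozen=True)
class QuoteDialect:
    """Which delimiter kinds the matcher pairs.

    Single quotes are off by default: apostrophes make them the lowest
    precision delimiter, so they are opt-in.  When enabled, both single
    quotes of a pair must be flanked by non-word characters on the outside
    (the apostrophe guard).
    """

    straight_double: bool = True
    curly_double: bool = True
    single: bool = False

    def __post_init__(self) -> None:
        if not (self.straight_double or self.curly_double or self.single):
            raise ValueError("dialect must enable at least one delimiter kind")


DEFAULT_DIALECT = QuoteDialect()

_PARAGRAPH_RE = re.compile(r"\n[ \t]*\n")
# a token = letters/digits, with internal apostrophes allowed ("don't")
_WORD_RE = re.compile(r"[^\W_]+(?:['’][^\W_]+)*", re.UNICODE)
_HTML_BIT = r"(?:</?[A-Za-z][^<>]*>|&#?[A-Za-z0-9]+;|[\w-]+\s*=\s*(?:'[^']*'|[^\s<>]+))"
_HTML_RE = re.compile(rf"(?:\s*{_HTML_BIT})+\s*")

CURLY_OPEN = "“"
CURLY_CLOSE = "”"


def count_words(cleaned_text: str) -> int:
    """Number of word tokens in a cleaned quotation.

    Tokens are maximal runs of letters/digits; internal apostrophes do not
    split a token.  Punctuation-only quotes count 0 words (they are real
    quotations and are retained, binned at word length 0).
    """
    return len(_WORD_RE.findall(cleaned_text))


def _is_word_char(ch: str) -> bool:
    return bool(re.match(r"[^\W_]", ch, re.UNICODE))


def _scan_paragraph(text: str, base: int, dialect: QuoteDialect) -> list[QuoteSpan]:
    spans: list[QuoteSpan] = []
    n = len(text)
    i = 0
    while i < n:
        ch = text[i]
        if dialect.straight_double and ch == '"':
            j = text.find('"', i + 1)
            if j == -1:
                i += 1  # unmatched trailing opener: no span
                continue
            spans.append(_make_span(text, base, i, j + 1, "straight_double"))
            i = j + 1
        elif dialect.curly_double and ch == CURLY_OPEN:
            j = text.find(CURLY_CLOSE, i + 1)
            if j == -1:
                i += 1
                continue
            spans.append(_make_span(text, base, i, j + 1, "curly_double"))
            i = j + 1
        elif dialect.single and ch == "'":
            if i > 0 and _is_word_char(text[i - 1]):
                i += 1  # apostrophe guard on the opener
                continue
            j = text.find("'", i + 1)
            while j != -1 and j + 1 < n and _is_word_char(text[j + 1]):
                j = text.find("'", j + 1)  # closer guard: skip apostrophes
            if j == -1:
                i += 1
                continue
            spans.append(_make_span(text, base, i, j + 1, "single"))
            i = j + 1
        else:
            i += 1
    return spans


def _make_span(text: str, base: int, i: int, j: int, kind: str) -> QuoteSpan:
    raw = text[i:j]
    cleaned = raw[1:-1].strip()
    return QuoteSpan(
        note_id="",
        patient_id="",
        timestamp=None,
        start_offset=base + i,
        end_offset=base + j,
        raw_text=raw,
        cleaned_text=cleaned,
        word_count=count_words(cleaned),
        delimiter_kind=kind,  # type: ignore[arg-type]
    )


def find_quote_spans(
    text: str, dialect: QuoteDialect = DEFAULT_DIALECT
) -> list[QuoteSpan]:
    """Find quotation spans in ``text``, left to right, non-overlapping.

    Straight double quotes are paired greedily left-to-right; curly quotes
    are matched as open/close pairs.  Candidates are sought within each
    blank-line paragraph separately, so a span can never cross a paragraph
    break and an unbalanced delimiter cannot corrupt pairing beyond its
    paragraph.  Returns spans with offsets into the original ``text``.
    """
    spans: list[QuoteSpan] = []
    pos = 0
    for m in _PARAGRAPH_RE.finditer(text):
        spans.extend(_scan_paragraph(text[pos : m.start()], pos, dialect))
        pos = m.end()
    spans.extend(_scan_paragraph(text[pos:], pos, dialect))
    return spans


def _is_html_artifact(cleaned_text: str) -> bool:
    return bool(_HTML_RE.fullmatch(cleaned_text))


def clean_quotes(
    spans: Iterable[QuoteSpan],
) -> tuple[list[QuoteSpan], dict[str, int]]:
    """Drop blank quotes and quotes that are html-tag debris.

    Blank means the cleaned text is empty or whitespace-only.  Html debris
    means the cleaned text consists entirely of markup tags, character
    entities, or attribute fragments.  Everything else passes through
    unchanged.  Returns the kept spans and removal counts.
    """
    kept: list[QuoteSpan] = []
    counts = {"blank": 0, "html": 0}
    for s in spans:
        if not s.cleaned_text.strip():
            counts["blank"] += 1
        elif _is_html_artifact(s.cleaned_text):
            counts["html"] += 1
        else:
            kept.append(s)
    return kept, counts


def build_quote_database(
    notes: Sequence[ClinicalNote], dialect: QuoteDialect = DEFAULT_DIALECT
) -> QuotationDatabase:
    """Run find → clean over all notes and assemble the quotation database.

    The index date of a patient is the timestamp of their earliest retained
    quotation.  Duplicate note ids are rejected.
    """
    seen: set[str] = set()
    all_spans: list[QuoteSpan] = []
    totals = {"blank": 0, "html": 0}
    for note in notes:
        if note.note_id in seen:
            raise ValueError(f"duplicate note_id: {note.note_id!r}")
        seen.add(note.note_id)
        found = find_quote_spans(note.text, dialect)
        kept, counts = clean_quotes(found)
        totals["blank"] += counts["blank"]
        totals["html"] += counts["html"]
        for s in kept:
            all_spans.append(
                replace(
                    s,
                    note_id=note.note_id,
                    patient_id=note.patient_id,
                    timestamp=note.timestamp,
                )
            )
    index_dates: dict[str, datetime] = {}
    for s in all_spans:
        prev = index_dates.get(s.patient_id)
        if prev is None or s.timestamp < prev:
            index_dates[s.patient_id] = s.timestamp
    return QuotationDatabase(spans=all_spans, index_dates=index_dates, removal_counts=totals)


#: word-length histogram bins: singletons 0–9, then coarser ranges.
HISTOGRAM_BINS: list[tuple[str, int, int]] = (
    [(str(i), i, i) for i in range(10)]
    + [
        ("10–14", 10, 14),
        ("15–19", 15, 19),
        ("20–24", 20, 24),
        ("25–29", 25, 29),
        ("30–34", 30, 34),
        ("35–39", 35, 39),
        ("40–44", 40, 44),
        ("45–49", 45, 49),
        ("50–54", 50, 54),
        ("55–74", 55, 74),
        ("75–99", 75, 99),
        ("100–149", 100, 149),
        ("150–199", 150, 199),
        ("200+", 200, None),
    ]
)


def word_length_histogram(db: QuotationDatabase):
    """Tabulate quotation counts by word-length bin.

    Returns a DataFrame with columns bin, count, percent; counts sum to the
    number of spans in the database.
    """
    import pandas as pd

    total = len(db.spans)
    rows = []
    for label, lo, hi in HISTOGRAM_BINS:
        c = sum(
            1
            for s in db.spans
            if s.word_count >= lo and (hi is None or s.word_count <= hi)
        )
        rows.append(
            {"bin": label, "count": c, "percent": 100.0 * c / total if total else 0.0}
        )
    return pd.DataFrame(rows)


def summary_stats(db: QuotationDatabase) -> dict[str, float]:
    """Mean, median, population SD (divisor n), min and max of word counts."""
    import numpy as np

    if not db.spans:
        raise ValueError("summary_stats requires a nonempty database")
    counts = np.array([s.word_count for s in db.spans], dtype=float)
    return {
        "mean": float(counts.mean()),
        "median": float(np.median(counts)),
        "sd": float(counts.std(ddof=0)),
        "min": float(counts.min()),
        "max": float(counts.max()),
    }


def evaluate_extraction(
    predicted: Sequence[QuoteSpan],
    gold: Sequence[GoldAnnotation],
    matching: Literal["exact-offset", "text-overlap"] = "exact-offset",
) -> ExtractionMetrics:
    """Span-level precision/recall of predicted spans against gold.

    With exact-offset matching, a prediction is correct iff a gold span in
    the same note has identical (start, end).  With text-overlap matching,
    overlapping character ranges match (greedily, left to right).  Each gold
    span can match at most one prediction.  An empty denominator reports the
    corresponding metric as 0 with an ``*_undefined`` flag.
    """
    gold_by_note = {g.note_id: list(g.spans) for g in gold}
    for s in predicted:
        if s.note_id not in gold_by_note:
            raise ValueError(f"prediction refers to unknown note_id {s.note_id!r}")

    tp = 0
    fp = 0
    matched: dict[str, set[int]] = {nid: set() for nid in gold_by_note}
    for s in sorted(predicted, key=lambda s: (s.note_id, s.start_offset)):
        candidates = gold_by_note[s.note_id]
        hit = None
        for idx, (gs, ge, _txt) in enumerate(candidates):
            if idx in matched[s.note_id]:
                continue
            if matching == "exact-offset":
                ok = (gs, ge) == (s.start_offset, s.end_offset)
            else:
                ok = max(gs, s.start_offset) < min(ge, s.end_offset)
            if ok:
                hit = idx
                break
        if hit is None:
            fp += 1
        else:
            matched[s.note_id].add(hit)
            tp += 1
    n_gold = sum(len(v) for v in gold_by_note.values())
    fn = n_gold - tp
    p_undef = tp + fp == 0
    r_undef = tp + fn == 0
    return ExtractionMetrics(
        true_positives=tp,
        false_positives=fp,
        false_negatives=fn,
        precision=0.0 if p_undef else tp / (tp + fp),
        recall=0.0 if r_undef else tp / (tp + fn),
        precision_undefined=p_undef,
        recall_undefined=r_undef,
    )
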