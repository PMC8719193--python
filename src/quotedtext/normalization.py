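"""Lower-casing, lemmatization and vocabulary filtering of one-word quotations.

The content analysis works on single-word quotations only.  Each instance is
lower-cased and reduced to its dictionary base form with a noun-default,
dictionary-based lemmatizer (an irregular-form table plus regular English
suffix-detachment rules), then aggregated into a lemma frequency table, and
finally thresholded: only lemmas seen at least ``min_count`` times (default
20) enter the vocabulary handed to the clustering stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .extraction import QuotationDatabase, _WORD_RE

__all__ = [
    "LemmaFrequencyTable",
    "Vocabulary",
    "normalize_token",
    "build_lemma_frequency",
    "filter_min_count",
]

# Irregular noun plurals mapped to their base form; checked before any rule.
_IRREGULAR = {
    "men": "man",
    "women": "woman",
    "children": "child",
    "feet": "foot",
    "teeth": "tooth",
    "geese": "goose",
    "mice": "mouse",
    "lice": "louse",
    "oxen": "ox",
    "people": "people",
    "voices": "voice",
}

# Forms that look inflected but are lexical items in their own right.
_KEEP = {
    "yes",
    "news",
    "series",
    "species",
    "always",
    "perhaps",
}

_ALPHA_RE = re.compile(r"[^\W\d_]+(?:'[^\W\d_]+)*", re.UNICODE)


def _lemmatize_noun(word: str) -> str:
    """Noun-default suffix detachment: plural → singular where regular."""
    if word in _IRREGULAR:
        return _IRREGULAR[word]
    if word in _KEEP or len(word) <= 3:
        return word
    if word.endswith("ies") and len(word) > 4:
        return word[:-3] + "y"
    for suf in ("sses", "ches", "shes", "xes", "zes"):
        if word.endswith(suf):
            return word[:-2]
    if word.endswith(("ss", "us", "is")):
        return word
    if word.endswith("s") and not word.endswith("'s"):
        return word[:-1]
    if word.endswith("'s"):
        return word[:-2]
    return word


def normalize_token(word: str) -> str:
    """Lower-case ``word`` and reduce it to its base form.

    Tokens containing digits or punctuation other than an internal
    apostrophe are lower-cased but not lemmatized.  The mapping is
    idempotent: a lemma maps to itself.
    """
    if not word:
        raise ValueError("cannot normalize an empty token")
    lowered = word.lower()
    if not _ALPHA_RE.fullmatch(lowered):
        return lowered
    return _lemmatize_noun(lowered)


@dataclass
class LemmaFrequencyTable:
    """lemma → (instance frequency, contributing surface forms)."""

    entries: dict[str, tuple[int, set[str]]] = field(default_factory=dict)

    def frequencies(self) -> dict[str, int]:
        return {lemma: f for lemma, (f, _) in self.entries.items()}

    def total(self) -> int:
        return sum(f for f, _ in self.entries.values())


@dataclass(frozen=True)
class Vocabulary:
    """Lemmas above the frequency threshold, ordered by descending
    frequency with alphabetical tie-break."""

    words: tuple[str, ...]
    min_count: int


def build_lemma_frequency(db: QuotationDatabase) -> LemmaFrequencyTable:
    """Aggregate one-word quotations into a lemma frequency table.

    Only spans with word_count == 1 contribute; every instance counts once
    (no per-patient or per-note deduplication).
    """
    entries: dict[str, tuple[int, set[str]]] = {}
    for s in db.spans:
        if s.word_count != 1:
            continue
        token = _WORD_RE.search(s.cleaned_text).group(0)
        lemma = normalize_token(token)
        freq, forms = entries.get(lemma, (0, set()))
        forms.add(token.lower())
        entries[lemma] = (freq + 1, forms)
    return LemmaFrequencyTable(entries=entries)


def filter_min_count(table: LemmaFrequencyTable, min_count: int = 20) -> Vocabulary:
    """Retain lemmas with frequency ≥ min_count."""
    if min_count < 1:
        raise ValueError("min_count must be ≥ 1")
    kept = [
        (lemma, freq)
        for lemma, (freq, _) in table.entries.items()
        if freq >= min_count
    ]
    kept.sort(key=lambda item: (-item[1], item[0]))
    return Vocabulary(words=tuple(lemma for lemma, _ in kept), min_count=min_count)
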