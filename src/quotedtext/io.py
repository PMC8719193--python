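"""Plain-text I/O for the pipeline's interchange formats.

Notes and gold annotations travel as JSONL, registries and statistical
tables as CSV, vocabularies as one word per line, and word vectors in the
word2vec text format (see :mod:`quotedtext.embeddings`).
"""

from __future__ import annotations

import json
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .extraction import ClinicalNote, GoldAnnotation, QuotationDatabase, QuoteSpan
from .normalization import LemmaFrequencyTable, Vocabulary

REGISTRY_COLUMNS = [
    "patient_id",
    "gender",
    "ethnicity_raw",
    "age_years",
    "imd_score",
    "icd10_code",
    "inpatient_12m",
    "contacts_12m",
    "first_referral_year",
    "has_quote",
]


def write_notes_jsonl(notes: Iterable[ClinicalNote], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for n in notes:
            fh.write(
                json.dumps(
                    {
                        "note_id": n.note_id,
                        "patient_id": n.patient_id,
                        "timestamp": n.timestamp.isoformat(),
                        "text": n.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_notes_jsonl(path: str | Path) -> list[ClinicalNote]:
    notes = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            notes.append(
                ClinicalNote(
                    note_id=str(obj["note_id"]),
                    patient_id=str(obj["patient_id"]),
                    timestamp=datetime.fromisoformat(obj["timestamp"]),
                    text=obj["text"],
                )
            )
    return notes


def read_notes_csv(path: str | Path) -> list[ClinicalNote]:
    df = pd.read_csv(path, dtype={"note_id": str, "patient_id": str})
    return [
        ClinicalNote(
            note_id=row.note_id,
            patient_id=row.patient_id,
            timestamp=datetime.fromisoformat(str(row.timestamp)),
            text="" if pd.isna(row.text) else str(row.text),
        )
        for row in df.itertuples()
    ]


def write_gold_jsonl(golds: Iterable[GoldAnnotation], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for g in golds:
            fh.write(
                json.dumps(
                    {"note_id": g.note_id, "spans": [list(s) for s in g.spans]},
                    ensure_ascii=False,
                )
                + "\n"
            )


def read_gold_jsonl(path: str | Path) -> list[GoldAnnotation]:
    golds = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            golds.append(
                GoldAnnotation(
                    note_id=str(obj["note_id"]),
                    spans=tuple((int(s), int(e), t) for s, e, t in obj["spans"]),
                )
            )
    return golds


def write_registry_csv(registry: pd.DataFrame, path: str | Path) -> None:
    registry.to_csv(path, index=False, columns=[c for c in REGISTRY_COLUMNS if c in registry.columns])


def read_registry_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"patient_id": str})


def write_spans_csv(db: QuotationDatabase, path: str | Path) -> None:
    rows = [
        {
            "note_id": s.note_id,
            "patient_id": s.patient_id,
            "timestamp": s.timestamp.isoformat() if s.timestamp else "",
            "start_offset": s.start_offset,
            "end_offset": s.end_offset,
            "cleaned_text": s.cleaned_text,
            "word_count": s.word_count,
            "delimiter_kind": s.delimiter_kind,
        }
        for s in db.spans
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_index_dates_csv(db: QuotationDatabase, path: str | Path) -> None:
    rows = [{"patient_id": p, "index_date": d.isoformat()} for p, d in sorted(db.index_dates.items())]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_frequency_csv(table: LemmaFrequencyTable, path: str | Path) -> None:
    rows = [
        {"lemma": lemma, "frequency": freq, "forms": "|".join(sorted(forms))}
        for lemma, (freq, forms) in sorted(table.entries.items(), key=lambda kv: (-kv[1][0], kv[0]))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_vocabulary_txt(vocab: Vocabulary, path: str | Path) -> None:
    Path(path).write_text("\n".join(vocab.words) + ("\n" if vocab.words else ""), encoding="utf-8")


def read_vocabulary_txt(path: str | Path, min_count: int = 0) -> Vocabulary:
    words = [w for w in Path(path).read_text(encoding="utf-8").splitlines() if w.strip()]
    return Vocabulary(words=tuple(words), min_count=min_count)
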