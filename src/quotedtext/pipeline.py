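"""Pipeline orchestration: the two analyses, configuration and manifests.

``run_distribution`` reproduces the cohort-profile analysis: extract
quotations, compute per-patient index dates, derive the categorical cohort
and emit the counts/χ²/odds-ratio tables.  ``run_content`` reproduces the
content analysis: one-word quotations → lemmatize → frequency threshold →
embed → k-means scan → silhouette-guided, labeler-driven selection.

Each run writes a manifest recording the configuration snapshot (and its
hash), library versions, the stage-by-stage record funnel (quotes found,
removed as blank/html, one-word count, unique lemmas, vocabulary size, OOV
count) and wall-clock timings, so any output file can be traced to the
exact configuration that produced it.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from . import io as qio
from .clustering import (
    KScan,
    SelectionOutcome,
    cluster_report,
    make_purity_labeler,
    scan_k,
    select_solution,
)
from .cohort import derive_cohort, distribution_report
from .embeddings import WordVectorTable, load_word_vectors, map_vocabulary, train_cbow
from .extraction import (
    DEFAULT_DIALECT,
    QuoteDialect,
    build_quote_database,
)
from .normalization import build_lemma_frequency, filter_min_count, normalize_token
from .extraction import _WORD_RE

__all__ = ["PipelineConfig", "RunManifest", "run_distribution", "run_content", "EmptyResult"]


class EmptyResult(Exception):
    """Raised when a stage legitimately yields nothing to analyse (e.g. the
    frequency threshold removes the whole vocabulary)."""


@dataclass
class PipelineConfig:
    notes_path: str | None = None
    registry_path: str | None = None
    vectors_path: str | None = None
    output_dir: str = "output"
    dialect: QuoteDialect = field(default_factory=QuoteDialect)
    min_count: int = 20
    k_min: int = 2
    k_max: int = 20
    restarts: int = 10
    referral_scheme: str = "table3"
    seed: int = 0
    cbow_dimension: int = 100
    cbow_window: int = 5
    cbow_min_count: int = 5
    cbow_epochs: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        dialect = QuoteDialect(**data.pop("dialect", {}))
        return cls(dialect=dialect, **data)

    def snapshot(self) -> dict:
        d = asdict(self)
        return d

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config: dict
    config_hash: str
    versions: dict
    counts: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str), encoding="utf-8")


def _versions() -> dict:
    import numpy, pandas, sklearn, statsmodels  # noqa: PLC0415

    import quotedtext

    return {
        "quotedtext": quotedtext.__version__,
        "numpy": numpy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def _new_manifest(config: PipelineConfig) -> RunManifest:
    return RunManifest(config=config.snapshot(), config_hash=config.hash(), versions=_versions())


def run_distribution(config: PipelineConfig, notes=None, registry=None):
    """Extract quotations, flag quote presence, derive the cohort, and emit
    the distribution tables.

    ``notes``/``registry`` may be passed in memory; otherwise they are read
    from the configured paths.  Returns (report dict, manifest).
    """
    manifest = _new_manifest(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if notes is None:
        if not config.notes_path or not Path(config.notes_path).exists():
            raise FileNotFoundError(f"notes file not found: {config.notes_path!r}")
        notes = qio.read_notes_jsonl(config.notes_path)
    if registry is None:
        if not config.registry_path or not Path(config.registry_path).exists():
            raise FileNotFoundError(f"registry file not found: {config.registry_path!r}")
        registry = qio.read_registry_csv(config.registry_path)

    db = build_quote_database(notes, config.dialect)
    manifest.timings["extract_s"] = round(time.perf_counter() - t0, 3)
    manifest.counts.update(
        {
            "notes": len(notes),
            "quotes_retained": len(db.spans),
            "removed_blank": db.removal_counts.get("blank", 0),
            "removed_html": db.removal_counts.get("html", 0),
            "quotes_found": len(db.spans)
            + db.removal_counts.get("blank", 0)
            + db.removal_counts.get("html", 0),
            "patients_with_quotes": len(db.index_dates),
        }
    )

    registry = registry.copy()
    registry["has_quote"] = registry["patient_id"].astype(str).isin(db.index_dates)
    cohort = derive_cohort(registry, referral_scheme=config.referral_scheme)
    report = distribution_report(cohort)

    qio.write_spans_csv(db, out / "quotes.csv")
    qio.write_index_dates_csv(db, out / "index_dates.csv")
    for name, frame in report.items():
        path = out / f"distribution_{name}.csv"
        frame.to_csv(path, index=False)
        manifest.outputs.append(str(path))
    manifest.timings["total_s"] = round(time.perf_counter() - t0, 3)
    manifest.write(out / "manifest_distribution.json")
    return report, manifest


def run_content(
    config: PipelineConfig,
    notes=None,
    vectors: WordVectorTable | None = None,
    labeler: Callable | None = None,
    training_corpus: Sequence[Sequence[str]] | None = None,
):
    """One-word quotation content analysis.

    Stages: extract → keep word_count==1 → lower-case + lemmatize →
    frequency threshold → map into the vector space (loading pre-trained
    vectors, or training CBOW on ``training_corpus`` / the note texts) →
    k scan → silhouette-ordered labeler selection.  Returns
    (SelectionOutcome, KScan, Vocabulary, manifest).  Raises EmptyResult if
    nothing survives the frequency threshold.
    """
    manifest = _new_manifest(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if notes is None:
        if not config.notes_path or not Path(config.notes_path).exists():
            raise FileNotFoundError(f"notes file not found: {config.notes_path!r}")
        notes = qio.read_notes_jsonl(config.notes_path)

    db = build_quote_database(notes, config.dialect)
    one_word = sum(1 for s in db.spans if s.word_count == 1)
    freq_table = build_lemma_frequency(db)
    vocab = filter_min_count(freq_table, config.min_count)
    manifest.counts.update(
        {
            "quotes_retained": len(db.spans),
            "one_word_quotes": one_word,
            "unique_lemmas": len(freq_table.entries),
            "vocabulary_size": len(vocab.words),
        }
    )
    if not vocab.words:
        manifest.write(out / "manifest_content.json")
        raise EmptyResult(
            f"no lemma reaches min_count={config.min_count}; nothing to cluster"
        )

    if vectors is None:
        if config.vectors_path:
            vectors = load_word_vectors(config.vectors_path)
        else:
            corpus = training_corpus
            if corpus is None:
                corpus = [
                    [normalize_token(t) for t in _WORD_RE.findall(n.text.lower())]
                    for n in notes
                ]
            vectors = train_cbow(
                corpus,
                dimension=config.cbow_dimension,
                window=config.cbow_window,
                min_count=config.cbow_min_count,
                epochs=config.cbow_epochs,
                seed=config.seed,
            )
    matrix, retained, oov = map_vocabulary(vocab.words, vectors)
    manifest.counts["oov_words"] = len(oov)

    k_max = min(config.k_max, matrix.shape[0])
    k_min = min(config.k_min, k_max)
    scan = scan_k(
        matrix,
        k_min=k_min,
        k_max=k_max,
        restarts=config.restarts,
        seed=config.seed,
        words=retained,
        oov_words=oov,
    )
    freqs = freq_table.frequencies()
    if labeler is None:
        labeler = lambda report: {c["cluster_id"]: ("unlabelled", True) for c in report.clusters}  # noqa: E731
    outcome = select_solution(scan, freqs, labeler)

    qio.write_vocabulary_txt(vocab, out / "vocabulary.txt")
    qio.write_frequency_csv(freq_table, out / "lemma_frequencies.csv")
    scan.table.to_csv(out / "k_scan.csv", index=False)
    if outcome.report is not None:
        outcome.report.to_frame().to_csv(out / "cluster_report.csv", index=False)
    pd.DataFrame(outcome.audit_trail).to_csv(out / "selection_audit.csv", index=False)
    manifest.outputs.extend(
        str(out / f) for f in ["vocabulary.txt", "lemma_frequencies.csv", "k_scan.csv", "selection_audit.csv"]
    )
    manifest.timings["total_s"] = round(time.perf_counter() - t0, 3)
    manifest.write(out / "manifest_content.json")
    return outcome, scan, vocab, manifest
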