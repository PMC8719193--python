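"""Synthetic EHR generator: registries, notes with planted quotations, and
topic-structured corpora.

The real clinical records this analysis was designed for cannot leave their
host firewall, so every downstream stage is exercised on synthetic data
with the statistical structure the analysis assumes:

* a patient registry whose quote-presence flag follows a known logistic
  model over the derived categorical variables (so parameter recovery can
  be checked against the generating truth);
* clinical notes of template filler text with quotation spans planted at
  known offsets (the gold standard), using a configurable mix of straight,
  curly and single delimiters, a positively skewed word-length
  distribution, and optional adversarial hazards (apostrophes, html-tag
  quotes, blank quotes, unbalanced delimiters);
* a topic-structured token corpus whose vocabulary clusters recover the
  planted semantic groups once embedded.

All generators are deterministic given the seed carried in their config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import (
    AGE_BANDS,
    CONTACTS_BANDS,
    DX_GROUPS,
    IMD_BANDS,
    REFERRAL_BANDS_TABLE3,
)
from .extraction import ClinicalNote, GoldAnnotation

__all__ = [
    "RegistryConfig",
    "NoteConfig",
    "generate_registry",
    "generate_notes",
    "generate_topic_corpus",
    "DEFAULT_TOPIC_VOCAB",
]

# ---------------------------------------------------------------------------
# registry generation

#: marginal category shares of the derived analysis variables, shaped like a
#: large urban secondary mental-healthcare census cohort
def _default_prevalences() -> dict[str, dict[str, float]]:
    def norm(labels: Sequence[str], weights: Sequence[float]) -> dict[str, float]:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        return dict(zip(labels, w.tolist()))

    return {
        "gender": norm(["Female", "Male"], [15992, 17459]),
        "ethnicity5": norm(
            ["White European", "Black", "Asian", "Other"], [14560, 7752, 1440, 1864]
        ),
        "age_group": norm(AGE_BANDS, [6850, 5284, 5785, 4947, 5004, 3083, 1299, 882, 328]),
        "imd_band": norm(IMD_BANDS, [11019, 10265, 10963]),
        "dx_group": norm(
            DX_GROUPS,
            [631, 2271, 5230, 2798, 2424, 543, 1165, 484, 1418, 2187, 280, 200, 13868],
        ),
        "inpatient_12m": norm(["no", "yes"], [33042, 457]),
        "contacts_band": norm(CONTACTS_BANDS, [16895, 7434, 3347, 2277, 1431, 1292, 823]),
        "referral_band": norm(
            REFERRAL_BANDS_TABLE3, [6110, 1932, 1781, 2028, 2469, 3789, 6138, 8995]
        ),
    }


#: generating log-odds of quote presence.  Nominal terms are keyed
#: (variable, category); ordinal terms are keyed (variable, "per_category")
#: and multiply the 1-based category score.  Signs and rough magnitudes
#: follow the unadjusted association pattern seen in routine mental-health
#: records: inpatient care and psychosis diagnoses strongly positive,
#: recency of first referral negative.
def _default_coefficients() -> dict:
    return {
        "intercept": -1.0,
        ("gender", "Male"): 0.19,
        ("ethnicity5", "Black"): 0.79,
        ("ethnicity5", "Asian"): 0.17,
        ("ethnicity5", "Other"): -0.15,
        ("inpatient_12m", "yes"): 2.28,
        ("dx_group", "F2x"): 1.2,
        ("dx_group", "Not recorded"): -1.8,
        ("age_group", "per_category"): 0.1,
        ("imd_band", "per_category"): 0.15,
        ("contacts_band", "per_category"): 0.45,
        ("referral_band", "per_category"): -0.5,
    }


def _default_missingness() -> dict[str, float]:
    return {
        "gender": 0.0014,
        "ethnicity5": 0.235,
        "age_group": 0.0011,
        "imd_band": 0.0374,
        "dx_group": 0.0,
        "inpatient_12m": 0.0,
        "contacts_band": 0.0,
        "referral_band": 0.0077,
    }


@dataclass
class RegistryConfig:
    n_patients: int = 2000
    category_prevalences: dict[str, dict[str, float]] = field(
        default_factory=_default_prevalences
    )
    quote_model_coefficients: dict = field(default_factory=_default_coefficients)
    missingness_rates: dict[str, float] = field(default_factory=_default_missingness)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be ≥ 1")
        # per-variable overrides merge over the default prevalence vectors,
        # so a config may pin just the variables it cares about
        merged = _default_prevalences()
        merged.update(self.category_prevalences)
        self.category_prevalences = merged
        for var, pv in self.category_prevalences.items():
            total = sum(pv.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"prevalences for {var!r} sum to {total}, not 1")
            if any(p < 0 for p in pv.values()):
                raise ValueError(f"negative prevalence in {var!r}")
        for var, r in self.missingness_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"missingness rate for {var!r} outside [0,1]")


_ETH_RAW = {
    "White European": ["British", "Irish", "Any other white background"],
    "Black": ["African", "Caribbean", "Any other black background"],
    "Asian": ["Indian", "Pakistani", "Chinese", "White and Asian"],
    "Other": ["Any other mixed background", "Any other ethnic group"],
}
_DX_CODE = {
    **{f"F{i}x": f"F{i}0" for i in range(10)},
    "Zx": "Z63",
    "Any other letter x": "G40",
    "Not recorded": "",
}
_AGE_RANGE = dict(
    zip(AGE_BANDS, [(1, 15), (16, 25), (26, 35), (36, 45), (46, 55), (56, 65), (66, 75), (76, 85), (86, 95)])
)
_CONTACT_RANGE = dict(
    zip(CONTACTS_BANDS, [(0, 0), (1, 7), (8, 14), (15, 21), (22, 28), (29, 42), (43, 60)])
)
_REFERRAL_RANGE = dict(
    zip(
        REFERRAL_BANDS_TABLE3,
        [(1990, 2006), (2007, 2008), (2009, 2010), (2011, 2012), (2013, 2014), (2015, 2016), (2017, 2018), (2019, 2020)],
    )
)


def generate_registry(
    config: RegistryConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a synthetic patient registry.

    Categories are drawn per the configured prevalences; the quote flag is
    Bernoulli with logit equal to the configured linear predictor over the
    TRUE categories; missing values are then injected independently per
    variable (so quote presence depends on the underlying truth, and the
    missingness is MCAR).  With ``return_truth`` the pre-missingness derived
    categories and linear predictor are returned alongside.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    truth = pd.DataFrame({"patient_id": [f"P{i:06d}" for i in range(n)]})
    for var, pv in config.category_prevalences.items():
        labels = list(pv)
        truth[var] = rng.choice(labels, size=n, p=list(pv.values()))

    coefs = config.quote_model_coefficients
    eta = np.full(n, float(coefs.get("intercept", 0.0)))
    for var, pv in config.category_prevalences.items():
        labels = list(pv)
        per_cat = coefs.get((var, "per_category"))
        if per_cat is not None:
            score = truth[var].map({lab: i + 1 for i, lab in enumerate(labels)})
            eta += float(per_cat) * score.to_numpy(dtype=float)
        for i, lab in enumerate(labels):
            c = coefs.get((var, lab))
            if c is not None:
                eta += float(c) * (truth[var] == lab).to_numpy(dtype=float)
    p = 1.0 / (1.0 + np.exp(-eta))
    truth["linear_predictor"] = eta
    truth["has_quote"] = rng.random(n) < p

    # realise raw registry fields from the derived categories
    def uniform_int(band_map, series):
        lo = series.map(lambda b: band_map[b][0]).to_numpy()
        hi = series.map(lambda b: band_map[b][1]).to_numpy()
        return lo + (rng.random(n) * (hi - lo + 1)).astype(int)

    reg = pd.DataFrame({"patient_id": truth["patient_id"]})
    reg["gender"] = truth["gender"]
    reg["ethnicity_raw"] = [
        _ETH_RAW[g][rng.integers(len(_ETH_RAW[g]))] for g in truth["ethnicity5"]
    ]
    reg["age_years"] = uniform_int(_AGE_RANGE, truth["age_group"]).astype(float)
    imd_lo = truth["imd_band"].map({"0≤x≤20": 0.0, "20<x≤30": 20.0, "30<x≤93": 30.0}).to_numpy()
    imd_hi = truth["imd_band"].map({"0≤x≤20": 20.0, "20<x≤30": 30.0, "30<x≤93": 93.0}).to_numpy()
    reg["imd_score"] = imd_lo + rng.random(n) * (imd_hi - imd_lo)
    reg["icd10_code"] = truth["dx_group"].map(_DX_CODE)
    reg["inpatient_12m"] = truth["inpatient_12m"]
    reg["contacts_12m"] = uniform_int(_CONTACT_RANGE, truth["contacts_band"]).astype(float)
    reg["first_referral_year"] = uniform_int(_REFERRAL_RANGE, truth["referral_band"]).astype(float)
    reg["has_quote"] = truth["has_quote"]

    raw_col = {
        "gender": "gender",
        "ethnicity5": "ethnicity_raw",
        "age_group": "age_years",
        "imd_band": "imd_score",
        "dx_group": "icd10_code",
        "inpatient_12m": "inpatient_12m",
        "contacts_band": "contacts_12m",
        "referral_band": "first_referral_year",
    }
    for var, rate in config.missingness_rates.items():
        if rate <= 0:
            continue
        col = raw_col[var]
        mask = rng.random(n) < rate
        if reg[col].dtype == float:
            reg.loc[mask, col] = np.nan
        else:
            reg.loc[mask, col] = ""
    if return_truth:
        return reg, truth
    return reg


# ---------------------------------------------------------------------------
# note generation

DEFAULT_TOPIC_VOCAB: dict[str, list[str]] = {
    "symptoms": ["voices", "paranoia", "anxiety", "depression", "stress", "panic",
                 "crisis", "episode", "breakdown", "psychosis"],
    "sentiment": ["fine", "good", "happy", "okay", "alright", "bad",
                  "terrible", "awful", "low", "sad"],
    "people": ["mother", "father", "friend", "sister", "brother", "family",
               "partner", "neighbour", "carer", "nurse"],
}

_FILLER = (
    "patient attended the clinic today and was seen by the community team for "
    "routine review of medication and mental state with no acute concerns noted "
    "plan to continue current care arrangements and follow up in two weeks"
).split()


def _geometric_like_lengths(p1: float = 0.27, max_len: int = 30) -> dict[int, float]:
    """Positively skewed word-length pmf with P(1 word) ≈ p1 and a long tail."""
    decay = 1.0 - p1
    raw = {k: p1 * decay ** (k - 1) for k in range(1, max_len)}
    raw[max_len] = 1.0 - sum(raw.values())
    return raw


@dataclass
class NoteConfig:
    quotes_per_note: dict[int, float] = field(
        default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1}
    )
    length_distribution: dict[int, float] = field(default_factory=_geometric_like_lengths)
    delimiter_mix: dict[str, float] = field(
        default_factory=lambda: {"straight_double": 0.6, "curly_double": 0.4, "single": 0.0}
    )
    adversarial_rates: dict[str, float] = field(
        default_factory=lambda: {"apostrophe": 0.0, "html": 0.0, "blank": 0.0, "unbalanced": 0.0}
    )
    topic_vocab: dict[str, list[str]] = field(
        default_factory=lambda: {t: list(ws) for t, ws in DEFAULT_TOPIC_VOCAB.items()}
    )
    notes_per_patient: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name, dist in (("quotes_per_note", self.quotes_per_note),
                           ("length_distribution", self.length_distribution),
                           ("delimiter_mix", self.delimiter_mix)):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"negative probability in {name}")
        for k, r in self.adversarial_rates.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"adversarial rate {k!r} outside [0,1]")
        seen: set[str] = set()
        for topic, words in self.topic_vocab.items():
            overlap = seen & set(words)
            if overlap:
                raise ValueError(f"topic word lists are not disjoint: {sorted(overlap)}")
            seen |= set(words)
        needs_quotes = any(k > 0 and p > 0 for k, p in self.quotes_per_note.items())
        if needs_quotes and not any(self.topic_vocab.values()):
            raise ValueError("nonzero quote rate with an empty topic vocabulary")


_DELIMS = {
    "straight_double": ('"', '"'),
    "curly_double": ("“", "”"),
    "single": ("'", "'"),
}


def _draw(rng: np.random.Generator, dist: dict) -> object:
    keys = list(dist)
    return keys[rng.choice(len(keys), p=np.asarray(list(dist.values()), dtype=float))]


def generate_notes(
    registry: pd.DataFrame, config: NoteConfig
) -> tuple[list[ClinicalNote], list[GoldAnnotation]]:
    """Generate template notes with quotation spans planted at recorded
    offsets.

    Patients flagged has_quote receive at least one well-formed quotation;
    unflagged patients receive none.  Adversarial hazards (possessive
    apostrophes, html-tag quotes, blank quotes, stray unbalanced
    delimiters) are planted per note with the configured probabilities; the
    gold annotations list only the well-formed, non-blank, non-html spans —
    exactly what a correct extract-and-clean pass should retain.
    """
    if registry.empty:
        raise ValueError("registry is empty")
    rng = np.random.default_rng(config.seed)
    topics = [t for t, ws in config.topic_vocab.items() if ws]
    notes: list[ClinicalNote] = []
    golds: list[GoldAnnotation] = []
    base_date = datetime(2019, 1, 1)

    for _, patient in registry.iterrows():
        has_quote = bool(patient["has_quote"])
        can_quote = any(k > 0 and p > 0 for k, p in config.quotes_per_note.items())
        quote_notes = []
        for j in range(config.notes_per_patient):
            n_quotes = int(_draw(rng, config.quotes_per_note)) if has_quote else 0
            quote_notes.append(n_quotes)
        if has_quote and can_quote and sum(quote_notes) == 0:
            quote_notes[0] = 1

        for j, n_quotes in enumerate(quote_notes):
            note_id = f"{patient['patient_id']}-N{j}"
            parts: list[str] = []
            pos = 0
            spans: list[tuple[int, int, str]] = []

            def emit(text: str) -> None:
                nonlocal pos
                parts.append(text)
                pos += len(text)

            n_sentences = int(rng.integers(3, 7))
            quote_slots = set(rng.choice(n_sentences, size=min(n_quotes, n_sentences), replace=False)) if n_quotes else set()
            adv = {k: rng.random() < r for k, r in config.adversarial_rates.items()}
            adv_slot = int(rng.integers(n_sentences))

            for s_idx in range(n_sentences):
                if s_idx > 0:
                    emit("\n\n" if rng.random() < 0.3 else " ")
                words = [ _FILLER[rng.integers(len(_FILLER))] for _ in range(int(rng.integers(5, 10))) ]
                emit(" ".join(words))
                if s_idx in quote_slots:
                    k = int(_draw(rng, config.length_distribution))
                    topic = topics[rng.integers(len(topics))]
                    vocab = config.topic_vocab[topic]
                    content = " ".join(vocab[rng.integers(len(vocab))] for _ in range(k))
                    kind = _draw(rng, config.delimiter_mix)
                    op, cl = _DELIMS[kind]
                    emit(" patient said ")
                    start = pos
                    emit(op + content + cl)
                    spans.append((start, pos, op + content + cl))
                if s_idx == adv_slot:
                    if adv.get("apostrophe"):
                        emit(" the patient's mood wasn't low")
                    if adv.get("html"):
                        emit(' noted "<br>" in record')
                    if adv.get("blank"):
                        emit(' recorded "" by mistake')
                    if adv.get("unbalanced"):
                        emit(' a stray " mark appears here')
                emit(".")
            text = "".join(parts)
            ts = base_date + timedelta(days=int(rng.integers(0, 365)), hours=j)
            notes.append(
                ClinicalNote(note_id=note_id, patient_id=str(patient["patient_id"]), timestamp=ts, text=text)
            )
            golds.append(GoldAnnotation(note_id=note_id, spans=tuple(spans)))
    return notes, golds


# ---------------------------------------------------------------------------
# topic corpus generation

def generate_topic_corpus(
    config: NoteConfig, n_sentences: int, noise: float = 0.1
) -> tuple[list[list[str]], dict[str, str]]:
    """Generate a token corpus with planted topic co-occurrence structure.

    Each sentence draws a topic, then fills 8–12 token slots from that
    topic's word list, replacing a ``noise`` fraction with words from other
    topics.  CBOW embeddings trained on the output place same-topic words
    closer together than cross-topic words, so vocabulary clustering can be
    validated against the returned word → topic map.
    """
    topics = {t: ws for t, ws in config.topic_vocab.items() if ws}
    if not topics:
        raise ValueError("topic vocabulary is empty")
    if n_sentences < len(topics):
        raise ValueError("need at least one sentence per topic")
    rng = np.random.default_rng(config.seed)
    names = list(topics)
    corpus: list[list[str]] = []
    for i in range(n_sentences):
        topic = names[i % len(names)] if i < len(names) else names[rng.integers(len(names))]
        own = topics[topic]
        sent: list[str] = []
        for _ in range(int(rng.integers(8, 13))):
            if len(names) > 1 and rng.random() < noise:
                other = names[rng.integers(len(names))]
                sent.append(topics[other][rng.integers(len(topics[other]))])
            else:
                sent.append(own[rng.integers(len(own))])
        corpus.append(sent)
    topic_map = {w: t for t, ws in topics.items() for w in ws}
    return corpus, topic_map
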