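"""Word vectors: word2vec-text I/O and CBOW training.

The clustering stage consumes a word → vector map.  In production this is a
pre-trained embedding file in the classic word2vec text format (header line
"<vocab> <dim>", then one word and its floats per line).  For end-to-end
testing on synthetic corpora the package also trains Continuous Bag of Words
(CBOW) embeddings with negative sampling, implemented on numpy: the model
predicts a centre word from the mean of its context-window input vectors,
maximising the sigmoid score of the true centre against k sampled noise
words.  Training is single-threaded and fully deterministic given a seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = ["WordVectorTable", "load_word_vectors", "save_word_vectors", "train_cbow", "map_vocabulary"]


@dataclass
class WordVectorTable:
    dimension: int
    vectors: dict[str, np.ndarray]
    source: str = ""

    def __post_init__(self) -> None:
        for w, v in self.vectors.items():
            if v.shape != (self.dimension,):
                raise ValueError(
                    f"vector for {w!r} has shape {v.shape}, expected ({self.dimension},)"
                )

    def __contains__(self, word: str) -> bool:
        return word in self.vectors

    def __len__(self) -> int:
        return len(self.vectors)


def load_word_vectors(path: str | Path) -> WordVectorTable:
    """Read a word2vec text file.

    The header line declares vocabulary size and dimension.  A duplicated
    word keeps its last vector (with a warning); a row with the wrong number
    of fields raises with its line number.
    """
    path = Path(path)
    vectors: dict[str, np.ndarray] = {}
    with path.open("r", encoding="utf-8") as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError(f"{path}: malformed header line")
        n_words, dim = int(header[0]), int(header[1])
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"{path}: line {lineno} has {len(parts) - 1} values, expected {dim}"
                )
            word = parts[0]
            if word in vectors:
                warnings.warn(f"{path}: duplicate word {word!r}, last occurrence wins")
            vectors[word] = np.asarray(parts[1:], dtype=np.float64)
    if len(vectors) != n_words:
        warnings.warn(
            f"{path}: header declared {n_words} words but {len(vectors)} parsed"
        )
    return WordVectorTable(dimension=dim, vectors=vectors, source=str(path))


def save_word_vectors(table: WordVectorTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"{len(table.vectors)} {table.dimension}\n")
        for word, vec in table.vectors.items():
            fh.write(word + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")


def train_cbow(
    corpus: Sequence[Sequence[str]],
    dimension: int = 100,
    window: int = 5,
    min_count: int = 5,
    epochs: int = 5,
    seed: int = 0,
    negative: int = 5,
    learning_rate: float = 0.025,
) -> WordVectorTable:
    """Train CBOW word embeddings with negative sampling on a token corpus.

    Vocabulary = words occurring at least ``min_count`` times; rarer words
    are dropped from sentences before windowing.  Noise words are drawn from
    the unigram distribution raised to 3/4.  The learning rate decays
    linearly to 10% of its initial value over training.
    """
    if not corpus:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for sent in corpus:
        for w in sent:
            counts[w] = counts.get(w, 0) + 1
    vocab = sorted(w for w, c in counts.items() if c >= min_count)
    if not vocab:
        raise ValueError("no word reaches min_count; effective vocabulary is empty")
    index = {w: i for i, w in enumerate(vocab)}
    sents = [[index[w] for w in sent if w in index] for sent in corpus]
    sents = [s for s in sents if len(s) >= 2]
    if not sents:
        raise ValueError("no sentence retains ≥2 in-vocabulary words")

    rng = np.random.default_rng(seed)
    V = len(vocab)
    w_in = (rng.random((V, dimension)) - 0.5) / dimension
    w_out = np.zeros((V, dimension))

    freq = np.array([counts[w] for w in vocab], dtype=np.float64) ** 0.75
    noise_p = freq / freq.sum()

    # flatten all (centre, padded context) examples once; contexts are padded
    # with -1 and averaged over their true length
    centers: list[int] = []
    contexts: list[list[int]] = []
    for s in sents:
        for pos, centre in enumerate(s):
            ctx = s[max(0, pos - window) : pos] + s[pos + 1 : pos + 1 + window]
            if ctx:
                centers.append(centre)
                contexts.append(ctx)
    max_ctx = max(len(c) for c in contexts)
    ctx_arr = np.full((len(centers), max_ctx), -1, dtype=np.int64)
    for i, c in enumerate(contexts):
        ctx_arr[i, : len(c)] = c
    centers_arr = np.asarray(centers, dtype=np.int64)
    ctx_len = (ctx_arr >= 0).sum(axis=1).astype(np.float64)

    n_examples = len(centers_arr)
    batch = 512
    total_steps = epochs * ((n_examples + batch - 1) // batch)
    step = 0
    for _epoch in range(epochs):
        order = rng.permutation(n_examples)
        for start in range(0, n_examples, batch):
            lr = learning_rate * max(0.1, 1.0 - step / max(total_steps, 1))
            step += 1
            idx = order[start : start + batch]
            B = len(idx)
            ctx = ctx_arr[idx]  # (B, C)
            mask = ctx >= 0
            safe_ctx = np.where(mask, ctx, 0)
            h = (w_in[safe_ctx] * mask[:, :, None]).sum(axis=1) / ctx_len[idx][:, None]

            neg = rng.choice(V, size=(B, negative), p=noise_p)
            targets = np.concatenate([centers_arr[idx][:, None], neg], axis=1)  # (B, 1+k)
            labels = np.zeros((B, 1 + negative))
            labels[:, 0] = 1.0

            out = w_out[targets]  # (B, 1+k, d)
            scores = np.einsum("bkd,bd->bk", out, h)
            g = (labels - 1.0 / (1.0 + np.exp(-scores))) * lr  # (B, 1+k)

            grad_h = np.einsum("bk,bkd->bd", g, out)
            grad_out = g[:, :, None] * h[:, None, :]
            np.add.at(w_out, targets, grad_out)
            spread = (grad_h / ctx_len[idx][:, None])[:, None, :] * mask[:, :, None]
            np.add.at(w_in, safe_ctx, spread)

    return WordVectorTable(
        dimension=dimension,
        vectors={w: w_in[i].copy() for w, i in index.items()},
        source=f"cbow(dim={dimension},window={window},min_count={min_count},epochs={epochs},seed={seed})",
    )


def map_vocabulary(
    words: Iterable[str], table: WordVectorTable
) -> tuple[np.ndarray, list[str], list[str]]:
    """Align a vocabulary with a vector table.

    Returns (matrix, retained_words, oov_words): matrix rows follow the
    original vocabulary order restricted to words present in the table; the
    out-of-vocabulary remainder is returned for bookkeeping.  Raises if no
    word has a vector.
    """
    retained: list[str] = []
    oov: list[str] = []
    for w in words:
        (retained if w in table.vectors else oov).append(w)
    if not retained:
        raise ValueError("no vocabulary word has a vector (everything is OOV)")
    matrix = np.vstack([table.vectors[w] for w in retained])
    return matrix, retained, oov
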