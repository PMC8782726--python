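"""Minimal deterministic skip-gram-with-negative-sampling trainer.

Trains token embeddings over substructure sentences with plain numpy
mini-batch SGD. Two deliberate simplifications relative to classic word2vec
keep training bit-reproducible for a fixed seed: the context window is fixed
(no per-position random shrinking) and frequent-token subsampling is off.
Single-threaded by construction.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import expit

from .errors import EmptyResultError, ConfigError


@dataclass(frozen=True)
class SgnsHyperparameters:
    vector_size: int = 100
    window: int = 10
    min_count: int = 1
    epochs: int = 5
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 0


def _build_vocab(sentences: Sequence[Sequence[str]], min_count: int):
    counts: dict[str, int] = {}
    for sent in sentences:
        for tok in sent:
            counts[tok] = counts.get(tok, 0) + 1
    # frequency-descending, token ascending: a stable, seed-independent order
    vocab = sorted((t for t, c in counts.items() if c >= min_count),
                   key=lambda t: (-counts[t], t))
    return vocab, counts


def _skipgram_pairs(sentences, token_index, window):
    centers, contexts = [], []
    for sent in sentences:
        idx = [token_index[t] for t in sent if t in token_index]
        n = len(idx)
        for i, ci in enumerate(idx):
            for j in range(max(0, i - window), min(n, i + window + 1)):
                if j != i:
                    centers.append(ci)
                    contexts.append(idx[j])
    return (np.asarray(centers, dtype=np.int64),
            np.asarray(contexts, dtype=np.int64))


def train_sgns(sentences: Sequence[Sequence[str]],
               hp: SgnsHyperparameters = SgnsHyperparameters(),
               batch_size: int = 2048):
    """Train SGNS embeddings; returns (vocab list, counts dict, (V, d) matrix).

    Raises
    ------
    EmptyResultError
        If no token reaches ``min_count`` occurrences.
    """
    if not sentences:
        raise EmptyResultError("empty sentence corpus: nothing to train on")
    if hp.vector_size < 2:
        raise ConfigError(f"vector_size must be >= 2, got {hp.vector_size}")
    if hp.epochs < 1:
        raise ConfigError(f"epochs must be >= 1, got {hp.epochs}")

    vocab, counts = _build_vocab(sentences, hp.min_count)
    if not vocab:
        raise EmptyResultError(
            f"empty vocabulary: no token occurs at least min_count={hp.min_count} times"
        )
    token_index = {t: i for i, t in enumerate(vocab)}
    V, d = len(vocab), hp.vector_size

    rng = np.random.default_rng(hp.seed)
    w_in = (rng.random((V, d)) - 0.5) / d
    w_out = np.zeros((V, d))

    centers, contexts = _skipgram_pairs(sentences, token_index, hp.window)
    n_pairs = centers.size
    if n_pairs == 0:
        # single-token sentences only: vectors stay at initialization
        return vocab, counts, w_in

    # unigram^0.75 negative-sampling distribution
    freq = np.array([counts[t] for t in vocab], dtype=np.float64) ** 0.75
    neg_cdf = np.cumsum(freq / freq.sum())

    n_batches_total = hp.epochs * ((n_pairs + batch_size - 1) // batch_size)
    batch_no = 0
    for _ in range(hp.epochs):
        order = rng.permutation(n_pairs)
        for start in range(0, n_pairs, batch_size):
            sel = order[start:start + batch_size]
            c = centers[sel]
            B = c.size
            neg = np.searchsorted(neg_cdf, rng.random((B, hp.negative)))
            targets = np.concatenate([contexts[sel][:, None], neg], axis=1)  # (B, 1+K)
            labels = np.zeros((B, 1 + hp.negative))
            labels[:, 0] = 1.0

            lr = hp.alpha + (hp.min_alpha - hp.alpha) * (batch_no / max(1, n_batches_total - 1))
            batch_no += 1

            h = w_in[c]                                   # (B, d)
            u = np.einsum("bd,bkd->bk", h, w_out[targets])
            g = (expit(u) - labels) * lr                  # (B, 1+K)

            grad_in = np.einsum("bk,bkd->bd", g, w_out[targets])
            grad_out = g[:, :, None] * h[:, None, :]      # (B, 1+K, d)
            # average the accumulated gradient per parameter row: frequent
            # tokens appear many times per batch and summed updates diverge
            flat_t = targets.ravel()
            delta_out = np.zeros_like(w_out)
            np.add.at(delta_out, flat_t, grad_out.reshape(-1, d))
            cnt_out = np.bincount(flat_t, minlength=V).astype(np.float64)
            w_out -= delta_out / np.maximum(cnt_out, 1.0)[:, None]
            delta_in = np.zeros_like(w_in)
            np.add.at(delta_in, c, grad_in)
            cnt_in = np.bincount(c, minlength=V).astype(np.float64)
            w_in -= delta_in / np.maximum(cnt_in, 1.0)[:, None]

    return vocab, counts, w_in


def save_model(path: str | Path, vocab: Sequence[str], counts: dict[str, int],
               vectors: np.ndarray, hp: SgnsHyperparameters,
               card_lines: Sequence[str] = ()) -> None:
    """Serialize a trained model as a directory (vocab.tsv + vectors + card)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    with open(path / "vocab.tsv", "w") as fh:
        fh.write("token\tindex\tfrequency\n")
        for i, tok in enumerate(vocab):
            fh.write(f"{tok}\t{i}\t{counts[tok]}\n")
    np.save(path / "vectors.npy", vectors)
    (path / "hyperparameters.json").write_text(json.dumps(asdict(hp), indent=2))
    if card_lines:
        (path / "model_card.txt").write_text("\n".join(card_lines) + "\n")


def load_model(path: str | Path):
    """Load (vocab, counts, vectors, hyperparameters) from :func:`save_model` output."""
    path = Path(path)
    vocab, counts = [], {}
    with open(path / "vocab.tsv") as fh:
        next(fh)
        for line in fh:
            tok, _, freq = line.rstrip("\n").split("\t")
            vocab.append(tok)
            counts[tok] = int(freq)
    vectors = np.load(path / "vectors.npy")
    hp = SgnsHyperparameters(**json.loads((path / "hyperparameters.json").read_text()))
    if vectors.shape[0] != len(vocab):
        raise EmptyResultError(f"corrupt model at {path}: vocab/vector size mismatch")
    return vocab, counts, vectors, hp
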