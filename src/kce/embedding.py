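"""Skip-gram negative-sampling (SGNS) concept embeddings.

Trains 100-dimensional word/concept vectors over the prepared token corpus.
For a center token c and an observed context token o within a +/-``window``
radius, the per-pair objective is

    log sigma(u_o . v_c) + sum_{i=1..K} log sigma(-u_{n_i} . v_c)

with K noise tokens n_i drawn from the unigram distribution raised to the
3/4 power.  Optimization is mini-batch stochastic gradient ascent with a
linearly decaying learning rate; input vectors v (the map f(.)) are the
final embedding, output vectors u exist only for training.

Default hyperparameters: window 5, min_count 5, batch 128, 20 negatives,
dimension 100.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "EmbeddingConfig",
    "Vocabulary",
    "EmbeddingModel",
    "MissingTokenError",
    "build_vocabulary",
    "sgns_loss_and_grad",
    "train_skipgram",
    "cosine",
]


class MissingTokenError(KeyError):
    """Lookup of a token that never entered the vocabulary."""

    def __init__(self, token: str):
        super().__init__(token)
        self.token = token

    def __str__(self) -> str:
        return f"token {self.token!r} is not in the embedding vocabulary"


@dataclass(frozen=True)
class EmbeddingConfig:
    window: int = 5
    min_count: int = 5
    batch_size: int = 128
    negatives: int = 20
    dim: int = 100
    epochs: int = 5
    learning_rate: float = 0.025
    noise_exponent: float = 0.75
    subsample: float = 0.0  # frequent-word subsampling threshold; 0 disables
    dynamic_window: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        for name in ("window", "min_count", "batch_size", "negatives", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class Vocabulary:
    """Token -> index map with corpus frequencies.

    Indices are assigned deterministically: descending frequency, ties broken
    by token string.
    """

    index: dict[str, int]
    counts: np.ndarray  # frequency per index

    def __len__(self) -> int:
        return len(self.index)

    def __contains__(self, token: str) -> bool:
        return token in self.index

    @property
    def tokens(self) -> list[str]:
        out = [""] * len(self.index)
        for tok, i in self.index.items():
            out[i] = tok
        return out


def build_vocabulary(corpus: Iterable[Sequence[str]], min_count: int = 5) -> Vocabulary:
    """Count tokens over token documents and keep those with freq >= min_count."""
    counts: dict[str, int] = {}
    for doc in corpus:
        tokens = doc.tokens if hasattr(doc, "tokens") else doc
        for tok in tokens:
            counts[tok] = counts.get(tok, 0) + 1
    kept = sorted(
        ((tok, n) for tok, n in counts.items() if n >= min_count),
        key=lambda kv: (-kv[1], kv[0]),
    )
    return Vocabulary(
        index={tok: i for i, (tok, _) in enumerate(kept)},
        counts=np.array([n for _, n in kept], dtype=np.int64),
    )


@dataclass
class EmbeddingModel:
    """The trained map f(.) from tokens to dense vectors (input vectors)."""

    vocabulary: Vocabulary
    input_vectors: np.ndarray  # (V, dim)
    output_vectors: np.ndarray | None = None
    epoch_losses: list[float] = field(default_factory=list)

    @property
    def dim(self) -> int:
        return self.input_vectors.shape[1]

    def __contains__(self, token: str) -> bool:
        return token in self.vocabulary

    def vector(self, token: str) -> np.ndarray:
        """Input vector of a vocabulary token; MissingTokenError otherwise."""
        try:
            return self.input_vectors[self.vocabulary.index[token]]
        except KeyError:
            raise MissingTokenError(token) from None

    def cosine(self, a: str, b: str) -> float:
        return cosine(self.vector(a), self.vector(b))

    # -- word2vec text format ------------------------------------------------

    def save(self, path: str | Path) -> None:
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "wt", encoding="utf-8") as fh:
            fh.write(f"{len(self.vocabulary)} {self.dim}\n")
            for tok in self.vocabulary.tokens:
                vec = self.input_vectors[self.vocabulary.index[tok]]
                fh.write(tok + " " + " ".join(format(x, ".8g") for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingModel":
        path = Path(path)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt", encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            index: dict[str, int] = {}
            vecs = np.empty((n, dim), dtype=np.float64)
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                index[parts[0]] = i
                vecs[i] = [float(x) for x in parts[1 : dim + 1]]
        vocab = Vocabulary(index=index, counts=np.zeros(n, dtype=np.int64))
        return cls(vocabulary=vocab, input_vectors=vecs)


def cosine(u: np.ndarray, w: np.ndarray) -> float:
    return float(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)))


# ---------------------------------------------------------------------------
# The SGNS objective and its gradient
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_sigmoid(x: np.ndarray) -> np.ndarray:
    # log sigma(x) = -log(1 + exp(-x)), numerically stable for both signs
    return -np.logaddexp(0.0, -x)


def sgns_loss_and_grad(
    v_c: np.ndarray, u_o: np.ndarray, u_neg: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Loss and analytic gradients of one (center, context, negatives) case.

    Returns ``(loss, grad_v_c, grad_u_o, grad_u_neg)`` where loss is the
    negated objective -[log sigma(u_o.v_c) + sum_i log sigma(-u_i.v_c)].
    ``u_neg`` has shape (K, dim).  This is the unit the trainer applies per
    pair and the surface checked against finite differences.
    """
    v_c = np.asarray(v_c, dtype=np.float64)
    u_o = np.asarray(u_o, dtype=np.float64)
    u_neg = np.atleast_2d(np.asarray(u_neg, dtype=np.float64))
    s_pos = float(np.dot(u_o, v_c))
    s_neg = u_neg @ v_c
    loss = -(_log_sigmoid(np.array([s_pos]))[0] + _log_sigmoid(-s_neg).sum())
    g_pos = _sigmoid(np.array([s_pos]))[0] - 1.0  # d loss / d s_pos
    g_neg = _sigmoid(s_neg)  # d loss / d s_neg_i
    grad_v = g_pos * u_o + g_neg @ u_neg
    grad_uo = g_pos * v_c
    grad_un = g_neg[:, None] * v_c[None, :]
    return float(loss), grad_v, grad_uo, grad_un


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _training_pairs(
    docs_idx: list[np.ndarray], window: int, dynamic: bool, rng: np.random.Generator
) -> np.ndarray:
    """All (center, context) index pairs within the window, as an (P, 2) array."""
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    for idx in docs_idx:
        n = len(idx)
        if n < 2:
            continue
        for off in range(1, window + 1):
            if dynamic:
                # shrinking window: pair kept with prob (window - off + 1)/window
                keep = rng.random(max(n - off, 0)) < (window - off + 1) / window
            else:
                keep = np.ones(max(n - off, 0), dtype=bool)
            left = idx[: n - off][keep]
            right = idx[off:][keep]
            centers.append(left)
            contexts.append(right)
            centers.append(right)  # symmetric: each side is a center once
            contexts.append(left)
    if not centers:
        return np.empty((0, 2), dtype=np.int64)
    return np.stack(
        [np.concatenate(centers).astype(np.int64), np.concatenate(contexts).astype(np.int64)],
        axis=1,
    )


try:  # compiled inner loop; the numpy path below implements identical math
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _train_batches_numba(
        W_in, W_out, centers, contexts, order, negs, batch_size, lr_start, lr_end
    ):
        """One epoch of mini-batch SGNS updates; returns summed loss.

        Gradients are computed from the vectors as they stand at the start of
        each mini-batch and applied afterwards, matching the numpy path.
        """
        P = len(order)
        D = W_in.shape[1]
        K = negs.shape[1]
        n_batches = (P + batch_size - 1) // batch_size
        total_loss = 0.0
        gv = np.empty((batch_size, D))
        guo = np.empty((batch_size, D))
        gun = np.empty((batch_size, K, D))
        for b in range(n_batches):
            lr = lr_start + (lr_end - lr_start) * (b / n_batches)
            lo = b * batch_size
            hi = min(lo + batch_size, P)
            for r in range(hi - lo):
                p = order[lo + r]
                c = centers[p]
                o = contexts[p]
                s_pos = 0.0
                for d in range(D):
                    s_pos += W_in[c, d] * W_out[o, d]
                # log sigma(x) = -log1p(exp(-x)), stable split by sign
                if s_pos >= 0:
                    total_loss += np.log1p(np.exp(-s_pos))
                    g_pos = 1.0 / (1.0 + np.exp(-s_pos)) - 1.0
                else:
                    total_loss += -s_pos + np.log1p(np.exp(s_pos))
                    e = np.exp(s_pos)
                    g_pos = e / (1.0 + e) - 1.0
                for d in range(D):
                    gv[r, d] = g_pos * W_out[o, d]
                    guo[r, d] = g_pos * W_in[c, d]
                for k in range(K):
                    n = negs[lo + r, k]
                    s_neg = 0.0
                    for d in range(D):
                        s_neg += W_in[c, d] * W_out[n, d]
                    if -s_neg >= 0:
                        total_loss += np.log1p(np.exp(s_neg))
                        g_neg = 1.0 / (1.0 + np.exp(-s_neg))
                    else:
                        total_loss += s_neg + np.log1p(np.exp(-s_neg))
                        e = np.exp(s_neg)
                        g_neg = e / (1.0 + e)
                    for d in range(D):
                        gv[r, d] += g_neg * W_out[n, d]
                        gun[r, k, d] = g_neg * W_in[c, d]
            for r in range(hi - lo):
                p = order[lo + r]
                c = centers[p]
                o = contexts[p]
                for d in range(D):
                    W_in[c, d] -= lr * gv[r, d]
                    W_out[o, d] -= lr * guo[r, d]
                for k in range(K):
                    n = negs[lo + r, k]
                    for d in range(D):
                        W_out[n, d] -= lr * gun[r, k, d]
        return total_loss


def _train_batches_numpy(
    W_in, W_out, centers, contexts, order, negs, batch_size, lr_start, lr_end
):
    """Vectorized-numpy twin of the compiled kernel (same math, same draws)."""
    P = len(order)
    dim = W_in.shape[1]
    n_batches = (P + batch_size - 1) // batch_size
    total_loss = 0.0
    for b in range(n_batches):
        lr = lr_start + (lr_end - lr_start) * (b / n_batches)
        sel = order[b * batch_size : (b + 1) * batch_size]
        c, o, neg = centers[sel], contexts[sel], negs[sel]
        v, uo, un = W_in[c], W_out[o], W_out[neg]
        s_pos = np.einsum("bd,bd->b", v, uo)
        s_neg = np.einsum("bkd,bd->bk", un, v)
        total_loss += float(-(_log_sigmoid(s_pos).sum() + _log_sigmoid(-s_neg).sum()))
        g_pos = _sigmoid(s_pos) - 1.0
        g_neg = _sigmoid(s_neg)
        grad_v = g_pos[:, None] * uo + np.einsum("bk,bkd->bd", g_neg, un)
        np.add.at(W_in, c, -lr * grad_v)
        np.add.at(W_out, o, -lr * (g_pos[:, None] * v))
        np.add.at(W_out, neg.ravel(), -lr * (g_neg[:, :, None] * v[:, None, :]).reshape(-1, dim))
    return total_loss


def train_skipgram(
    corpus: Iterable[Sequence[str]],
    config: EmbeddingConfig = EmbeddingConfig(),
    vocabulary: Vocabulary | None = None,
) -> EmbeddingModel:
    """Train SGNS embeddings over token documents; reproducible per seed."""
    docs = [list(doc.tokens) if hasattr(doc, "tokens") else list(doc) for doc in corpus]
    vocab = vocabulary if vocabulary is not None else build_vocabulary(docs, config.min_count)
    if len(vocab) == 0:
        raise ValueError("vocabulary is empty; nothing to train on")
    rng = np.random.default_rng(config.seed)
    dim = config.dim

    docs_idx = [
        np.array([vocab.index[t] for t in doc if t in vocab.index], dtype=np.int64)
        for doc in docs
    ]
    if config.subsample > 0:
        total = vocab.counts.sum()
        freq = vocab.counts / total
        keep_p = np.minimum(1.0, np.sqrt(config.subsample / freq) + config.subsample / freq)
        docs_idx = [idx[rng.random(len(idx)) < keep_p[idx]] for idx in docs_idx]

    pairs = _training_pairs(docs_idx, config.window, config.dynamic_window, rng)
    if len(pairs) == 0:
        raise ValueError("corpus yields no training pairs (documents too short)")

    # Noise distribution: unigram^0.75, as cumulative table for fast sampling.
    noise = vocab.counts.astype(np.float64) ** config.noise_exponent
    noise_cdf = np.cumsum(noise / noise.sum())

    W_in = rng.uniform(-0.5 / dim, 0.5 / dim, size=(len(vocab), dim))
    W_out = np.zeros((len(vocab), dim))

    K = config.negatives
    centers = np.ascontiguousarray(pairs[:, 0])
    contexts = np.ascontiguousarray(pairs[:, 1])
    epoch_losses = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(pairs))
        # draw the epoch's noise tokens up front (chunked to bound memory)
        negs = np.empty((len(pairs), K), dtype=np.int64)
        for lo in range(0, len(pairs), 200_000):
            hi = min(lo + 200_000, len(pairs))
            negs[lo:hi] = np.searchsorted(noise_cdf, rng.random((hi - lo, K)))
        lr_start = config.learning_rate * max(1e-4, 1.0 - epoch / config.epochs)
        lr_end = config.learning_rate * max(1e-4, 1.0 - (epoch + 1) / config.epochs)
        if _HAVE_NUMBA:
            loss = _train_batches_numba(
                W_in, W_out, centers, contexts, order, negs,
                config.batch_size, lr_start, lr_end,
            )
        else:
            loss = _train_batches_numpy(
                W_in, W_out, centers, contexts, order, negs,
                config.batch_size, lr_start, lr_end,
            )
        epoch_losses.append(loss / len(pairs))

    return EmbeddingModel(
        vocabulary=vocab,
        input_vectors=W_in,
        output_vectors=W_out,
        epoch_losses=epoch_losses,  # mean per-pair loss per epoch
    )
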