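"""Multiscale k-mer document embeddings and self-attention fusion.

Each lncRNA sequence is tokenized into overlapping k-mers at several
scales, one distributed-memory paragraph-vector (PV-DM) model is trained
per scale, and the per-scale document vectors are fused into a single
embedding by single-head scaled dot-product self-attention over the scale
axis.

The PV-DM trainer is a from-scratch NumPy implementation: for every
centre position the hidden state is the average of the document vector and
the surrounding token vectors, a softmax over the scale vocabulary scores
the centre token, and negative sampling (noise drawn from the unigram
distribution raised to 0.75) replaces the full softmax during training.
Updates are batched per document for speed; the objective is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io import RnaSequence

__all__ = [
    "KmerDocument",
    "PvdmModel",
    "MultiscaleStack",
    "AttentionFusion",
    "segment_kmers",
    "pvdm_hidden",
    "pvdm_predict_prob",
    "train_pvdm",
    "infer_doc_vector",
    "fuse_multiscale",
]


@dataclass(frozen=True)
class KmerDocument:
    """An ordered list of overlapping k-mers for one RNA at one scale."""

    rna_id: str
    k: int
    tokens: tuple[str, ...]


def segment_kmers(seq: RnaSequence, k: int) -> KmerDocument:
    """Slide a window of size ``k``, producing length - k + 1 tokens.

    Consecutive tokens overlap by k - 1 characters.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if seq.length < k:
        raise ValueError(
            f"sequence {seq.id!r} has length {seq.length} < k={k}; "
            "cannot segment"
        )
    tokens = tuple(seq.seq[i:i + k] for i in range(seq.length - k + 1))
    return KmerDocument(rna_id=seq.id, k=k, tokens=tokens)


@dataclass
class PvdmModel:
    """Trained PV-DM tables for one k scale.

    ``word_table`` holds input token embeddings, ``context_table`` the
    output-layer prediction vectors, and ``doc_table`` one row per
    training document (aligned with ``doc_ids``).
    """

    k: int
    vocab: list[str]
    word_table: np.ndarray      # |V| x d
    context_table: np.ndarray   # |V| x d
    doc_table: np.ndarray       # n_docs x d
    doc_ids: list[str]
    window: int
    n_negative: int
    seed: int
    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._index:
            self._index = {w: i for i, w in enumerate(self.vocab)}
        if len(self._index) != len(self.vocab):
            raise ValueError("vocabulary contains duplicates")

    @property
    def dim(self) -> int:
        return self.word_table.shape[1]

    def token_index(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise KeyError(f"token {token!r} not in vocabulary (k={self.k})") from None

    def doc_vector(self, rna_id: str) -> np.ndarray:
        return self.doc_table[self.doc_ids.index(rna_id)]

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            k=self.k,
            vocab=np.array(self.vocab),
            word_table=self.word_table,
            context_table=self.context_table,
            doc_table=self.doc_table,
            doc_ids=np.array(self.doc_ids),
            window=self.window,
            n_negative=self.n_negative,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PvdmModel":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                k=int(z["k"]),
                vocab=[str(w) for w in z["vocab"]],
                word_table=z["word_table"],
                context_table=z["context_table"],
                doc_table=z["doc_table"],
                doc_ids=[str(d) for d in z["doc_ids"]],
                window=int(z["window"]),
                n_negative=int(z["n_negative"]),
                seed=int(z["seed"]),
            )


def pvdm_hidden(doc_vec: np.ndarray, context_vecs: Sequence[np.ndarray],
                window: int) -> np.ndarray:
    """Hidden state: average of the document vector and 2c context vectors."""
    context_vecs = [np.asarray(v, dtype=np.float64) for v in context_vecs]
    if len(context_vecs) != 2 * window:
        raise ValueError(
            f"expected exactly {2 * window} context vectors, got {len(context_vecs)}"
        )
    total = np.asarray(doc_vec, dtype=np.float64).copy()
    for v in context_vecs:
        total += v
    return total / (2 * window + 1)


def pvdm_predict_prob(model: PvdmModel, hidden: np.ndarray, target: str) -> float:
    """Full-softmax probability of ``target`` given a hidden state."""
    idx = model.token_index(target)
    scores = model.context_table @ np.asarray(hidden, dtype=np.float64)
    scores -= scores.max()  # stability; softmax invariant to shifts
    e = np.exp(scores)
    return float(e[idx] / e.sum())


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _window_sums(rows: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum of rows inside each sliding window, centre excluded.

    Returns the per-position context sums and context counts.  Positions
    near the edges simply have fewer context rows (no zero padding).
    """
    n = rows.shape[0]
    cs = np.vstack([np.zeros((1, rows.shape[1])), np.cumsum(rows, axis=0)])
    pos = np.arange(n)
    lo = np.maximum(0, pos - window)
    hi = np.minimum(n, pos + window + 1)
    sums = cs[hi] - cs[lo] - rows
    counts = (hi - lo - 1).astype(np.float64)
    return sums, counts


def _neg_sample_losses(hidden, pos_vecs, neg_vecs):
    pos_score = np.einsum("td,td->t", pos_vecs, hidden)
    neg_score = np.einsum("tnd,td->tn", neg_vecs, hidden)
    # minimize -log sigma(pos) - sum log sigma(-neg)
    loss = (np.logaddexp(0.0, -pos_score).sum()
            + np.logaddexp(0.0, neg_score).sum())
    return pos_score, neg_score, loss


def train_pvdm(corpus: Sequence[KmerDocument], *, dim: int = 64,
               window: int = 5, n_negative: int = 5, epochs: int = 30,
               lr: float = 0.025, seed: int = 0,
               return_loss_trace: bool = False):
    """Train one PV-DM model on all documents of a single scale.

    Negative-sampling noise follows the unigram distribution raised to
    0.75.  One gradient step is taken per document per epoch (gradients
    accumulated over all centre positions of the document), which keeps the
    pass fully vectorized while optimizing the same objective as per-
    position SGD.
    """
    if not corpus:
        raise ValueError("empty corpus")
    ks = {doc.k for doc in corpus}
    if len(ks) != 1:
        raise ValueError(f"corpus mixes scales {sorted(ks)}")
    k = ks.pop()

    vocab: dict[str, int] = {}
    counts: list[int] = []
    for doc in corpus:
        for tok in doc.tokens:
            if tok not in vocab:
                vocab[tok] = len(vocab)
                counts.append(0)
            counts[vocab[tok]] += 1
    if not vocab:
        raise ValueError("empty vocabulary")
    vsize = len(vocab)
    noise = np.asarray(counts, dtype=np.float64) ** 0.75
    noise /= noise.sum()

    rng = np.random.default_rng(seed)
    word = (rng.random((vsize, dim)) - 0.5) / dim
    docv = (rng.random((len(corpus), dim)) - 0.5) / dim
    ctx = np.zeros((vsize, dim))

    doc_tok_ids = [np.array([vocab[t] for t in doc.tokens], dtype=np.intp)
                   for doc in corpus]
    trace: list[float] = []

    for _ in range(epochs):
        epoch_loss = 0.0
        n_positions = 0
        for di, ids in enumerate(doc_tok_ids):
            T = len(ids)
            emb = word[ids]
            ctx_sum, ctx_cnt = _window_sums(emb, window)
            denom = (ctx_cnt + 1.0)[:, None]
            hidden = (docv[di] + ctx_sum) / denom

            neg = rng.choice(vsize, size=(T, n_negative), p=noise)
            pos_vecs = ctx[ids]
            neg_vecs = ctx[neg]
            pos_score, neg_score, loss = _neg_sample_losses(hidden, pos_vecs, neg_vecs)
            epoch_loss += loss
            n_positions += T

            g_pos = _sigmoid(pos_score) - 1.0           # d loss / d pos_score
            g_neg = _sigmoid(neg_score)                 # d loss / d neg_score

            # one batch-gradient step per document: normalize by the number
            # of centre positions so the step size is length-invariant
            step = lr / T
            # output-layer updates (scatter-add handles repeated tokens)
            np.add.at(ctx, ids, -step * g_pos[:, None] * hidden)
            np.add.at(ctx, neg.reshape(-1),
                      -step * (g_neg[..., None] * hidden[:, None, :]).reshape(-1, dim))

            # gradient wrt the hidden state, shared by doc and context rows
            gh = (g_pos[:, None] * pos_vecs
                  + np.einsum("tn,tnd->td", g_neg, neg_vecs)) / denom
            docv[di] -= step * gh.sum(axis=0)
            # each input token receives the hidden-gradients of the windows
            # it participates in (a reversed sliding-window sum)
            back_sum, _ = _window_sums(gh, window)
            np.add.at(word, ids, -step * back_sum)
        trace.append(epoch_loss / max(n_positions, 1))

    model = PvdmModel(
        k=k, vocab=list(vocab), word_table=word, context_table=ctx,
        doc_table=docv, doc_ids=[doc.rna_id for doc in corpus],
        window=window, n_negative=n_negative, seed=seed,
    )
    if return_loss_trace:
        return model, trace
    return model


def infer_doc_vector(model: PvdmModel, doc: KmerDocument, steps: int = 20,
                     lr: float = 0.025, seed: int = 0) -> np.ndarray:
    """Infer a document vector for an unseen RNA with frozen tables.

    Only the fresh document vector is optimized, by the same negative-
    sampling objective.  Out-of-vocabulary tokens are skipped.  With
    ``steps=0`` the seeded random initialization is returned unchanged.
    """
    if doc.k != model.k:
        raise ValueError(f"document scale k={doc.k} != model scale k={model.k}")
    ids = np.array([model._index[t] for t in doc.tokens if t in model._index],
                   dtype=np.intp)
    if ids.size == 0:
        raise ValueError(
            f"document {doc.rna_id!r} shares no token with the k={model.k} vocabulary"
        )
    dim = model.dim
    rng = np.random.default_rng(seed)
    vec = (rng.random(dim) - 0.5) / dim
    if steps == 0:
        return vec

    counts = np.zeros(len(model.vocab))
    # reuse training noise shape: unigram^0.75 over the model vocabulary,
    # estimated from this document plus add-one smoothing for stability
    np.add.at(counts, ids, 1.0)
    noise = (counts + 1.0) ** 0.75
    noise /= noise.sum()

    emb = model.word_table[ids]
    ctx_sum, ctx_cnt = _window_sums(emb, model.window)
    denom = (ctx_cnt + 1.0)[:, None]
    pos_vecs = model.context_table[ids]
    for _ in range(steps):
        hidden = (vec + ctx_sum) / denom
        neg = rng.choice(len(model.vocab), size=(len(ids), model.n_negative),
                         p=noise)
        neg_vecs = model.context_table[neg]
        pos_score = np.einsum("td,td->t", pos_vecs, hidden)
        neg_score = np.einsum("tnd,td->tn", neg_vecs, hidden)
        g_pos = _sigmoid(pos_score) - 1.0
        g_neg = _sigmoid(neg_score)
        gh = (g_pos[:, None] * pos_vecs
              + np.einsum("tn,tnd->td", g_neg, neg_vecs)) / denom
        vec -= (lr / len(ids)) * gh.sum(axis=0)
    return vec


@dataclass
class MultiscaleStack:
    """Per-RNA matrix with one row per scale (S x d)."""

    rna_id: str
    H: np.ndarray
    scales: list[int]

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float64)
        if self.H.ndim != 2 or self.H.shape[0] != len(self.scales):
            raise ValueError("H must be S x d with one row per scale")
        if not np.all(np.isfinite(self.H)):
            raise ValueError(f"non-finite embedding for {self.rna_id!r}")


@dataclass
class AttentionFusion:
    """Single-head scaled dot-product attention parameters (d x d each)."""

    W_Q: np.ndarray
    W_K: np.ndarray
    W_V: np.ndarray

    def __post_init__(self):
        for name in ("W_Q", "W_K", "W_V"):
            m = np.asarray(getattr(self, name), dtype=np.float64)
            if m.ndim != 2 or m.shape[0] != m.shape[1]:
                raise ValueError(f"{name} must be square, got {m.shape}")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, m)
        if not (self.W_Q.shape == self.W_K.shape == self.W_V.shape):
            raise ValueError("projection matrices must share one width")

    @property
    def dim(self) -> int:
        return self.W_Q.shape[0]

    @classmethod
    def init(cls, dim: int, seed: int = 0) -> "AttentionFusion":
        rng = np.random.default_rng(seed)
        lim = np.sqrt(6.0 / (2 * dim))
        return cls(*(rng.uniform(-lim, lim, (dim, dim)) for _ in range(3)))


def attention_weights(H: np.ndarray, att: AttentionFusion) -> np.ndarray:
    """Row-stochastic S x S attention matrix softmax(Q K^T / sqrt(d))."""
    Q = H @ att.W_Q
    K = H @ att.W_K
    scores = (Q @ K.T) / np.sqrt(att.dim)
    scores -= scores.max(axis=-1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=-1, keepdims=True)


def fuse_multiscale(stack: MultiscaleStack, att: AttentionFusion) -> np.ndarray:
    """Fuse the S per-scale rows into one d-vector.

    Computes softmax(Q K^T / sqrt(d)) V and mean-pools over the S rows.
    """
    if stack.H.shape[1] != att.dim:
        raise ValueError(
            f"stack width {stack.H.shape[1]} != projection width {att.dim}"
        )
    A = attention_weights(stack.H, att)
    V = stack.H @ att.W_V
    return (A @ V).mean(axis=0)
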