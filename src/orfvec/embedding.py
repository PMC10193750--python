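"""Protein "documents" and their distributed (paragraph-vector) representation.

A protein translated from the longest ORF is split into non-overlapping
words of length 3 (``MNFLLSWVHWSLALLLYL -> MNF LLS WVH WSL ALL LYL``); every
split protein forms a document of a corpus.  The distributed-memory
paragraph-vector model (PV-DM) concatenates a per-document vector with the
context word vectors to predict the central word; after SGD training the
document vector is a fixed-length embedding carrying contextual information
of the protein.

Two application modes exist: ``stored`` returns the paragraph vectors
trained for known document ids (the transductive protocol: train and test
documents embedded jointly), and ``infer`` freezes the word and softmax
parameters and optimizes a fresh paragraph vector for an unseen document.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import _pvdm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EmbeddingConfig:
    """PV-DM hyperparameters; defaults follow the predictor's tuning.

    ``window`` is the context half-length k (k words each side, 2k context
    slots), ``word_len`` the non-overlapping split width over the protein.
    """

    dim: int = 100
    window: int = 2
    word_len: int = 3
    epochs: int = 20
    min_count: int = 1
    negative: int = 5
    alpha: float = 0.025
    min_alpha: float = 1e-4
    seed: int = 1

    def __post_init__(self):
        if self.dim < 1 or self.window < 1 or self.word_len < 1:
            raise ValueError("dim, window and word_len must all be >= 1")


def split_protein(protein: str, word_len: int = 3) -> list[str]:
    """Split into consecutive non-overlapping words; the remainder is dropped."""
    if word_len < 1:
        raise ValueError("word_len must be >= 1")
    n = (len(protein) // word_len) * word_len
    return [protein[i : i + word_len] for i in range(0, n, word_len)]


def build_corpus(proteins, config: EmbeddingConfig | None = None):
    """One (id, words) document per protein, in stable input order.

    ``proteins`` is a mapping id -> protein or an iterable of (id, protein).
    Duplicate ids are rejected; empty word lists are allowed but logged.
    """
    config = config or EmbeddingConfig()
    items = proteins.items() if hasattr(proteins, "items") else proteins
    corpus: list[tuple[str, list[str]]] = []
    seen: set[str] = set()
    for ident, protein in items:
        if ident in seen:
            raise ValueError(f"duplicate document id: {ident!r}")
        seen.add(ident)
        words = split_protein(protein, config.word_len)
        if not words:
            logger.warning("document %r has no words (protein shorter than %d)",
                           ident, config.word_len)
        corpus.append((ident, words))
    return corpus


class ProteinDocEmbedder(BaseEstimator, TransformerMixin):
    """PV-DM paragraph-vector embedder for split-protein documents.

    Seeded, single-threaded SGD with negative sampling; training is bitwise
    reproducible for a fixed ``random_state``.  ``fit`` expects documents as
    (id, words) pairs — see :func:`build_corpus`.

    Attributes (after fit)
    ----------------------
    vocab_ : dict word -> index (indices start at 1; 0 is the pad slot)
    word_vectors_ : (V+1, dim) float32 input word matrix (row 0 = pad)
    doc_vectors_ : dict id -> (dim,) float32 trained paragraph vector
    out_vectors_ : (V+1, (2*window+1)*dim) float32 softmax/output parameters
    """

    def __init__(self, dim=100, window=2, word_len=3, epochs=20, min_count=1,
                 negative=5, alpha=0.025, min_alpha=1e-4, random_state=1):
        self.dim = dim
        self.window = window
        self.word_len = word_len
        self.epochs = epochs
        self.min_count = min_count
        self.negative = negative
        self.alpha = alpha
        self.min_alpha = min_alpha
        self.random_state = random_state

    @property
    def config(self) -> EmbeddingConfig:
        return EmbeddingConfig(self.dim, self.window, self.word_len,
                               self.epochs, self.min_count, self.negative,
                               self.alpha, self.min_alpha, self.random_state)

    # ------------------------------------------------------------------
    def fit(self, X, y=None):
        """Train PV-DM on documents X = list of (id, words)."""
        corpus = list(X)
        if not corpus:
            raise ValueError("cannot train on an empty corpus")
        if all(len(words) == 0 for _, words in corpus):
            raise ValueError("all documents are empty; nothing to train on")
        counts: dict[str, int] = {}
        for _, words in corpus:
            for w in words:
                counts[w] = counts.get(w, 0) + 1
        vocab_words = sorted(w for w, c in counts.items() if c >= self.min_count)
        self.vocab_ = {w: i + 1 for i, w in enumerate(vocab_words)}
        V = len(vocab_words)
        if V == 0:
            raise ValueError("min_count leaves an empty vocabulary")

        tokens, offsets, doc_ids = self._encode_corpus(corpus)
        hidden = (2 * self.window + 1) * self.dim
        rng = np.random.default_rng(self.random_state)
        self.word_vectors_ = ((rng.random((V + 1, self.dim), dtype=np.float32)
                               - 0.5) / self.dim)
        doc_mat = ((rng.random((len(doc_ids), self.dim), dtype=np.float32)
                    - 0.5) / self.dim)
        self.out_vectors_ = np.zeros((V + 1, hidden), dtype=np.float32)

        freq = np.array([counts[w] for w in vocab_words], dtype=np.float64)
        noise = freq ** 0.75
        self.neg_cdf_ = np.cumsum(noise / noise.sum())

        _pvdm.train_epochs(tokens, offsets, self.word_vectors_, doc_mat,
                           self.out_vectors_, self.neg_cdf_,
                           self.window, self.negative,
                           float(self.alpha), float(self.min_alpha),
                           int(self.epochs), int(self.random_state) & 0x7FFFFFFF,
                           True)
        self.doc_vectors_ = {ident: doc_mat[i] for i, ident in enumerate(doc_ids)}
        return self

    def _encode_corpus(self, corpus):
        doc_ids = []
        token_list = []
        offsets = [0]
        for ident, words in corpus:
            doc_ids.append(ident)
            ids = [self.vocab_[w] for w in words if w in self.vocab_]
            token_list.extend(ids)
            offsets.append(len(token_list))
        return (np.array(token_list, dtype=np.int64),
                np.array(offsets, dtype=np.int64), doc_ids)

    # ------------------------------------------------------------------
    def embed(self, docs, mode: str = "stored") -> dict[str, np.ndarray]:
        """Embed documents; ``stored`` looks up trained vectors, ``infer``
        optimizes a fresh paragraph vector with frozen word/softmax weights."""
        if mode not in ("stored", "infer"):
            raise ValueError(f"unknown embedding mode: {mode!r}")
        out: dict[str, np.ndarray] = {}
        for ident, words in docs:
            if mode == "stored":
                if ident not in self.doc_vectors_:
                    raise KeyError(
                        f"document id {ident!r} was not part of training; "
                        "use mode='infer' for unseen documents"
                    )
                out[ident] = self.doc_vectors_[ident]
            else:
                out[ident] = self.infer_vector(words, ident=ident)
        return out

    def infer_vector(self, words, ident="<unseen>") -> np.ndarray:
        """Optimize a paragraph vector for one unseen document (seeded)."""
        ids = [self.vocab_[w] for w in words if w in self.vocab_]
        vec = np.zeros((1, self.dim), dtype=np.float32)
        if not ids:
            logger.warning("inferring document %r with no known words: "
                           "returning the zero vector", ident)
            return vec[0]
        tokens = np.array(ids, dtype=np.int64)
        offsets = np.array([0, len(ids)], dtype=np.int64)
        _pvdm.train_epochs(tokens, offsets, self.word_vectors_, vec,
                           self.out_vectors_, self.neg_cdf_,
                           self.window, self.negative,
                           float(self.alpha), float(self.min_alpha),
                           int(self.epochs),
                           (int(self.random_state) + 0x5D2E) & 0x7FFFFFFF,
                           False)
        return vec[0]

    def transform(self, X) -> np.ndarray:
        """Matrix of embeddings for documents X; stored when known, else inferred."""
        rows = []
        for ident, words in X:
            if ident in self.doc_vectors_:
                rows.append(self.doc_vectors_[ident])
            else:
                rows.append(self.infer_vector(words, ident=ident))
        return np.vstack(rows) if rows else np.empty((0, self.dim), np.float32)

    # ------------------------------------------------------------------
    def save(self, directory) -> None:
        """Persist the model as .npy matrices plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        doc_ids = list(self.doc_vectors_)
        np.save(directory / "word_vectors.npy", self.word_vectors_)
        np.save(directory / "out_vectors.npy", self.out_vectors_)
        np.save(directory / "doc_vectors.npy",
                np.vstack([self.doc_vectors_[i] for i in doc_ids])
                if doc_ids else np.empty((0, self.dim), np.float32))
        np.save(directory / "neg_cdf.npy", self.neg_cdf_)
        manifest = {
            "format_version": 1,
            "params": self.get_params(),
            "vocab": list(self.vocab_),
            "doc_ids": doc_ids,
        }
        (directory / "embedding.json").write_text(json.dumps(manifest))

    @classmethod
    def load(cls, directory) -> "ProteinDocEmbedder":
        directory = Path(directory)
        manifest = json.loads((directory / "embedding.json").read_text())
        model = cls(**manifest["params"])
        model.vocab_ = {w: i + 1 for i, w in enumerate(manifest["vocab"])}
        model.word_vectors_ = np.load(directory / "word_vectors.npy")
        model.out_vectors_ = np.load(directory / "out_vectors.npy")
        model.neg_cdf_ = np.load(directory / "neg_cdf.npy")
        doc_mat = np.load(directory / "doc_vectors.npy")
        model.doc_vectors_ = {ident: doc_mat[i]
                              for i, ident in enumerate(manifest["doc_ids"])}
        return model


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train_pvdm(corpus, config: EmbeddingConfig | None = None) -> ProteinDocEmbedder:
    """Train a PV-DM embedder on a corpus of (id, words) documents."""
    config = config or EmbeddingConfig()
    model = ProteinDocEmbedder(
        dim=config.dim, window=config.window, word_len=config.word_len,
        epochs=config.epochs, min_count=config.min_count,
        negative=config.negative, alpha=config.alpha,
        min_alpha=config.min_alpha, random_state=config.seed,
    )
    return model.fit(corpus)


def embed_documents(model: ProteinDocEmbedder, docs, mode="stored"):
    """Mapping id -> embedding vector for the given documents."""
    return model.embed(docs, mode=mode)


def export_corpus(corpus, path) -> None:
    """Write one document per line: id followed by space-separated words."""
    with Path(path).open("w") as out:
        for ident, words in corpus:
            out.write(ident + "\t" + " ".join(words) + "\n")
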