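"""End-to-end coding-potential classifier.

Per transcript: locate the longest ORF, compute the classic features
(ORF / protein / RNA groups, optional CTD) and the 100-dimensional PV-DM
embedding of the translated protein, scale every feature to [-1, 1]
(min/max from the training split only) and classify with an RBF-kernel SVM
(C=300, gamma=0.4, Platt-calibrated probabilities).

The paragraph vectors follow the transductive protocol by default: pass the
evaluation transcripts as ``unlabeled`` to ``fit`` and their embeddings are
trained jointly with the training corpus; transcripts never seen by the
embedder fall back to seeded inference with frozen word/softmax weights.

Ablation switches: ``feature_groups=("embedding",)`` is the embedding-only
model (OVEC) and ``("orf", "protein", "rna")`` the no-embedding model (NVEC).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.preprocessing import MinMaxScaler
from sklearn.svm import SVC

from .classic_features import GROUP_FEATURES, GROUP_ORDER, ClassicFeatureExtractor, \
    _canonical_labels
from .embedding import (EmbeddingConfig, ProteinDocEmbedder, build_corpus,
                        split_protein)
from .seqio_orf import as_records, find_longest_orf

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("orf", "protein", "rna", "embedding")
EMBEDDING_GROUP = "embedding"


@dataclass(frozen=True)
class ClassifierConfig:
    """SVM and feature-assembly configuration."""

    kernel: str = "rbf"
    C: float = 300.0
    gamma: float = 0.4
    probability: bool = True
    scaling: str = "minmax_symmetric"
    threshold: float = 0.5
    feature_groups: tuple = DEFAULT_GROUPS

    def __post_init__(self):
        if self.C <= 0 or self.gamma <= 0:
            raise ValueError("C and gamma must be positive")
        if not 0 < self.threshold < 1:
            raise ValueError("threshold must lie in (0, 1)")
        if self.scaling not in ("minmax_symmetric", "none"):
            raise ValueError(f"unknown scaling: {self.scaling!r}")


@dataclass(frozen=True)
class FeatureVector:
    """Named, grouped feature values of one transcript."""

    id: str
    values: tuple
    names: tuple
    group_mask: tuple

    def __post_init__(self):
        if not (len(self.values) == len(self.names) == len(self.group_mask)):
            raise ValueError("values, names and group_mask must align")


def assemble_features(records, table, embeddings, config: ClassifierConfig,
                      *, orfs=None, extractor=None) -> list[FeatureVector]:
    """Assemble per-transcript feature vectors for the enabled groups.

    ``embeddings`` maps transcript id -> vector and is required when the
    embedding group is on; ``table`` is the fitted hexamer table (orf group).
    """
    records = as_records(records)
    groups = set(config.feature_groups)
    classic_groups = tuple(g for g in GROUP_ORDER if g in groups)
    if extractor is None:
        extractor = ClassicFeatureExtractor(groups=classic_groups)
        if "orf" in groups:
            if table is None:
                raise ValueError("the orf group requires a hexamer table")
            extractor.hexamer_table_ = table
        extractor.feature_names_ = [n for g in classic_groups
                                    for n in GROUP_FEATURES[g]]
    classic = extractor.transform(records, orfs=orfs)
    names = list(extractor.feature_names_)
    mask = [g for g in classic_groups for _ in GROUP_FEATURES[g]]

    emb_rows = None
    if EMBEDDING_GROUP in groups:
        if embeddings is None:
            raise ValueError("the embedding group requires an id -> vector map")
        rows = []
        for rec in records:
            if rec.id not in embeddings:
                raise ValueError(f"no embedding available for transcript "
                                 f"{rec.id!r}")
            rows.append(np.asarray(embeddings[rec.id], dtype=float))
        emb_rows = np.vstack(rows) if rows else np.empty((0, 0))
        dim = emb_rows.shape[1]
        names += [f"emb_{i:03d}" for i in range(dim)]
        mask += [EMBEDDING_GROUP] * dim

    out = []
    for i, rec in enumerate(records):
        vals = list(classic[i])
        if emb_rows is not None:
            vals += list(emb_rows[i])
        for name, v in zip(names, vals):
            if not np.isfinite(v):
                raise ValueError(f"non-finite feature {name!r} for transcript "
                                 f"{rec.id!r}")
        out.append(FeatureVector(rec.id, tuple(vals), tuple(names), tuple(mask)))
    return out


def features_to_frame(features: list[FeatureVector]) -> pd.DataFrame:
    """Feature matrix as a DataFrame indexed by transcript id."""
    if not features:
        return pd.DataFrame()
    return pd.DataFrame([f.values for f in features],
                        index=[f.id for f in features],
                        columns=list(features[0].names))


# ---------------------------------------------------------------------------
# SVM head over assembled features (spec-level train/predict operations)
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A trained head: scaler + SVM + the exact feature-name contract."""

    scaler: object
    svm: SVC
    feature_names: tuple
    config: ClassifierConfig
    embedder: object = None
    hexamer_table: object = None


def train_model(features, labels, config: ClassifierConfig,
                random_state: int = 1) -> ModelBundle:
    """Fit the scaled RBF-SVM head on assembled feature vectors."""
    if not features:
        raise ValueError("no training features")
    names = features[0].names
    for f in features:
        if f.names != names:
            raise ValueError("inconsistent feature names across samples")
    X = np.array([f.values for f in features], dtype=float)
    y = np.array([1 if lab == "coding" else 0
                  for lab in _canonical_labels(labels)])
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("training requires at least two samples per class")
    scaler = None
    if config.scaling == "minmax_symmetric":
        scaler = MinMaxScaler(feature_range=(-1, 1)).fit(X)
        X = scaler.transform(X)
    svm = SVC(kernel=config.kernel, C=config.C, gamma=config.gamma,
              probability=config.probability, cache_size=500,
              random_state=random_state)
    svm.fit(X, y)
    return ModelBundle(scaler, svm, tuple(names), config)


def predict(bundle: ModelBundle, features) -> list[tuple[str, float]]:
    """(label, coding_probability) per feature vector, thresholded at config."""
    if not features:
        return []
    for f in features:
        if f.names != bundle.feature_names:
            missing = set(bundle.feature_names) - set(f.names)
            extra = set(f.names) - set(bundle.feature_names)
            raise ValueError(
                "feature names do not match the trained model "
                f"(missing: {sorted(missing)}, unexpected: {sorted(extra)}, "
                "order must match exactly)"
            )
    X = np.array([f.values for f in features], dtype=float)
    if bundle.scaler is not None:
        X = bundle.scaler.transform(X)
    probs = _coding_probability(bundle, X)
    thr = bundle.config.threshold
    return [("coding" if p >= thr else "noncoding", float(p)) for p in probs]


def _coding_probability(bundle: ModelBundle, X) -> np.ndarray:
    if bundle.config.probability:
        pos = list(bundle.svm.classes_).index(1)
        return bundle.svm.predict_proba(X)[:, pos]
    # fall back to the decision value pushed through a logistic squash
    return 1.0 / (1.0 + np.exp(-bundle.svm.decision_function(X)))


# ---------------------------------------------------------------------------
# the end-to-end estimator
# ---------------------------------------------------------------------------

class CodingPotentialClassifier(BaseEstimator, ClassifierMixin):
    """mRNA-vs-ncRNA classifier over ORF, protein, RNA and embedding features.

    Parameters mirror the published configuration: RBF-SVM with ``C=300``
    and ``gamma=0.4``; PV-DM embedding with ``dim=100``, context half-length
    ``window=4`` and ``word_len=3``.

    ``fit(X, y, unlabeled=...)`` trains the embedder transductively on the
    union of training and (optional) unlabeled/evaluation transcripts.
    ``X`` may be a list of TranscriptRecord, (id, seq) pairs, or sequences.
    """

    def __init__(self, C=300.0, gamma=0.4, probability=True,
                 scaling="minmax_symmetric", threshold=0.5,
                 feature_groups=DEFAULT_GROUPS,
                 dim=100, window=2, word_len=3, epochs=20, min_count=1,
                 negative=5, random_state=1):
        self.C = C
        self.gamma = gamma
        self.probability = probability
        self.scaling = scaling
        self.threshold = threshold
        self.feature_groups = feature_groups
        self.dim = dim
        self.window = window
        self.word_len = word_len
        self.epochs = epochs
        self.min_count = min_count
        self.negative = negative
        self.random_state = random_state

    @property
    def config(self) -> ClassifierConfig:
        return ClassifierConfig(
            kernel="rbf", C=self.C, gamma=self.gamma,
            probability=self.probability, scaling=self.scaling,
            threshold=self.threshold,
            feature_groups=tuple(self.feature_groups),
        )

    # ------------------------------------------------------------------
    def fit(self, X, y, unlabeled=None):
        config = self.config
        records = as_records(X)
        labels = _canonical_labels(y)
        if len(records) != len(labels):
            raise ValueError("X and y lengths differ")
        orfs = [find_longest_orf(r.seq) for r in records]

        groups = set(config.feature_groups)
        classic_groups = tuple(g for g in GROUP_ORDER if g in groups)
        self.extractor_ = ClassicFeatureExtractor(groups=classic_groups)
        self.extractor_.fit(records, labels)
        self.hexamer_table_ = getattr(self.extractor_, "hexamer_table_", None)

        self.embedder_ = None
        embeddings = None
        if EMBEDDING_GROUP in groups:
            extra = as_records(unlabeled) if unlabeled is not None else []
            pool = list(records) + [r for r in extra
                                    if r.id not in {t.id for t in records}]
            pool_orfs = orfs + [find_longest_orf(r.seq) for r in pool[len(records):]]
            proteins = [(r.id, o.protein) for r, o in zip(pool, pool_orfs)]
            docs = build_corpus(proteins, EmbeddingConfig(
                dim=self.dim, window=self.window, word_len=self.word_len))
            self.embedder_ = ProteinDocEmbedder(
                dim=self.dim, window=self.window, word_len=self.word_len,
                epochs=self.epochs, min_count=self.min_count,
                negative=self.negative, random_state=self.random_state,
            ).fit(docs)
            embeddings = self.embedder_.doc_vectors_

        features = assemble_features(records, self.hexamer_table_, embeddings,
                                     config, orfs=orfs,
                                     extractor=self.extractor_)
        self.bundle_ = train_model(features, labels, config,
                                   random_state=self.random_state)
        self.bundle_.embedder = self.embedder_
        self.bundle_.hexamer_table = self.hexamer_table_
        self.feature_names_ = list(self.bundle_.feature_names)
        self.classes_ = np.array(["coding", "noncoding"])
        return self

    # ------------------------------------------------------------------
    def featurize(self, X) -> list[FeatureVector]:
        """Assembled feature vectors for transcripts under the fitted model."""
        records = as_records(X)
        orfs = [find_longest_orf(r.seq) for r in records]
        embeddings = None
        if self.embedder_ is not None:
            embeddings = {}
            for rec, orf in zip(records, orfs):
                if rec.id in self.embedder_.doc_vectors_:
                    embeddings[rec.id] = self.embedder_.doc_vectors_[rec.id]
                else:
                    words = split_protein(orf.protein, self.word_len)
                    embeddings[rec.id] = self.embedder_.infer_vector(
                        words, ident=rec.id)
        return assemble_features(records, self.hexamer_table_, embeddings,
                                 self.config, orfs=orfs,
                                 extractor=self.extractor_)

    def predict_proba(self, X) -> np.ndarray:
        """Columns follow ``classes_``: [P(coding), P(noncoding)]."""
        preds = predict(self.bundle_, self.featurize(X))
        p = np.array([prob for _, prob in preds])
        return np.column_stack([p, 1.0 - p])

    def coding_probability(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 0]

    def predict(self, X) -> np.ndarray:
        preds = predict(self.bundle_, self.featurize(X))
        return np.array([lab for lab, _ in preds])

    def score(self, X, y) -> float:
        y = np.array(_canonical_labels(y))
        return float((self.predict(X) == y).mean())

    # ------------------------------------------------------------------
    def save(self, directory) -> None:
        """Persist the model bundle to a directory (format-versioned)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"format_version": 1, "params": self.get_params(),
                    "feature_names": self.feature_names_}
        (directory / "manifest.json").write_text(json.dumps(manifest))
        joblib.dump({"scaler": self.bundle_.scaler, "svm": self.bundle_.svm},
                    directory / "svm.joblib")
        if self.hexamer_table_ is not None:
            self.hexamer_table_.to_tsv(directory / "hexamer_table.tsv")
        if self.embedder_ is not None:
            self.embedder_.save(directory / "embedding")

    @classmethod
    def load(cls, directory) -> "CodingPotentialClassifier":
        from .hexamer import HexamerTable

        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        model = cls(**manifest["params"])
        head = joblib.load(directory / "svm.joblib")
        model.hexamer_table_ = None
        if (directory / "hexamer_table.tsv").exists():
            model.hexamer_table_ = HexamerTable.from_tsv(
                directory / "hexamer_table.tsv")
        model.embedder_ = None
        if (directory / "embedding").exists():
            model.embedder_ = ProteinDocEmbedder.load(directory / "embedding")
        config = model.config
        groups = set(config.feature_groups)
        classic_groups = tuple(g for g in GROUP_ORDER if g in groups)
        model.extractor_ = ClassicFeatureExtractor(groups=classic_groups)
        if model.hexamer_table_ is not None:
            model.extractor_.hexamer_table_ = model.hexamer_table_
        model.extractor_.feature_names_ = [
            n for g in classic_groups for n in GROUP_FEATURES[g]]
        model.feature_names_ = manifest["feature_names"]
        model.bundle_ = ModelBundle(head["scaler"], head["svm"],
                                    tuple(model.feature_names_), config,
                                    model.embedder_, model.hexamer_table_)
        model.classes_ = np.array(["coding", "noncoding"])
        return model
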