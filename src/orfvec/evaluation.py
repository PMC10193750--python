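"""End-to-end evaluation harness on synthetic benchmark datasets.

Runs the study protocol: simulate a labeled dataset, split per class into
train and held-out sets, fit the full classifier (transductive embedding),
and score the held-out transcripts; optionally re-fit the SVM head on
feature subsets for the embedding-only (OVEC) and no-embedding (NVEC)
ablations, reusing the very same assembled features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .metrics import EvalMetrics, evaluate_predictions
from .pipeline import (ClassifierConfig, CodingPotentialClassifier,
                       FeatureVector, predict, train_model)
from .synthetic import SyntheticConfig, simulate_dataset


@dataclass
class BenchmarkResult:
    classifier: CodingPotentialClassifier
    metrics: EvalMetrics
    ablations: dict[str, EvalMetrics]
    n_train: int
    n_test: int
    train_features: list
    test_features: list
    y_train: list
    y_test: list


def subset_features(fv: FeatureVector, groups) -> FeatureVector:
    """Restrict a feature vector to the given groups (order preserved)."""
    idx = [i for i, g in enumerate(fv.group_mask) if g in groups]
    return FeatureVector(fv.id,
                         tuple(fv.values[i] for i in idx),
                         tuple(fv.names[i] for i in idx),
                         tuple(fv.group_mask[i] for i in idx))


def ablation_metrics(train_features, y_train, test_features, y_test,
                     groups, seed: int) -> EvalMetrics:
    """Re-fit the SVM head on a feature-group subset and score held-out."""
    cfg = ClassifierConfig(feature_groups=tuple(groups))
    bundle = train_model([subset_features(f, groups) for f in train_features],
                         y_train, cfg, random_state=seed)
    preds = predict(bundle, [subset_features(f, groups)
                             for f in test_features])
    return evaluate_predictions(y_test, [l for l, _ in preds],
                                [p for _, p in preds])


def run_synthetic_benchmark(seed: int = 42, n_train_per_class: int = 2000,
                            n_test_per_class: int = 500,
                            with_ablations: bool = True,
                            **classifier_params) -> BenchmarkResult:
    """Simulate, train and evaluate at the standard benchmark sizes."""
    cfg = SyntheticConfig(n_coding=n_train_per_class + n_test_per_class,
                          n_noncoding=n_train_per_class + n_test_per_class,
                          seed=seed)
    coding, noncoding, _ = simulate_dataset(cfg)
    train = coding[:n_train_per_class] + noncoding[:n_train_per_class]
    y_train = ["coding"] * n_train_per_class + ["noncoding"] * n_train_per_class
    test = coding[n_train_per_class:] + noncoding[n_train_per_class:]
    y_test = ["coding"] * n_test_per_class + ["noncoding"] * n_test_per_class

    clf = CodingPotentialClassifier(random_state=seed, **classifier_params)
    clf.fit(train, y_train, unlabeled=test)
    labels = clf.predict(test)
    probs = clf.coding_probability(test)
    metrics = evaluate_predictions(y_test, labels, probs)

    train_features = clf.featurize(train)
    test_features = clf.featurize(test)
    ablations = {}
    if with_ablations:
        ablations["ovec"] = ablation_metrics(
            train_features, y_train, test_features, y_test,
            ("embedding",), seed)
        ablations["nvec"] = ablation_metrics(
            train_features, y_train, test_features, y_test,
            ("orf", "protein", "rna"), seed)
    return BenchmarkResult(clf, metrics, ablations,
                           2 * n_train_per_class, 2 * n_test_per_class,
                           train_features, test_features, y_train, y_test)
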