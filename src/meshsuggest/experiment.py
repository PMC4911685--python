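"""Reproducible planted-signal experiments on synthetic corpora.

Runs the full kNN pipeline (index -> candidate features -> classifier
-> label-count selection) and the ESA ranker on a generated corpus,
and scores them with the example-based metrics against a matched-N
uniform-random baseline.  The classifier's training instances are
drawn from a subsample of the training documents (default 400): each
training document contributes tens of candidate instances, so a few
hundred documents already give a stable fit while keeping a full
experiment to a few seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .esa import Measure, build_concept_index, classify_esa
from .evaluate import EvalReport, aggregate, make_pairs
from .preprocess import AnnotatedDocument, Thesaurus, tokenize_document
from .ranker import (
    DEFAULT_K,
    Algorithm,
    RankedPrediction,
    SelectionParams,
    build_training_set,
    classify_corpus,
    train_ranker,
)
from .synthetic import GeneratorConfig, generate, split
from .vsm import build_index

__all__ = ["KnnExperimentResult", "run_knn_experiment", "run_esa_experiment",
           "random_baseline_report"]


@dataclass
class KnnExperimentResult:
    report: EvalReport
    baseline_report: EvalReport
    predictions: list[RankedPrediction]
    test_docs: list[AnnotatedDocument]
    thesaurus: Thesaurus
    label_ids: list[str]


def random_baseline_report(
    test_docs: list[AnnotatedDocument],
    predictions: list[RankedPrediction],
    label_ids: list[str],
    seed: int,
) -> EvalReport:
    """Uniform-random label sets with the same per-document N."""
    rng = np.random.default_rng(seed)
    predicted = {}
    for pred in predictions:
        n = max(1, pred.selected_n or 1)
        n = min(n, len(label_ids))
        predicted[pred.doc_id] = frozenset(
            rng.choice(label_ids, size=n, replace=False)
        )
    gold = {d.doc_id: d.labels for d in test_docs}
    pairs, excluded = make_pairs(gold, predicted)
    return aggregate(pairs, n_excluded=excluded)


def run_knn_experiment(
    seed: int,
    config: GeneratorConfig | None = None,
    algorithm: Algorithm = "rf",
    params: SelectionParams = SelectionParams(strategy="cutoff"),
    k: int = DEFAULT_K,
    train_frac: float = 0.8,
    n_train_instances_docs: int = 400,
    n_test_docs: int | None = 300,
) -> KnnExperimentResult:
    """Generate a corpus, train the kNN ranker, classify held-out docs."""
    if config is None:
        config = GeneratorConfig(seed=seed)
    elif config.seed != seed:
        config = GeneratorConfig(**{**config.__dict__, "seed": seed})
    corpus, thesaurus, truth = generate(config)
    train_docs, test_docs = split(corpus, train_frac, seed=seed)
    if n_test_docs is not None:
        test_docs = test_docs[:n_test_docs]
    index = build_index(train_docs)
    instances = build_training_set(
        train_docs[:n_train_instances_docs], index, thesaurus, k
    )
    model = train_ranker(instances, algorithm, seed=seed, k=k)
    predictions = classify_corpus(test_docs, index, model, thesaurus, params)
    gold = {d.doc_id: d.labels for d in test_docs}
    predicted = {p.doc_id: frozenset(p.selected) for p in predictions}
    pairs, excluded = make_pairs(gold, predicted)
    report = aggregate(pairs, n_excluded=excluded)
    label_ids = sorted(truth)
    baseline = random_baseline_report(
        test_docs, predictions, label_ids, seed=seed + 1
    )
    return KnnExperimentResult(
        report=report,
        baseline_report=baseline,
        predictions=predictions,
        test_docs=test_docs,
        thesaurus=thesaurus,
        label_ids=label_ids,
    )


def run_esa_experiment(
    seed: int,
    config: GeneratorConfig | None = None,
    measure: Measure = "jaccard",
    train_frac: float = 0.8,
    n_test_docs: int | None = 300,
) -> EvalReport:
    """ESA ranking with the true label-set size as the per-document N."""
    if config is None:
        config = GeneratorConfig(seed=seed)
    elif config.seed != seed:
        config = GeneratorConfig(**{**config.__dict__, "seed": seed})
    corpus, _, _ = generate(config)
    train_docs, test_docs = split(corpus, train_frac, seed=seed)
    if n_test_docs is not None:
        test_docs = test_docs[:n_test_docs]
    index = build_concept_index(train_docs, measure)
    gold, predicted = {}, {}
    for doc in test_docs:
        ranking = classify_esa(tokenize_document(doc), index, len(doc.labels))
        gold[doc.doc_id] = doc.labels
        predicted[doc.doc_id] = frozenset(c for c, _ in ranking.ranked)
    pairs, excluded = make_pairs(gold, predicted)
    return aggregate(pairs, n_excluded=excluded)
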