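"""kNN-based label ranking: features, classifiers and label-count selection.

Given a document, the descriptors attached to its k nearest neighbours
become *candidate labels*.  Each candidate is described by six features:

f1  fraction of the k neighbours annotated with the label
f2  sum of cosine similarities of those neighbours, divided by k
f3  1 iff every stemmed token of the preferred term occurs anywhere in
    the title + abstract (captures terms made of disjoint words)
f4  1 iff some entry term occurs as a contiguous stemmed-token
    subsequence of the title + abstract
f5  total count of such contiguous entry-term occurrences (0 iff f4 = 0)
f6  1 iff some entry term occurs contiguously in the title

A classical classifier (NB, decision tree, random forest or MLP) is
trained on candidates of annotated documents (class 1 iff the label is
truly assigned) and its class-1 probability becomes the relevance
score.  The number N of labels finally kept is chosen by one of three
strategies: a fixed score threshold, the average neighbour label-set
size, or a rank cut-off that stops at the first i where
s_{i+1}/s_i < i/(i+1+alpha).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .preprocess import (
    AnnotatedDocument,
    Thesaurus,
    TokenizedDocument,
    preprocess_text,
    tokenize_document,
)
from .vsm import NeighborSet, VsmIndex, retrieve_neighbors

__all__ = [
    "LabelFeatureVector",
    "RankedPrediction",
    "SelectionParams",
    "RankerModel",
    "collect_candidates",
    "compute_features",
    "build_training_set",
    "discretize_features",
    "apply_bins",
    "train_ranker",
    "score_labels",
    "select_labels",
    "feature_information_gain",
    "classify_document",
    "classify_corpus",
]

logger = logging.getLogger(__name__)

DEFAULT_K = 25
DEFAULT_THRESHOLD = 0.5
DEFAULT_ALPHA = 1.6

Algorithm = Literal["nb", "dt", "rf", "mlp"]
Strategy = Literal["threshold", "average_size", "cutoff"]

FEATURE_NAMES = ("f1", "f2", "f3", "f4", "f5", "f6")
_NUMERIC_FEATURES = ("f1", "f2", "f5")  # discretized before training


@dataclass(frozen=True)
class LabelFeatureVector:
    doc_id: str
    label_id: str
    f1: float
    f2: float
    f3: int
    f4: int
    f5: int
    f6: int
    cls: int | None = None  # 1 iff label truly assigned (training only)

    def values(self) -> tuple[float, ...]:
        return (self.f1, self.f2, self.f3, self.f4, self.f5, self.f6)


@dataclass
class RankedPrediction:
    doc_id: str
    ranked: list[tuple[str, float]]  # descending relevance
    selected_n: int | None = None

    @property
    def selected(self) -> list[str]:
        if self.selected_n is None:
            raise ValueError("no selection strategy applied yet")
        return [label for label, _ in self.ranked[: self.selected_n]]


@dataclass(frozen=True)
class SelectionParams:
    strategy: Strategy = "cutoff"
    threshold: float = DEFAULT_THRESHOLD
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must be in [0, 1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")


@dataclass
class RankerModel:
    algorithm: Algorithm
    estimator: object | None  # fitted sklearn classifier, None if prior-only
    bins: dict[str, np.ndarray]  # cut points per numeric feature
    seed: int
    k: int = DEFAULT_K
    prior: float | None = None  # constant class-1 score for prior-only model


def collect_candidates(neighbors: NeighborSet, index: VsmIndex) -> list[str]:
    """Union of the labels of the neighbour documents, sorted by id."""
    labels: set[str] = set()
    for doc_id, _ in neighbors.neighbors:
        labels |= index.labels_of[doc_id]
    return sorted(labels)


def _count_contiguous(haystack: Sequence[str], needle: Sequence[str]) -> int:
    """Occurrences (overlaps allowed) of *needle* as a contiguous run."""
    n = len(needle)
    if n == 0 or n > len(haystack):
        return 0
    needle = tuple(needle)
    return sum(
        1
        for i in range(len(haystack) - n + 1)
        if tuple(haystack[i : i + n]) == needle
    )


def compute_features(
    label: str,
    doc: TokenizedDocument,
    neighbors: NeighborSet,
    index: VsmIndex,
    thesaurus: Thesaurus,
    k: int,
    cls: int | None = None,
) -> LabelFeatureVector:
    assigned = [
        sim
        for doc_id, sim in neighbors.neighbors
        if label in index.labels_of[doc_id]
    ]
    f1 = len(assigned) / k
    f2 = sum(assigned) / k

    if label in thesaurus:
        desc = thesaurus.descriptors[label]
        preferred, entries = desc.preferred_term, desc.entry_terms
    else:
        logger.warning(
            "label %r absent from thesaurus; matching on its id text", label
        )
        preferred, entries = label, (label,)

    doc_tokens = doc.tokens
    token_set = set(doc_tokens)
    preferred_tokens = preprocess_text(preferred)
    f3 = int(
        bool(preferred_tokens)
        and all(t in token_set for t in preferred_tokens)
    )

    entry_token_seqs = [preprocess_text(e) for e in entries]
    f5 = sum(
        _count_contiguous(doc_tokens, seq) for seq in entry_token_seqs if seq
    )
    f4 = int(f5 > 0)
    f6 = int(
        any(
            _count_contiguous(doc.title_tokens, seq) > 0
            for seq in entry_token_seqs
            if seq
        )
    )
    return LabelFeatureVector(doc.doc_id, label, f1, f2, f3, f4, f5, f6, cls)


def candidate_features(
    doc: AnnotatedDocument,
    index: VsmIndex,
    thesaurus: Thesaurus,
    k: int = DEFAULT_K,
    with_class: bool = False,
) -> tuple[list[LabelFeatureVector], NeighborSet]:
    """Neighbour search plus feature extraction for one document."""
    tok = tokenize_document(doc, index.stopwords)
    neighbors = retrieve_neighbors(index, tok, k)
    instances = [
        compute_features(
            label,
            tok,
            neighbors,
            index,
            thesaurus,
            k,
            cls=int(label in doc.labels) if with_class else None,
        )
        for label in collect_candidates(neighbors, index)
    ]
    return instances, neighbors


def build_training_set(
    train_docs: Sequence[AnnotatedDocument],
    index: VsmIndex,
    thesaurus: Thesaurus,
    k: int = DEFAULT_K,
) -> list[LabelFeatureVector]:
    """One instance per (document, candidate label); class 1 iff assigned.

    Documents present in the index never see themselves among their
    neighbours (leave-one-out is built into the retrieval).
    """
    instances: list[LabelFeatureVector] = []
    for doc in train_docs:
        feats, _ = candidate_features(doc, index, thesaurus, k, with_class=True)
        instances.extend(feats)
    return instances


def discretize_features(
    instances: Sequence[LabelFeatureVector], n_bins: int = 10
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Equal-frequency binning of f1, f2, f5; binary features pass through.

    Returns the nominal design matrix (columns f1 f2 f3 f4 f5 f6) and
    the learned cut points, to be reused verbatim at classification
    time.  On ties-free data bin populations differ by at most one.
    """
    raw = np.array([inst.values() for inst in instances], dtype=float)
    bins: dict[str, np.ndarray] = {}
    for name in _NUMERIC_FEATURES:
        col = raw[:, FEATURE_NAMES.index(name)]
        s = np.sort(col)
        n = len(s)
        cuts = []
        for i in range(1, n_bins):
            pos = (i * n) // n_bins
            if pos < n:
                cuts.append(s[pos])
        # a cut at the minimum separates nothing (bins are [cut_i, cut_{i+1}))
        bins[name] = np.unique([c for c in cuts if c > s[0]])
    return apply_bins(raw, bins), bins


def apply_bins(raw: np.ndarray, bins: dict[str, np.ndarray]) -> np.ndarray:
    """Map raw feature rows to nominal bin indices using stored cuts."""
    out = raw.astype(float).copy()
    for name, cuts in bins.items():
        j = FEATURE_NAMES.index(name)
        out[:, j] = np.searchsorted(cuts, raw[:, j], side="right")
    return out.astype(np.int64)


def _make_estimator(algorithm: Algorithm, seed: int, n_bins: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.naive_bayes import CategoricalNB
    from sklearn.neural_network import MLPClassifier
    from sklearn.tree import DecisionTreeClassifier

    if algorithm == "nb":
        return CategoricalNB(min_categories=n_bins + 1)
    if algorithm == "dt":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if algorithm == "mlp":
        return MLPClassifier(random_state=seed, max_iter=300)
    raise ValueError(f"unknown algorithm {algorithm!r}")


def train_ranker(
    instances: Sequence[LabelFeatureVector],
    algorithm: Algorithm = "rf",
    seed: int = 0,
    k: int = DEFAULT_K,
    n_bins: int = 10,
) -> RankerModel:
    """Discretize the training instances and fit the chosen classifier.

    Single-class training data degrades to a prior-only model (constant
    score equal to the class-1 prior) with a logged warning.
    """
    if len(instances) < 2:
        raise ValueError("need at least 2 training instances")
    if any(inst.cls is None for inst in instances):
        raise ValueError("training instances must carry a class")
    X, bins = discretize_features(instances, n_bins)
    y = np.array([inst.cls for inst in instances], dtype=np.int64)
    if len(np.unique(y)) < 2:
        prior = float(y.mean())
        logger.warning(
            "single-class training data; using prior-only model (p=%.3f)",
            prior,
        )
        return RankerModel(algorithm, None, bins, seed, k, prior=prior)
    est = _make_estimator(algorithm, seed, n_bins)
    est.fit(X, y)
    return RankerModel(algorithm, est, bins, seed, k)


def _relevance_scores(
    model: RankerModel, candidates: Sequence[LabelFeatureVector]
) -> np.ndarray:
    raw = np.array([c.values() for c in candidates], dtype=float)
    if model.prior is not None:
        return np.full(len(candidates), model.prior)
    X = apply_bins(raw, model.bins)
    proba = model.estimator.predict_proba(X)
    classes = list(model.estimator.classes_)
    return proba[:, classes.index(1)]


def score_labels(
    model: RankerModel, candidates: Sequence[LabelFeatureVector]
) -> RankedPrediction:
    """Rank candidates by class-1 probability.

    Ties break by descending f2 (similarity mass) then ascending label
    id, so equally-scored labels with stronger neighbour support rank
    first.
    """
    if not candidates:
        return RankedPrediction(doc_id="", ranked=[])
    scores = _relevance_scores(model, candidates)
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], -candidates[i].f2, candidates[i].label_id),
    )
    return RankedPrediction(
        doc_id=candidates[0].doc_id,
        ranked=[(candidates[i].label_id, float(scores[i])) for i in order],
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def select_labels(
    prediction: RankedPrediction,
    params: SelectionParams,
    neighbors: NeighborSet | None = None,
    index: VsmIndex | None = None,
) -> list[str]:
    """Choose how many top-ranked labels to keep; always at least one.

    threshold     keep every label scoring >= params.threshold
    average_size  keep N = rounded mean label-set size of the neighbours
    cutoff        keep ranks 1..i, stopping at the first i with
                  s_{i+1}/s_i < i/(i+1+alpha)
    """
    ranked = prediction.ranked
    if not ranked:
        prediction.selected_n = 0
        return []
    scores = [s for _, s in ranked]
    if params.strategy == "threshold":
        n = sum(1 for s in scores if s >= params.threshold)
    elif params.strategy == "average_size":
        if neighbors is None or index is None:
            raise ValueError("average_size needs the neighbour set and index")
        sizes = [
            len(index.labels_of[doc_id]) for doc_id, _ in neighbors.neighbors
        ]
        n = _round_half_up(sum(sizes) / len(sizes)) if sizes else 1
    elif params.strategy == "cutoff":
        n = 1
        for i in range(1, len(scores)):  # i = 1-based rank of predecessor
            s_prev, s_next = scores[i - 1], scores[i]
            if s_prev <= 0.0 or s_next / s_prev < i / (i + 1 + params.alpha):
                break
            n = i + 1
    else:
        raise ValueError(f"unknown strategy {params.strategy!r}")
    n = max(1, min(n, len(ranked)))
    prediction.selected_n = n
    return [label for label, _ in ranked[:n]]


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def feature_information_gain(
    X: np.ndarray, y: np.ndarray, names: Sequence[str] = FEATURE_NAMES
) -> dict[str, float]:
    """Information gain (bits) of each nominal column w.r.t. the class."""
    y = np.asarray(y)
    _, y_counts = np.unique(y, return_counts=True)
    h_y = _entropy(y_counts)
    gains: dict[str, float] = {}
    n = len(y)
    for j, name in enumerate(names):
        col = X[:, j]
        h_cond = 0.0
        for v in np.unique(col):
            mask = col == v
            _, c = np.unique(y[mask], return_counts=True)
            h_cond += (mask.sum() / n) * _entropy(c)
        gains[name] = h_y - h_cond
    return gains


# ---------------------------------------------------------------------------
# end-to-end helpers

def classify_document(
    doc: AnnotatedDocument,
    index: VsmIndex,
    model: RankerModel,
    thesaurus: Thesaurus,
    params: SelectionParams = SelectionParams(),
) -> RankedPrediction:
    """Rank and select labels for one (possibly unannotated) document."""
    candidates, neighbors = candidate_features(
        doc, index, thesaurus, model.k, with_class=False
    )
    if not candidates:
        return RankedPrediction(doc.doc_id, [], selected_n=0)
    prediction = score_labels(model, candidates)
    prediction = replace_doc_id(prediction, doc.doc_id)
    select_labels(prediction, params, neighbors, index)
    return prediction


def replace_doc_id(
    prediction: RankedPrediction, doc_id: str
) -> RankedPrediction:
    prediction.doc_id = doc_id
    return prediction


def classify_corpus(
    docs: Sequence[AnnotatedDocument],
    index: VsmIndex,
    model: RankerModel,
    thesaurus: Thesaurus,
    params: SelectionParams = SelectionParams(),
) -> list[RankedPrediction]:
    return [
        classify_document(doc, index, model, thesaurus, params)
        for doc in docs
    ]
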