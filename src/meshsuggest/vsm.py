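"""TF.IDF vector-space index and cosine k-nearest-neighbour retrieval.

Documents are represented as sparse vectors of unigram weights
w = tf * ln(n/df) (raw term count times natural-log inverse document
frequency) and compared with the cosine measure

    Sim(d_i, d_j) = sum_k w_k^i w_k^j / (||d_i|| ||d_j||).

Queries are unseen documents and are weighted with the *index's* global
document frequencies.  A document that is itself in the index is never
returned as its own neighbour, so a leave-one-out search over the
training collection needs no special casing.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .preprocess import (
    STOPWORDS,
    AnnotatedDocument,
    TokenizedDocument,
    tokenize_document,
)

__all__ = [
    "WeightedTermVector",
    "VsmIndex",
    "NeighborSet",
    "tfidf_weight",
    "cosine_similarity",
    "build_index",
    "retrieve_neighbors",
    "save_index",
    "load_index",
]


@dataclass(frozen=True)
class WeightedTermVector:
    doc_id: str
    weights: Mapping[str, float]

    def norm(self) -> float:
        return math.sqrt(sum(w * w for w in self.weights.values()))


@dataclass(frozen=True)
class NeighborSet:
    """Top-k neighbours of a query, in descending cosine similarity."""

    doc_id: str
    neighbors: tuple[tuple[str, float], ...]
    k: int

    def __len__(self) -> int:
        return len(self.neighbors)

    def __bool__(self) -> bool:
        return bool(self.neighbors)


def tfidf_weight(tf: float, df: int, n: int) -> float:
    """tf * ln(n/df); zero when tf = 0 or when the term is in every doc."""
    if n < 1:
        raise ValueError("corpus size n must be >= 1")
    if tf == 0:
        return 0.0
    if df == 0:
        raise ValueError("df = 0 with tf > 0: inconsistent index")
    return tf * math.log(n / df)


def cosine_similarity(a: WeightedTermVector, b: WeightedTermVector) -> float:
    """Cosine of two sparse weight vectors; 0 if either is all-zero.

    The dot product accumulates over the terms of *a* in their stored
    order, which keeps results bit-identical with the posting-list
    accumulation used by :func:`retrieve_neighbors`.
    """
    na, nb = a.norm(), b.norm()
    if na == 0.0 or nb == 0.0:
        return 0.0
    dot = 0.0
    bw = b.weights
    for term, wa in a.weights.items():
        wb = bw.get(term)
        if wb is not None:
            dot += wa * wb
    return dot / (na * nb)


@dataclass
class VsmIndex:
    """Inverted TF.IDF index over an annotated collection.

    ``postings[t]`` holds ``(doc_indices, weights)`` arrays; ``doc_ids``
    maps the internal index back to external ids.
    """

    n_docs: int
    doc_ids: list[str]
    document_frequency: dict[str, int]
    postings: dict[str, tuple[np.ndarray, np.ndarray]]
    norms: np.ndarray
    labels_of: dict[str, frozenset[str]]
    stopwords: frozenset[str] = STOPWORDS
    _id_to_pos: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._id_to_pos:
            self._id_to_pos = {d: i for i, d in enumerate(self.doc_ids)}

    def vector_of(self, doc_id: str) -> WeightedTermVector:
        """Reconstruct a stored document vector from the postings."""
        pos = self._id_to_pos[doc_id]
        weights: dict[str, float] = {}
        for term, (idx, w) in self.postings.items():
            hit = np.nonzero(idx == pos)[0]
            if hit.size:
                weights[term] = float(w[hit[0]])
        return WeightedTermVector(doc_id, weights)

    def query_vector(self, doc: TokenizedDocument) -> WeightedTermVector:
        """Weight a query with the index's df/n; unindexed terms drop out."""
        counts: dict[str, int] = {}
        for t in doc.tokens:
            counts[t] = counts.get(t, 0) + 1
        weights: dict[str, float] = {}
        for term, tf in counts.items():
            df = self.document_frequency.get(term, 0)
            if df == 0:
                continue
            w = tfidf_weight(tf, df, self.n_docs)
            if w != 0.0:
                weights[term] = w
        return WeightedTermVector(doc.doc_id, weights)


def build_index(
    corpus: Sequence[AnnotatedDocument],
    stopwords: frozenset[str] = STOPWORDS,
) -> VsmIndex:
    """Tokenize *corpus* (title + abstract) and build the TF.IDF index."""
    if not corpus:
        raise ValueError("cannot index an empty corpus")
    n = len(corpus)
    doc_ids = [d.doc_id for d in corpus]
    token_counts: list[dict[str, int]] = []
    df: dict[str, int] = {}
    for doc in corpus:
        tok = tokenize_document(doc, stopwords)
        counts: dict[str, int] = {}
        for t in tok.tokens:
            counts[t] = counts.get(t, 0) + 1
        token_counts.append(counts)
        for t in counts:
            df[t] = df.get(t, 0) + 1

    post_idx: dict[str, list[int]] = {t: [] for t in df}
    post_w: dict[str, list[float]] = {t: [] for t in df}
    norms = np.zeros(n)
    for pos, counts in enumerate(token_counts):
        sq = 0.0
        for t, tf in counts.items():
            w = tfidf_weight(tf, df[t], n)
            if w != 0.0:
                post_idx[t].append(pos)
                post_w[t].append(w)
                sq += w * w
        norms[pos] = math.sqrt(sq)

    postings = {
        t: (np.asarray(post_idx[t], dtype=np.int64),
            np.asarray(post_w[t], dtype=np.float64))
        for t in df
    }
    labels_of = {d.doc_id: frozenset(d.labels) for d in corpus}
    return VsmIndex(
        n_docs=n,
        doc_ids=doc_ids,
        document_frequency=dict(df),
        postings=postings,
        norms=norms,
        labels_of=labels_of,
        stopwords=stopwords,
    )


def retrieve_neighbors(
    index: VsmIndex, query: TokenizedDocument, k: int
) -> NeighborSet:
    """Top-k documents by cosine similarity to *query*.

    Ties at the boundary break by ascending doc id.  A query sharing no
    indexed term gets an empty neighbour set.  If the query document is
    itself indexed it is excluded from the result.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    qvec = index.query_vector(query)
    qnorm = qvec.norm()
    if qnorm == 0.0:
        return NeighborSet(query.doc_id, (), k)

    # Accumulate dot products term-by-term in the query vector's order;
    # per-document sums then match cosine_similarity exactly.
    dots = np.zeros(index.n_docs)
    for term, qw in qvec.weights.items():
        idx, w = index.postings[term]
        dots[idx] += qw * w

    with np.errstate(invalid="ignore", divide="ignore"):
        sims = np.where(index.norms > 0, dots / (index.norms * qnorm), 0.0)

    self_pos = index._id_to_pos.get(query.doc_id)
    if self_pos is not None:
        sims[self_pos] = -np.inf

    order = sorted(
        (pos for pos in range(index.n_docs) if sims[pos] > 0.0),
        key=lambda pos: (-sims[pos], index.doc_ids[pos]),
    )
    top = order[:k]
    return NeighborSet(
        query.doc_id,
        tuple((index.doc_ids[pos], float(sims[pos])) for pos in top),
        k,
    )


def save_index(index: VsmIndex, out_dir: str | Path) -> None:
    """Persist the index as TSV postings/norms/labels plus a JSON header."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "postings.tsv", "w", encoding="utf-8") as fh:
        for term in sorted(index.postings):
            idx, w = index.postings[term]
            df = index.document_frequency[term]
            for pos, weight in zip(idx, w):
                fh.write(
                    f"{term}\t{df}\t{index.doc_ids[pos]}\t{float(weight)!r}\n"
                )
    with open(out / "norms.tsv", "w", encoding="utf-8") as fh:
        for pos, doc_id in enumerate(index.doc_ids):
            fh.write(f"{doc_id}\t{float(index.norms[pos])!r}\n")
    with open(out / "labels.tsv", "w", encoding="utf-8") as fh:
        for doc_id in index.doc_ids:
            fh.write(f"{doc_id}\t{'|'.join(sorted(index.labels_of[doc_id]))}\n")
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump({"n_docs": index.n_docs}, fh)


def load_index(in_dir: str | Path) -> VsmIndex:
    src = Path(in_dir)
    with open(src / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    doc_ids: list[str] = []
    norms_map: dict[str, float] = {}
    with open(src / "norms.tsv", encoding="utf-8") as fh:
        for line in fh:
            doc_id, norm = line.rstrip("\n").split("\t")
            doc_ids.append(doc_id)
            norms_map[doc_id] = float(norm)
    id_to_pos = {d: i for i, d in enumerate(doc_ids)}
    df: dict[str, int] = {}
    post_idx: dict[str, list[int]] = {}
    post_w: dict[str, list[float]] = {}
    with open(src / "postings.tsv", encoding="utf-8") as fh:
        for line in fh:
            term, df_s, doc_id, weight = line.rstrip("\n").split("\t")
            df[term] = int(df_s)
            post_idx.setdefault(term, []).append(id_to_pos[doc_id])
            post_w.setdefault(term, []).append(float(weight))
    labels_of: dict[str, frozenset[str]] = {}
    with open(src / "labels.tsv", encoding="utf-8") as fh:
        for line in fh:
            doc_id, raw = (line.rstrip("\n").split("\t") + [""])[:2]
            labels_of[doc_id] = frozenset(l for l in raw.split("|") if l)
    postings = {
        t: (np.asarray(post_idx[t], dtype=np.int64),
            np.asarray(post_w[t], dtype=np.float64))
        for t in df
    }
    norms = np.array([norms_map[d] for d in doc_ids])
    return VsmIndex(
        n_docs=meta["n_docs"],
        doc_ids=doc_ids,
        document_frequency=df,
        postings=postings,
        norms=norms,
        labels_of=labels_of,
    )
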