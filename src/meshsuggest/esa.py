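"""Explicit-semantic-analysis concept classifier.

Instead of Wikipedia articles, the explicit concepts here are the
descriptors of an annotated training corpus: each concept is
represented by the terms of the documents it annotates, scored by a
term-concept association measure,

    TF.ICF(t, c) = TF(t, c) * log10(N / n_i),
        TF(t, c)  = sum over d in D_c of freq(t, d) / |d|
    J(t, c)      = cocc(t, c) / (occ(t) + occ(c) - cocc(t, c)),

where D_c is the set of documents annotated by c, N the number of
concepts, n_i the number of concepts associated with t, occ/cocc are
document counts.  Each concept keeps its 200 strongest terms and terms
in fewer than 5 documents are dropped; the term->concept mapping is
inverted for retrieval.  A new document d is ranked against concepts by

    Rel(c, d) = sum over terms t of d of TF.IDF(t, d) * score(t, c)

with TF.IDF(t, d) = tf * ln(n/df) frozen to the training-corpus
statistics.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

from .preprocess import (
    STOPWORDS,
    AnnotatedDocument,
    TokenizedDocument,
    tokenize_document,
)
from .vsm import tfidf_weight

__all__ = [
    "AssociationStats",
    "ConceptIndex",
    "ConceptRanking",
    "build_association_stats",
    "compute_tf_icf",
    "compute_jaccard",
    "build_concept_index",
    "classify_esa",
    "save_concept_index",
    "load_concept_index",
]

DEFAULT_TOP_M = 200
DEFAULT_MIN_DF = 5

Measure = Literal["tficf", "jaccard"]


@dataclass
class AssociationStats:
    """Co-occurrence statistics between terms and concepts (labels)."""

    n_docs: int
    n_concepts: int
    term_df: dict[str, int]  # occ(t): documents containing t
    concept_df: dict[str, int]  # occ(c): documents annotated by c
    cocc: dict[str, Counter]  # concept -> {term: #docs with both}
    tf: dict[str, dict[str, float]]  # concept -> {term: sum freq/|d|}
    n_concepts_of_term: dict[str, int]  # n_i: concepts associated with t


def build_association_stats(
    corpus: Sequence[AnnotatedDocument],
    stopwords: frozenset[str] = STOPWORDS,
) -> AssociationStats:
    term_df: Counter = Counter()
    concept_df: Counter = Counter()
    cocc: dict[str, Counter] = {}
    tf: dict[str, dict[str, float]] = {}
    for doc in corpus:
        tokens = tokenize_document(doc, stopwords).tokens
        counts = Counter(tokens)
        length = len(tokens)
        term_df.update(counts.keys())
        for c in doc.labels:
            concept_df[c] += 1
            c_cocc = cocc.setdefault(c, Counter())
            c_tf = tf.setdefault(c, {})
            if length == 0:
                continue
            for t, freq in counts.items():
                c_cocc[t] += 1
                c_tf[t] = c_tf.get(t, 0.0) + freq / length
    n_concepts_of_term: Counter = Counter()
    for c_counter in cocc.values():
        n_concepts_of_term.update(c_counter.keys())
    return AssociationStats(
        n_docs=len(corpus),
        n_concepts=len(concept_df),
        term_df=dict(term_df),
        concept_df=dict(concept_df),
        cocc=cocc,
        tf=tf,
        n_concepts_of_term=dict(n_concepts_of_term),
    )


def compute_tf_icf(t: str, c: str, stats: AssociationStats) -> float:
    """TF(t,c) * log10(N/n_i); zero when t never occurs in c's documents."""
    tf_tc = stats.tf.get(c, {}).get(t, 0.0)
    if tf_tc == 0.0:
        return 0.0
    n_i = stats.n_concepts_of_term.get(t, 0)
    if n_i == 0:
        raise ValueError(f"term {t!r} has TF > 0 but no associated concept")
    return tf_tc * math.log10(stats.n_concepts / n_i)


def compute_jaccard(t: str, c: str, stats: AssociationStats) -> float:
    """cocc(t,c) / (occ(t) + occ(c) - cocc(t,c)); 0 when both supports empty."""
    cocc_tc = stats.cocc.get(c, Counter()).get(t, 0)
    occ_t = stats.term_df.get(t, 0)
    occ_c = stats.concept_df.get(c, 0)
    denom = occ_t + occ_c - cocc_tc
    if denom == 0:
        return 0.0
    return cocc_tc / denom


@dataclass
class ConceptIndex:
    """Inverted term -> [(concept, association score)] map.

    Carries the training corpus's document frequencies and size so test
    documents can be TF.IDF-weighted against a frozen snapshot.
    """

    measure: Measure
    inverted: dict[str, list[tuple[str, float]]]
    term_df: dict[str, int]
    n_docs: int
    top_m: int = DEFAULT_TOP_M
    min_df: int = DEFAULT_MIN_DF
    concepts: tuple[str, ...] = ()


@dataclass
class ConceptRanking:
    doc_id: str
    ranked: list[tuple[str, float]]  # descending Rel


def build_concept_index(
    corpus: Sequence[AnnotatedDocument],
    measure: Measure = "jaccard",
    top_m: int = DEFAULT_TOP_M,
    min_df: int = DEFAULT_MIN_DF,
    stopwords: frozenset[str] = STOPWORDS,
) -> ConceptIndex:
    """Score every eligible (term, concept) pair, prune, and invert.

    Per concept, only terms with corpus document frequency >= *min_df*
    are scored; the *top_m* highest-scoring are kept (ties at the
    boundary break by ascending term string).
    """
    stats = build_association_stats(corpus, stopwords)
    scorer = compute_jaccard if measure == "jaccard" else (
        lambda t, c, s: compute_tf_icf(t, c, s)
    )
    inverted: dict[str, list[tuple[str, float]]] = {}
    for c in sorted(stats.concept_df):
        scored = [
            (t, scorer(t, c, stats))
            for t in stats.cocc.get(c, Counter())
            if stats.term_df.get(t, 0) >= min_df
        ]
        scored = [(t, s) for t, s in scored if s > 0.0]
        scored.sort(key=lambda ts: (-ts[1], ts[0]))
        for t, s in scored[:top_m]:
            inverted.setdefault(t, []).append((c, s))
    return ConceptIndex(
        measure=measure,
        inverted=inverted,
        term_df=dict(stats.term_df),
        n_docs=stats.n_docs,
        top_m=top_m,
        min_df=min_df,
        concepts=tuple(sorted(stats.concept_df)),
    )


def classify_esa(
    doc: TokenizedDocument,
    index: ConceptIndex,
    n_labels: int | None = None,
) -> ConceptRanking:
    """Rank concepts by Rel(c, d); truncate to *n_labels* if given.

    In evaluation mode the caller passes the size of the document's
    true label set as *n_labels* (the count of relevant concepts is
    treated as known).  A document sharing no indexed term yields an
    empty ranking.
    """
    counts = Counter(doc.tokens)
    rel: dict[str, float] = {}
    for t, tf in counts.items():
        concepts = index.inverted.get(t)
        if not concepts:
            continue
        df = index.term_df.get(t, 0)
        if df == 0:
            continue
        w = tfidf_weight(tf, df, index.n_docs)
        if w == 0.0:
            continue
        for c, score in concepts:
            rel[c] = rel.get(c, 0.0) + w * score
    ranked = sorted(rel.items(), key=lambda cs: (-cs[1], cs[0]))
    if n_labels is not None:
        ranked = ranked[:n_labels]
    return ConceptRanking(doc.doc_id, ranked)


def save_concept_index(index: ConceptIndex, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "concept_index.tsv", "w", encoding="utf-8") as fh:
        for t in sorted(index.inverted):
            for c, s in index.inverted[t]:
                fh.write(f"{t}\t{c}\t{s!r}\n")
    with open(out / "term_df.tsv", "w", encoding="utf-8") as fh:
        for t in sorted(index.term_df):
            fh.write(f"{t}\t{index.term_df[t]}\n")
    with open(out / "meta.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "measure": index.measure,
                "n_docs": index.n_docs,
                "top_m": index.top_m,
                "min_df": index.min_df,
                "concepts": list(index.concepts),
            },
            fh,
        )


def load_concept_index(in_dir: str | Path) -> ConceptIndex:
    src = Path(in_dir)
    with open(src / "meta.json", encoding="utf-8") as fh:
        meta = json.load(fh)
    inverted: dict[str, list[tuple[str, float]]] = {}
    with open(src / "concept_index.tsv", encoding="utf-8") as fh:
        for line in fh:
            t, c, s = line.rstrip("\n").split("\t")
            inverted.setdefault(t, []).append((c, float(s)))
    term_df: dict[str, int] = {}
    with open(src / "term_df.tsv", encoding="utf-8") as fh:
        for line in fh:
            t, df = line.rstrip("\n").split("\t")
            term_df[t] = int(df)
    return ConceptIndex(
        measure=meta["measure"],
        inverted=inverted,
        term_df=term_df,
        n_docs=meta["n_docs"],
        top_m=meta["top_m"],
        min_df=meta["min_df"],
        concepts=tuple(meta["concepts"]),
    )
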