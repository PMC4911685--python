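# Methods

## Problem

A biomedical citation is a title + abstract annotated with a set of
controlled descriptors (MeSH-style main headings, each with a preferred
term and synonym "entry terms").  The task is multi-label
classification from this partial information: predict the descriptor
set of an unseen citation.  The package provides two independent
methods — a kNN-based label ranker and an ESA-based concept ranker —
plus example-based evaluation and a synthetic corpus generator.

## Text normalisation

Lowercasing; tokenisation on maximal runs of Unicode letters/digits
(underscore excluded); removal of a fixed English stop-word list
shipped with the package (≈130 words); single-pass Porter stemming
(the classic 1980 five-step cascade, implemented in `_porter.py`).
Sentence segmentation is skipped: it has no effect on a bag-of-words
representation.  One-character and numeric tokens are kept — no filter
is applied beyond stop words.  Token order is preserved because entry
terms are matched as contiguous token subsequences.

Porter stemming is applied once per token.  Single-pass Porter is not
idempotent for stems ending in a lone "s" ("response" → "respons" →
"respon" on a second pass); the single-pass form is canonical here
(e.g. "adiposity" → "adipos") and the test suite asserts idempotence
up to that documented exception.

## kNN label ranker

**Retrieval.**  Documents are sparse vectors of unigram weights
`w = tf · ln(n/df)` — raw term count times natural-log inverse document
frequency.  The variant is a deliberate choice: "TF.IDF" alone does not
pin down smoothing or log base, and the plain product is deterministic
and easy to verify; it is isolated in `tfidf_weight` should another
variant be needed.  Queries (unseen documents) are weighted with the
*index's* df/n statistics; terms unseen in the index drop out.  The
k = 25 nearest neighbours by cosine similarity are retrieved via an
inverted index with posting-list accumulation; ties at the top-k
boundary break by ascending document id for reproducibility.  A
document indexed in the collection is excluded from its own neighbour
set, so training-set construction is leave-one-out by construction.

**Candidates and features.**  Candidate labels are the union of the
neighbours' label sets.  For candidate l of document d with neighbours
V = {d_1…d_k}:

| feature | definition |
|---|---|
| f1 | (1/k) Σ assigned(l, d_i) — fraction of neighbours carrying l |
| f2 | (1/k) Σ_{l ∈ d_i} sim(d, d_i) — similarity mass of those neighbours |
| f3 | 1 iff every stemmed token of the preferred term occurs anywhere in title+abstract |
| f4 | 1 iff some entry term occurs as a contiguous stemmed-token subsequence of title+abstract |
| f5 | total count of such contiguous occurrences over all entry terms (0 ⇔ f4 = 0) |
| f6 | 1 iff some entry term occurs contiguously in the title |

f1 is normalised by the *requested* k (not the returned count), so both
f1 and f2 lie in [0,1] and f2 ≤ f1.  f3 deliberately ignores adjacency
(it exists to catch multi-word terms whose words are scattered);
f4–f6 require contiguity, with overlapping occurrences counted.  A
preferred term that normalises to nothing (all stop words) scores
f3 = 0.  A candidate absent from the thesaurus falls back to matching
its own id text, with a logged warning.

**Classifier.**  Numeric features (f1, f2, f5) are discretized into
equal-frequency bins (default 10) whose cut points are learned on the
training instances and frozen into the model; cuts that separate
nothing (at the feature minimum) are dropped, so a constant feature
yields a single bin.  The class of a training instance is 1 iff the
label is truly assigned to its document.  Four classifiers are
supported through scikit-learn: categorical Naive Bayes, decision
tree, random forest (default, 100 trees) and MLP, all seeded for
determinism.  Degenerate single-class training data yields a
prior-only model with a warning.  The relevance score of a candidate
is the fitted model's class-1 probability; ranking ties break by
descending f2, then ascending label id.

**Choosing N.**  Three strategies fix how many top-ranked labels are
kept (always at least one):

* `threshold` — keep scores ≥ 0.5 (inclusive);
* `average_size` — N = mean label-set size of the neighbour documents,
  rounded half-up;
* `cutoff` (default) — scan ranks downward and stop at the first i
  where `s_{i+1}/s_i < i/(i+1+α)`, with α = 1.6.  Rank 1 is always
  kept; a zero predecessor score counts as a violation.  Larger α keeps
  more labels (monotone, property-tested).

Feature relevance can be inspected with `feature_information_gain`
(Shannon information gain in bits of each nominal feature w.r.t. the
class).

## ESA concept ranker

The concept space is the descriptor vocabulary of an annotated training
corpus.  Association scores between a stemmed term t and a concept c:

* TF.ICF: `TF(t,c) · log10(N/n_i)` with
  `TF(t,c) = Σ_{d∈D_c} freq(t,d)/|d|`, N the number of concepts and
  n_i the number of concepts whose documents contain t.  Base-10 log;
  the base only rescales scores within each n_i stratum and is fixed
  for determinism.
* Jaccard: `cocc(t,c) / (occ(t) + occ(c) − cocc(t,c))` over document
  counts, 0 when both supports are empty.

Each concept keeps its 200 strongest terms (ties at the boundary break
by ascending term string) among terms occurring in ≥ 5 documents; the
mapping is inverted to term → [(concept, score)].  A new document is
ranked by `Rel(c,d) = Σ_t TF.IDF(t,d) · score(t,c)` where the query
TF.IDF uses the same `tf · ln(n/df)` variant with document frequencies
*frozen from the training corpus* (a fixed snapshot keeps
classification independent of test-set composition).  In evaluation
mode the number of concepts kept per document is its true label-set
size, so precision equals recall there.

Known behaviour: with few concepts and dense label co-occurrence (as
in small synthetic corpora) most terms co-occur with *every* concept,
so `log10(N/n_i) = 0` and TF.ICF collapses toward zero scores; the
measure needs a large, sparse concept space to be informative.  The
Jaccard variant has no such degeneracy.  Which measure wins is
corpus-dependent and is logged, not asserted, by the tests.

## Evaluation

Per document with true set Y and predicted set Z: precision |Y∩Z|/|Z|
(0 for empty Z), recall |Y∩Z|/|Y|, F = 2|Y∩Z|/(|Y|+|Z|), accuracy
|Y∩Z|/|Y∪Z|.  EBP/EBR/EBF/Acc are arithmetic means over documents;
MiF = 2·TP/(2·TP+FP+FN) micro-averages all label decisions.  The F
definition restores the conventional factor 2 — it makes per-document
F the harmonic mean of precision and recall, which is the only reading
consistent with reported (EBP, EBR, EBF) triples in the literature;
`literal_ebf=True` exposes the halved variant `|Y∩Z|/(|Y|+|Z|)` for
comparison.  Documents with empty true label sets cannot be scored;
they are excluded and counted in the report.

## Synthetic corpus generator

Each of `n_docs` documents draws a label count from a Poisson
(mean `labels_per_doc` = 5, truncated below at 1), samples that many
distinct labels uniformly, and emits `title_len` + `abstract_len`
(10 + 100) tokens: with probability `signal_strength` a token comes
from a uniformly chosen assigned label's block of
`signal_terms_per_label` = 10 dedicated signal terms; otherwise from a
Zipf-like background over the whole vocabulary (exponent 1.1, to mimic
natural-language frequency skew; a uniform background is available).
Defaults: 2000 documents, 50 labels, vocabulary 2000.  The thesaurus
assigns each label 3 entry terms drawn from its own signal terms
(first = preferred), so the lexical features f3–f6 and the ESA
association measures have genuine structure to detect.  Tokens are
pre-stemmed synthetic strings ("t0001", …) on which the Porter stemmer
is a no-op; the real-word preprocessing path is exercised separately
with English fixtures.

What the generator does *not* emulate: realistic vocabulary sizes and
MeSH's 27k-descriptor space, hierarchical label structure, label
imbalance, multi-word entry terms, and document-length variation.
Passing tests therefore demonstrate that the machinery recovers
planted structure under controlled conditions — not any particular
performance level on real MEDLINE data, where reported F-measures are
far lower.

## Problem sizes and numerical choices

Experiments (`run_knn_experiment`) split the corpus 80/20, build the
classifier's training set from 400 training documents (each document
contributes tens of candidate instances, so a few hundred documents
already give a stable fit) and evaluate on 300 held-out documents;
the acceptance script averages three derived seeds.  The matched-N
random baseline draws, per document, the same number of labels the
pipeline selected, uniformly without replacement.

Floating-point cosine scores are accumulated in a fixed term order so
indexed retrieval and the brute-force oracle agree bitwise; comparisons
in tests use 1e-12 relative tolerances.  All randomness flows through
`numpy.random.default_rng` with explicit seeds; classifier seeds are
recorded in the model.

## Limitations

* Unigram bag-of-words only; no concept mapping, no hierarchy-aware
  metrics, no learning-to-rank.
* The retrieval index is exact and in-memory; it targets corpora of
  thousands to hundreds of thousands of documents, not the
  multi-million-document regime (which would want an external IR
  engine).
* TF.ICF degenerates when the concept space is small (see above).
* The score threshold strategy depends on well-calibrated classifier
  probabilities; random-forest probabilities on near-separable planted
  data saturate at 0/1, which makes the threshold strategy coarse
  there.
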