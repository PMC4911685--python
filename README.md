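# meshsuggest

Multi-label classification of biomedical citations from partial
information: given only a document's **title and abstract**, suggest the
controlled-vocabulary descriptors (MeSH-style main headings) that
describe its full content.

The package implements two standalone classifiers plus the evaluation
machinery to compare them:

**kNN label ranker.**  Documents are bag-of-words vectors of Porter-
stemmed unigrams weighted by TF.IDF (`w = tf · ln(n/df)`); the k = 25
nearest neighbours of a target document are retrieved by cosine
similarity

```
Sim(d_i, d_j) = Σ_k w_k^i w_k^j / (‖d_i‖ ‖d_j‖)
```

and every descriptor attached to a neighbour becomes a *candidate
label*.  Each candidate is described by six features — the fraction of
neighbours carrying it (f1), its similarity mass `f2 = (1/k) Σ sim(d, d_i)`
over those neighbours, and four lexical matches of the descriptor's
preferred/entry terms against the document text and title (f3–f6).  A
classical classifier (Naive Bayes, decision tree, random forest or MLP)
trained on candidates of already-annotated documents turns the features
into a relevance score P(relevant), and the number N of labels kept is
fixed by one of three strategies: a 0.5 score threshold, the average
label-set size of the neighbours, or the rank cut-off that stops at the
first position i where `s_{i+1}/s_i < i/(i+1+α)` (α = 1.6).

**ESA concept ranker.**  An explicit-semantic-analysis classifier whose
concept space is the descriptor vocabulary itself: from an annotated
corpus, each descriptor is represented by its 200 most strongly
associated stemmed terms (terms in ≥ 5 documents), scored either by the
Jaccard coefficient `cocc/(occ(t)+occ(c)−cocc)` or by TF.ICF
`TF(t,c)·log10(N/n_i)`.  The inverted term→concept index ranks a new
document by `Rel(c,d) = Σ_t TF.IDF(t,d)·score(t,c)`.

**Evaluation.**  Example-based precision/recall/F/accuracy (EBP, EBR,
EBF, Acc — per-document, then averaged) and micro-averaged F over all
label decisions (MiF).

Because the original million-citation collections cannot be shipped, a
**synthetic corpus generator** produces annotated corpora with planted
label–term associations (per-label signal vocabularies, Zipf background,
a matching thesaurus) so the whole pipeline is trainable and testable
offline.

## Worked example

```python
from meshsuggest import *

config = GeneratorConfig(n_docs=800, n_labels=30, vocab_size=1000, seed=42)
corpus, thesaurus, truth = generate(config)
train_docs, test_docs = split(corpus, 0.8, seed=42)

index = build_index(train_docs)
instances = build_training_set(train_docs[:200], index, thesaurus, k=25)
model = train_ranker(instances, "rf", seed=42)

params = SelectionParams(strategy="cutoff", alpha=1.6)
predictions = classify_corpus(test_docs[:100], index, model, thesaurus, params)

doc, pred = test_docs[0], predictions[0]
print(f"document {doc.doc_id}: true labels {sorted(doc.labels)}")
print(f"top ranked: {[(l, round(s, 2)) for l, s in pred.ranked[:6]]}")
print(f"selected (cut-off, alpha=1.6): {pred.selected}")

pairs, _ = make_pairs(
    {d.doc_id: d.labels for d in test_docs[:100]},
    {p.doc_id: frozenset(p.selected) for p in predictions},
)
r = aggregate(pairs)
print(f"EBP={r.ebp:.3f} EBR={r.ebr:.3f} EBF={r.ebf:.3f} "
      f"Acc={r.acc:.3f} MiF={r.mif:.3f} (m={r.m})")
```

prints

```
document S00397: true labels ['L008', 'L018', 'L026']
top ranked: [('L008', 1.0), ('L018', 1.0), ('L026', 1.0), ('L005', 0.04), ('L020', 0.04), ('L002', 0.04)]
selected (cut-off, alpha=1.6): ['L008', 'L018', 'L026']
EBP=0.921 EBR=0.936 EBF=0.918 Acc=0.862 MiF=0.918 (m=100)
```

The ranker scores the document's three true descriptors at the top and
the cut-off rule truncates the list right after them; over the 100
held-out documents the pipeline reaches an example-based F of 0.92 on
this planted corpus (a matched-size random predictor scores ≈ 0.1).

The same workflow is available from the shell:

```
meshsuggest simulate --out data --seed 1
meshsuggest index --corpus data/corpus.jsonl --out idx
meshsuggest train --corpus data/corpus.jsonl --index idx \
    --thesaurus data/thesaurus.tsv --algo rf --k 25 --seed 1 --out model.joblib
meshsuggest classify --model model.joblib --index idx \
    --thesaurus data/thesaurus.tsv --in data/corpus.jsonl \
    --strategy cutoff --alpha 1.6 --out pred.jsonl
meshsuggest evaluate --gold data/corpus.jsonl --pred pred.jsonl --out report.tsv
```

(`esa-build` / `esa-classify` drive the ESA ranker analogously.)

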