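"""Synthetic annotated corpora with planted label-term associations.

Emulates the statistical shape of a MEDLINE-style collection: each
document carries a title and abstract and a handful of descriptors.
Every label owns a disjoint block of *signal terms*; a document's
tokens are a mixture of its labels' signal terms (with probability
``signal_strength``, split uniformly over its labels) and a Zipf-like
background over the whole vocabulary.  The matching thesaurus draws
each label's preferred and entry terms from its signal terms, so the
entry-term features and the ESA association measures have real
structure to find.  Tokens are pre-stemmed synthetic strings
("t0001", ...) on which the Porter stemmer is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .preprocess import AnnotatedDocument, Descriptor, Thesaurus

__all__ = ["GeneratorConfig", "generate", "split"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_docs: int = 2000
    n_labels: int = 50
    vocab_size: int = 2000
    labels_per_doc: float = 5.0  # Poisson mean, truncated at 1
    signal_terms_per_label: int = 10
    signal_strength: float = 0.8
    title_len: int = 10
    abstract_len: int = 100
    entry_terms_per_label: int = 3
    background: str = "zipf"  # or "uniform"
    zipf_exponent: float = 1.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_docs",
            "n_labels",
            "vocab_size",
            "signal_terms_per_label",
            "title_len",
            "abstract_len",
            "entry_terms_per_label",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.vocab_size < self.n_labels * self.signal_terms_per_label:
            raise ValueError(
                "vocab_size must be >= n_labels * signal_terms_per_label"
            )


def _background_probs(config: GeneratorConfig) -> np.ndarray:
    if config.background == "uniform":
        p = np.ones(config.vocab_size)
    elif config.background == "zipf":
        ranks = np.arange(1, config.vocab_size + 1, dtype=float)
        p = ranks ** (-config.zipf_exponent)
    else:
        raise ValueError(f"unknown background {config.background!r}")
    return p / p.sum()


def generate(
    config: GeneratorConfig,
) -> tuple[list[AnnotatedDocument], Thesaurus, dict[str, list[str]]]:
    """Generate (corpus, thesaurus, label -> signal-term truth table)."""
    rng = np.random.default_rng(config.seed)
    vocab = [f"t{i:04d}" for i in range(config.vocab_size)]
    label_ids = [f"L{i:03d}" for i in range(config.n_labels)]
    s = config.signal_terms_per_label
    truth = {
        label: vocab[i * s : (i + 1) * s]
        for i, label in enumerate(label_ids)
    }

    descriptors: dict[str, Descriptor] = {}
    for label in label_ids:
        n_entries = min(config.entry_terms_per_label, s)
        entries = tuple(truth[label][:n_entries])
        descriptors[label] = Descriptor(entries[0], entries)
    thesaurus = Thesaurus(descriptors)

    bg = _background_probs(config)
    vocab_arr = np.array(vocab)
    docs: list[AnnotatedDocument] = []
    for i in range(config.n_docs):
        n_labels_doc = max(1, int(rng.poisson(config.labels_per_doc)))
        n_labels_doc = min(n_labels_doc, config.n_labels)
        doc_labels = sorted(
            rng.choice(config.n_labels, size=n_labels_doc, replace=False)
        )
        doc_label_ids = [label_ids[j] for j in doc_labels]

        n_tokens = config.title_len + config.abstract_len
        from_signal = rng.random(n_tokens) < config.signal_strength
        tokens = np.empty(n_tokens, dtype=object)
        n_sig = int(from_signal.sum())
        if n_sig:
            which_label = rng.integers(0, n_labels_doc, size=n_sig)
            which_term = rng.integers(0, s, size=n_sig)
            sig_tokens = [
                truth[doc_label_ids[l]][t]
                for l, t in zip(which_label, which_term)
            ]
            tokens[from_signal] = sig_tokens
        n_bg = n_tokens - n_sig
        if n_bg:
            tokens[~from_signal] = vocab_arr[
                rng.choice(config.vocab_size, size=n_bg, p=bg)
            ]
        title = " ".join(tokens[: config.title_len])
        abstract = " ".join(tokens[config.title_len :])
        docs.append(
            AnnotatedDocument(
                doc_id=f"S{i:05d}",
                title=title,
                abstract=abstract,
                labels=frozenset(doc_label_ids),
            )
        )
    return docs, thesaurus, truth


def split(
    corpus: Sequence[AnnotatedDocument], train_frac: float, seed: int
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Seeded shuffle split into disjoint, exhaustive train/test lists."""
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    n_train = int(round(train_frac * len(corpus)))
    train = [corpus[i] for i in order[:n_train]]
    test = [corpus[i] for i in order[n_train:]]
    return train, test
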