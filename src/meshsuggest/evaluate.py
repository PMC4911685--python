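"""Example-based multi-label evaluation metrics.

For each document i with true label set Yi and predicted set Zi:

    precision  |Yi n Zi| / |Zi|        (0 when Zi is empty)
    recall     |Yi n Zi| / |Yi|
    F          2|Yi n Zi| / (|Yi| + |Zi|)
    accuracy   |Yi n Zi| / |Yi u Zi|

EBP/EBR/EBF/Acc are the arithmetic means over documents; MiF is the
micro-averaged F1 over all individual label decisions.  The F formula
restores the conventional factor 2 (harmonic mean of precision and
recall); ``literal_ebf=True`` switches to the variant without it,
|Yi n Zi| / (|Yi| + |Zi|), which is exactly half the standard value.
Documents with an empty true label set cannot be scored; they are
excluded and counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = ["EvalPair", "EvalReport", "example_metrics", "aggregate", "make_pairs"]


@dataclass(frozen=True)
class EvalPair:
    doc_id: str
    true_labels: frozenset[str]
    predicted_labels: frozenset[str]

    def __post_init__(self) -> None:
        if not self.true_labels:
            raise ValueError(
                f"document {self.doc_id!r} has no true labels; exclude it"
            )


@dataclass
class EvalReport:
    m: int
    ebp: float
    ebr: float
    ebf: float
    acc: float
    mif: float
    per_doc: pd.DataFrame
    n_excluded: int = 0


def example_metrics(
    pair: EvalPair, literal_ebf: bool = False
) -> tuple[float, float, float, float]:
    """Per-document (precision, recall, F, accuracy)."""
    y, z = pair.true_labels, pair.predicted_labels
    tp = len(y & z)
    p = tp / len(z) if z else 0.0
    r = tp / len(y)
    factor = 1 if literal_ebf else 2
    f = factor * tp / (len(y) + len(z)) if (y or z) else 0.0
    acc = tp / len(y | z)
    return p, r, f, acc


def aggregate(
    pairs: Sequence[EvalPair],
    literal_ebf: bool = False,
    n_excluded: int = 0,
) -> EvalReport:
    """Mean example-based metrics plus micro-averaged F over all decisions."""
    if not pairs:
        raise ValueError("need at least one evaluation pair")
    rows = []
    tp_total = fp_total = fn_total = 0
    for pair in pairs:
        p, r, f, acc = example_metrics(pair, literal_ebf)
        rows.append(
            {
                "doc_id": pair.doc_id,
                "precision": p,
                "recall": r,
                "f": f,
                "accuracy": acc,
            }
        )
        tp = len(pair.true_labels & pair.predicted_labels)
        tp_total += tp
        fp_total += len(pair.predicted_labels) - tp
        fn_total += len(pair.true_labels) - tp
    per_doc = pd.DataFrame(rows)
    denom = 2 * tp_total + fp_total + fn_total
    mif = 2 * tp_total / denom if denom else 0.0
    return EvalReport(
        m=len(pairs),
        ebp=float(per_doc["precision"].mean()),
        ebr=float(per_doc["recall"].mean()),
        ebf=float(per_doc["f"].mean()),
        acc=float(per_doc["accuracy"].mean()),
        mif=mif,
        per_doc=per_doc,
        n_excluded=n_excluded,
    )


def make_pairs(
    gold: Mapping[str, Iterable[str]],
    predicted: Mapping[str, Iterable[str]],
) -> tuple[list[EvalPair], int]:
    """Join gold and predicted label sets by doc id.

    Documents without gold labels are excluded (second return value
    counts them); documents missing from *predicted* score an empty
    prediction.
    """
    pairs: list[EvalPair] = []
    excluded = 0
    for doc_id, labels in gold.items():
        y = frozenset(labels)
        if not y:
            excluded += 1
            continue
        z = frozenset(predicted.get(doc_id, ()))
        pairs.append(EvalPair(doc_id, y, z))
    return pairs, excluded
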