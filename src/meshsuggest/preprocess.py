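"""Text normalisation and corpus / thesaurus I/O.

Documents are MEDLINE-style citations: a title and an abstract standing
in for the full text, optionally annotated with a set of controlled
descriptors (MeSH-style main headings).  Normalisation is the classic
bag-of-words pipeline: lowercasing, tokenisation on letter/digit runs,
stop-word removal, Porter stemming.  Token order is preserved because
downstream features match entry terms as contiguous token subsequences.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from ._porter import stem

__all__ = [
    "STOPWORDS",
    "AnnotatedDocument",
    "TokenizedDocument",
    "Thesaurus",
    "CorpusFormatError",
    "preprocess_text",
    "tokenize_document",
    "read_corpus",
    "write_corpus",
    "read_thesaurus",
    "write_thesaurus",
]

# Fixed English stop-word list shipped with the package for determinism.
STOPWORDS: frozenset[str] = frozenset("""
a about above after again against all am an and any are as at be because
been before being below between both but by can did do does doing down
during each few for from further had has have having he her here hers
herself him himself his how i if in into is it its itself just me more
most my myself no nor not now of off on once only or other our ours
ourselves out over own same she should so some such than that the their
theirs them themselves then there these they this those through to too
under until up very was we were what when where which while who whom why
will with you your yours yourself yourselves
""".split())

_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class AnnotatedDocument:
    """A citation: id, title, abstract and (possibly empty) label set."""

    doc_id: str
    title: str
    abstract: str
    labels: frozenset[str] = frozenset()

    def text(self) -> str:
        return f"{self.title} {self.abstract}"


@dataclass(frozen=True)
class TokenizedDocument:
    """A citation after normalisation; token order is source order."""

    doc_id: str
    title_tokens: tuple[str, ...]
    abstract_tokens: tuple[str, ...]

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.title_tokens + self.abstract_tokens


@dataclass(frozen=True)
class Descriptor:
    preferred_term: str
    entry_terms: tuple[str, ...]  # always includes the preferred term


@dataclass
class Thesaurus:
    """Maps descriptor ids to their preferred term and entry terms."""

    descriptors: dict[str, Descriptor] = field(default_factory=dict)

    def __contains__(self, descriptor_id: str) -> bool:
        return descriptor_id in self.descriptors

    def __len__(self) -> int:
        return len(self.descriptors)

    def entry_terms(self, descriptor_id: str) -> tuple[str, ...]:
        return self.descriptors[descriptor_id].entry_terms


class CorpusFormatError(ValueError):
    """Raised for malformed corpus or thesaurus files."""


def preprocess_text(
    text: str, stopwords: frozenset[str] = STOPWORDS
) -> list[str]:
    """Lowercase, tokenize, drop stop words and Porter-stem *text*.

    Tokens are maximal runs of Unicode letters and digits; order is
    preserved.  Empty input yields an empty list.
    """
    out = []
    for match in _TOKEN_RE.finditer(text.lower()):
        token = match.group()
        if token in stopwords:
            continue
        out.append(stem(token))
    return out


def tokenize_document(
    doc: AnnotatedDocument, stopwords: frozenset[str] = STOPWORDS
) -> TokenizedDocument:
    return TokenizedDocument(
        doc_id=doc.doc_id,
        title_tokens=tuple(preprocess_text(doc.title, stopwords)),
        abstract_tokens=tuple(preprocess_text(doc.abstract, stopwords)),
    )


def read_corpus(path: str | Path) -> list[AnnotatedDocument]:
    """Read a JSON-lines corpus (keys pmid, title, abstractText, meshMajor).

    ``meshMajor`` may be absent or empty for unannotated documents.
    Raises :class:`CorpusFormatError` naming the offending line for
    malformed JSON, missing keys or duplicate ids.
    """
    docs: list[AnnotatedDocument] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: invalid JSON ({exc})"
                ) from exc
            try:
                doc_id = str(obj["pmid"])
                title = obj["title"]
                abstract = obj["abstractText"]
            except KeyError as exc:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: missing key {exc}"
                ) from exc
            if doc_id in seen:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: duplicate doc id {doc_id!r}"
                )
            seen.add(doc_id)
            labels = frozenset(str(l) for l in obj.get("meshMajor", []))
            docs.append(AnnotatedDocument(doc_id, title, abstract, labels))
    return docs


def write_corpus(docs: Iterable[AnnotatedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(
                json.dumps(
                    {
                        "pmid": doc.doc_id,
                        "title": doc.title,
                        "abstractText": doc.abstract,
                        "meshMajor": sorted(doc.labels),
                    }
                )
                + "\n"
            )


def read_thesaurus(path: str | Path) -> Thesaurus:
    """Read a TSV thesaurus: descriptor_id, preferred_term, entry terms.

    Entry terms are pipe-separated; the preferred term is prepended if
    not already listed.  Duplicate descriptor ids are an error.
    """
    descriptors: dict[str, Descriptor] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected >= 2 tab-separated "
                    f"columns, got {len(parts)}"
                )
            desc_id, preferred = parts[0], parts[1]
            if desc_id in descriptors:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: duplicate descriptor id "
                    f"{desc_id!r}"
                )
            raw_entries = parts[2] if len(parts) > 2 else ""
            entries = [e for e in raw_entries.split("|") if e]
            if preferred not in entries:
                entries.insert(0, preferred)
            descriptors[desc_id] = Descriptor(preferred, tuple(entries))
    return Thesaurus(descriptors)


def write_thesaurus(thesaurus: Thesaurus, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for desc_id, desc in thesaurus.descriptors.items():
            extra = [t for t in desc.entry_terms if t != desc.preferred_term]
            fh.write(f"{desc_id}\t{desc.preferred_term}\t{'|'.join(extra)}\n")
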