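"""Entity lexicon, document corpus and occurrence counting.

The lexicon groups entity names into synonym clusters, each cluster tagged
with one biological category (e.g. disease, drug, gene, target) and headed
by a representative name that stands for the whole cluster in the network.
Documents are dated text records; entity occurrences are detected by exact,
case-insensitive phrase matching on word boundaries — no stemming, no
natural-language processing, no context heuristics.

File formats:

* lexicon — a JSON array of objects
  ``{"representative": str, "category": str, "synonyms": [str, ...]}``;
* corpus — JSON lines, one object per line
  ``{"id": str, "date": "YYYY-MM-DD", "text": str}``.
"""

from __future__ import annotations

import datetime
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .errors import (
    CorpusFormatError,
    DuplicateDocumentError,
    DuplicateRepresentativeError,
    EmptyDocumentError,
    InvalidDateError,
    LexiconFormatError,
    MissingCategoryError,
    SharedSynonymError,
)

__all__ = [
    "EntityCluster",
    "Lexicon",
    "Document",
    "OccurrenceIndex",
    "load_lexicon",
    "load_corpus",
    "filter_by_date",
    "count_occurrences",
]


@dataclass(frozen=True)
class EntityCluster:
    """A set of synonymous entity names treated as one network node.

    ``synonyms`` always contains the representative itself; name comparison
    is case-insensitive throughout.
    """

    representative: str
    category: str
    synonyms: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.representative.strip():
            raise LexiconFormatError("cluster with empty representative name")
        if not self.category.strip():
            raise MissingCategoryError(
                f"cluster {self.representative!r} has no category"
            )
        names = {self.representative} | set(self.synonyms)
        object.__setattr__(
            self, "synonyms", frozenset(n for n in names if n.strip())
        )


class Lexicon:
    """A validated collection of entity clusters.

    Representatives are unique and synonym sets of distinct clusters are
    disjoint (case-insensitively), so every matched phrase maps to exactly
    one network node. ``t`` is the entity-vocabulary size of the network:
    the number of clusters.
    """

    def __init__(self, clusters: Iterable[EntityCluster]):
        self.clusters: tuple[EntityCluster, ...] = tuple(clusters)
        seen_reps: set[str] = set()
        seen_syns: dict[str, str] = {}
        for cl in self.clusters:
            rep_key = cl.representative.casefold()
            if rep_key in seen_reps:
                raise DuplicateRepresentativeError(
                    f"duplicate representative {cl.representative!r}"
                )
            seen_reps.add(rep_key)
            for syn in cl.synonyms:
                key = " ".join(syn.casefold().split())
                if key in seen_syns and seen_syns[key] != cl.representative:
                    raise SharedSynonymError(
                        f"synonym {syn!r} shared by clusters "
                        f"{seen_syns[key]!r} and {cl.representative!r}"
                    )
                seen_syns[key] = cl.representative
        self._by_rep = {cl.representative: cl for cl in self.clusters}

    @property
    def t(self) -> int:
        """Number of clusters (network entity-vocabulary size)."""
        return len(self.clusters)

    @property
    def categories(self) -> tuple[str, ...]:
        """Category names in canonical (lexicographic) order."""
        return tuple(sorted({cl.category for cl in self.clusters}))

    @property
    def representatives(self) -> tuple[str, ...]:
        return tuple(cl.representative for cl in self.clusters)

    def cluster(self, representative: str) -> EntityCluster:
        return self._by_rep[representative]

    def __contains__(self, representative: str) -> bool:
        return representative in self._by_rep

    def category_of(self, representative: str) -> str:
        return self._by_rep[representative].category

    def reps_by_category(self, category: str) -> tuple[str, ...]:
        """Cluster representatives of one category, lexicographically sorted."""
        return tuple(
            sorted(
                cl.representative
                for cl in self.clusters
                if cl.category == category
            )
        )

    def category_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for cl in self.clusters:
            sizes[cl.category] = sizes.get(cl.category, 0) + 1
        return sizes


@dataclass(frozen=True)
class Document:
    """A dated text record (the unit in which co-occurrence is counted)."""

    id: str
    date: datetime.date
    text: str


@dataclass(frozen=True)
class OccurrenceIndex:
    """Per-document entity occurrence counts and the derived statistics.

    ``counts[doc_id][rep]`` is f_{x,i}, the number of phrase matches of
    cluster ``rep`` in document ``doc_id`` (only nonzero entries stored).
    ``max_freq[doc_id]`` is the count of the document's most frequent
    entity (0 when the document matches nothing), ``doc_count`` is N and
    ``doc_freq[rep]`` is n_x, the number of documents containing the
    entity at least once.
    """

    counts: Mapping[str, Mapping[str, int]]
    max_freq: Mapping[str, int]
    doc_count: int
    doc_freq: Mapping[str, int]
    postings: Mapping[str, frozenset[str]]

    def count(self, doc_id: str, rep: str) -> int:
        return self.counts.get(doc_id, {}).get(rep, 0)

    def entities_in(self, doc_id: str) -> tuple[str, ...]:
        """Representatives with at least one occurrence in the document."""
        return tuple(sorted(self.counts.get(doc_id, {})))


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from its JSON file format."""
    raw = Path(path).read_text(encoding="utf-8")
    try:
        data = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise LexiconFormatError(f"{path}: not valid JSON ({exc})") from exc
    if not isinstance(data, list):
        raise LexiconFormatError(f"{path}: expected a JSON array of clusters")
    clusters = []
    for i, entry in enumerate(data):
        if not isinstance(entry, dict) or "representative" not in entry:
            raise LexiconFormatError(
                f"{path}: entry {i} is not a cluster object"
            )
        clusters.append(
            EntityCluster(
                representative=str(entry["representative"]),
                category=str(entry.get("category", "")),
                synonyms=frozenset(map(str, entry.get("synonyms", []))),
            )
        )
    return Lexicon(clusters)


def load_corpus(path: str | Path) -> list[Document]:
    """Load a JSON-lines corpus, preserving file order."""
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            try:
                entry = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusFormatError(
                    f"{path}:{lineno}: not valid JSON ({exc})"
                ) from exc
            if not isinstance(entry, dict) or not {
                "id",
                "date",
                "text",
            } <= entry.keys():
                raise CorpusFormatError(
                    f"{path}:{lineno}: record needs id, date and text fields"
                )
            doc_id = str(entry["id"])
            if doc_id in seen:
                raise DuplicateDocumentError(
                    f"{path}:{lineno}: duplicate document id {doc_id!r}"
                )
            seen.add(doc_id)
            try:
                date = datetime.date.fromisoformat(str(entry["date"]))
            except ValueError as exc:
                raise InvalidDateError(
                    f"{path}:{lineno}: bad date {entry['date']!r}"
                ) from exc
            text = str(entry["text"])
            if not text.strip():
                raise EmptyDocumentError(
                    f"{path}:{lineno}: document {doc_id!r} has empty text"
                )
            docs.append(Document(id=doc_id, date=date, text=text))
    return docs


def filter_by_date(docs: Iterable[Document], last_year: int) -> list[Document]:
    """Documents issued on or before December 31 of ``last_year``.

    Order is preserved; the cutoff is inclusive of the whole year.
    """
    cutoff = datetime.date(last_year, 12, 31)
    return [d for d in docs if d.date <= cutoff]


def _cluster_pattern(cluster: EntityCluster) -> re.Pattern[str]:
    # Longest synonym first so that a phrase embedding a shorter synonym
    # is counted once; \s+ lets phrases match across arbitrary whitespace.
    # Boundaries: a match may not start or end inside an alphanumeric token.
    alternatives = sorted(cluster.synonyms, key=len, reverse=True)
    parts = [
        r"\s+".join(re.escape(tok) for tok in syn.split())
        for syn in alternatives
    ]
    return re.compile(
        r"(?<![0-9A-Za-z])(?:" + "|".join(parts) + r")(?![0-9A-Za-z])",
        re.IGNORECASE,
    )


def count_occurrences(
    docs: Iterable[Document], lexicon: Lexicon
) -> OccurrenceIndex:
    """Count non-overlapping phrase matches of every cluster in every document.

    Matching is case-insensitive and scans each document left to right,
    preferring the longest synonym at each position, so overlapping
    variants of the same entity are never double-counted. Counting one
    cluster is independent of every other cluster, hence of lexicon order.
    """
    patterns = {
        cl.representative: _cluster_pattern(cl) for cl in lexicon.clusters
    }
    counts: dict[str, dict[str, int]] = {}
    max_freq: dict[str, int] = {}
    postings: dict[str, set[str]] = {rep: set() for rep in patterns}
    n_docs = 0
    for doc in docs:
        n_docs += 1
        per_doc: dict[str, int] = {}
        for rep, pattern in patterns.items():
            f = sum(1 for _ in pattern.finditer(doc.text))
            if f:
                per_doc[rep] = f
                postings[rep].add(doc.id)
        if per_doc:
            counts[doc.id] = per_doc
        max_freq[doc.id] = max(per_doc.values(), default=0)
    return OccurrenceIndex(
        counts=counts,
        max_freq=max_freq,
        doc_count=n_docs,
        doc_freq={rep: len(ids) for rep, ids in postings.items()},
        postings={rep: frozenset(ids) for rep, ids in postings.items()},
    )
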