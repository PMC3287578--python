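"""Vector space model: TFIDF entity weights and cosine similarity.

The vocabulary is the network entity set only (the t cluster
representatives), not the full text vocabulary. An entity's weight in a
document is

    w_{x,i} = tf_{x,i} * idf_x,
    tf_{x,i} = f_{x,i} / max_{j,i},
    idf_x   = log(N / n_x),

where f_{x,i} is the entity's occurrence count in document i, max_{j,i}
the count of the document's most frequent entity, N the corpus size and
n_x the number of documents containing the entity. The logarithm base is
configurable (natural log by default); changing it only rescales all
weights by a common factor, which cosine similarity cancels.

Queries are conjunctions of entities from distinct categories with all
query weights fixed at 1; the cosine of a query against a document is

    sim(d_i, q) = sum_{x in q} w_{x,i} / (|d_i| * sqrt(|q|)),

with the document norm |d_i| taken over all t network entities. Only
documents containing every query entity are scored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple

from .corpus import OccurrenceIndex
from .errors import InconsistentIndexError, UndefinedEntityError, UnknownEntityError

__all__ = [
    "EntityWeightMatrix",
    "ConjunctionQuery",
    "SimilarityRecord",
    "term_frequency",
    "inverse_document_frequency",
    "entity_weight",
    "build_weight_matrix",
    "matching_documents",
    "similarity",
    "query_similarities",
]


def term_frequency(f: int, max_f: int) -> float:
    """Normalized frequency f / max_f; 0 for an empty document."""
    if max_f == 0:
        if f != 0:
            raise InconsistentIndexError(f"f={f} but max_f=0")
        return 0.0
    if f > max_f:
        raise InconsistentIndexError(f"f={f} exceeds max_f={max_f}")
    return f / max_f


def inverse_document_frequency(
    n_docs: int, doc_freq: int, base: float = math.e
) -> float:
    """log(N / n_x) in the given base; 0 for a ubiquitous entity."""
    if doc_freq == 0:
        raise UndefinedEntityError("idf undefined for an entity in 0 documents")
    if doc_freq > n_docs:
        raise InconsistentIndexError(
            f"doc_freq={doc_freq} exceeds corpus size {n_docs}"
        )
    return math.log(n_docs / doc_freq) / math.log(base)


def entity_weight(tf: float, idf: float) -> float:
    return tf * idf


@dataclass(frozen=True)
class EntityWeightMatrix:
    """Sparse TFIDF weights plus per-document vector norms.

    ``weights[doc_id][rep]`` holds w_{x,i} for nonzero entries only; the
    norm of a document runs over all t network entities (absent entries
    are zero).
    """

    weights: Mapping[str, Mapping[str, float]]
    norms: Mapping[str, float]

    def weight(self, doc_id: str, rep: str) -> float:
        return self.weights.get(doc_id, {}).get(rep, 0.0)


def build_weight_matrix(
    index: OccurrenceIndex, base: float = math.e
) -> EntityWeightMatrix:
    """TFIDF weight of every occurring entity in every document."""
    n_docs = index.doc_count
    idf = {
        rep: inverse_document_frequency(n_docs, n, base)
        for rep, n in index.doc_freq.items()
        if n > 0
    }
    weights: dict[str, dict[str, float]] = {}
    norms: dict[str, float] = {}
    for doc_id, per_doc in index.counts.items():
        max_f = index.max_freq[doc_id]
        row = {
            rep: entity_weight(term_frequency(f, max_f), idf[rep])
            for rep, f in per_doc.items()
        }
        weights[doc_id] = row
        norms[doc_id] = math.sqrt(math.fsum(w * w for w in row.values()))
    return EntityWeightMatrix(weights=weights, norms=norms)


@dataclass(frozen=True)
class ConjunctionQuery:
    """A conjunction of >=2 distinct entities, each with query weight 1.

    Category distinctness is enforced by the network layer, which forms
    queries from subnetwork cells (one entity per category).
    """

    entities: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.entities) < 2:
            raise ValueError("a conjunction query needs at least 2 entities")
        if len(set(self.entities)) != len(self.entities):
            raise ValueError(f"duplicate entities in query {self.entities!r}")


class SimilarityRecord(NamedTuple):
    doc_id: str
    similarity: float


def matching_documents(
    q: ConjunctionQuery, index: OccurrenceIndex
) -> set[str]:
    """Documents containing every query entity at least once."""
    result: set[str] | None = None
    for rep in q.entities:
        if rep not in index.doc_freq:
            raise UnknownEntityError(f"query entity {rep!r} not in lexicon")
        ids = index.postings.get(rep, frozenset())
        result = set(ids) if result is None else result & ids
        if not result:
            return set()
    return result or set()


def similarity(
    q: ConjunctionQuery, doc_id: str, matrix: EntityWeightMatrix
) -> float:
    """Cosine of a conjunction query against one (matching) document.

    A document whose every contained entity has idf 0 has a zero norm;
    it scores 0 with a warning rather than raising.
    """
    norm = matrix.norms.get(doc_id, 0.0)
    if norm == 0.0:
        warnings.warn(
            f"document {doc_id!r} has zero weight norm; similarity set to 0",
            stacklevel=2,
        )
        return 0.0
    numerator = math.fsum(matrix.weight(doc_id, x) for x in q.entities)
    # Cauchy-Schwarz bounds the cosine by 1; clamp float overshoot.
    return min(1.0, numerator / (norm * math.sqrt(len(q.entities))))


def query_similarities(
    q: ConjunctionQuery,
    matrix: EntityWeightMatrix,
    index: OccurrenceIndex,
) -> list[SimilarityRecord]:
    """Similarity of every conjunction-satisfying document to the query.

    Sorted by similarity descending, ties broken by document id.
    """
    records = [
        SimilarityRecord(doc_id, similarity(q, doc_id, matrix))
        for doc_id in matching_documents(q, index)
    ]
    records.sort(key=lambda r: (-r.similarity, r.doc_id))
    return records
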