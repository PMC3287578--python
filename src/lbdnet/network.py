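"""Subnetwork enumeration and known-interaction network construction.

A network over c entity categories is composed of one subnetwork per
combination of >=2 distinct categories (2^c - c - 1 subnetworks in
total; 11 for four categories). Each subnetwork is a matrix whose cells
are tuples of cluster representatives, one per category in canonical
(lexicographic) category order. A cell is *known* when at least one
document contains all of its entities; its interaction level aggregates
the VSM similarities of those documents under one of three strategies:
arithmetic average, maximum, or sum. Cells with no co-occurring document
stay *absent* (level 0) until closure inference possibly turns them
*new*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

from .corpus import Document, Lexicon, count_occurrences
from .errors import UnknownEntityError
from .vsm import (
    ConjunctionQuery,
    SimilarityRecord,
    build_weight_matrix,
    query_similarities,
)

__all__ = [
    "ABSENT",
    "KNOWN",
    "NEW",
    "STRATEGIES",
    "SubnetworkSpec",
    "InteractionCell",
    "Subnetwork",
    "Network",
    "enumerate_subnetworks",
    "count_possible_interactions",
    "aggregate_level",
    "build_known_network",
    "write_network_tsv",
]

ABSENT = "absent"
KNOWN = "known"
NEW = "new"

STRATEGIES = ("average", "maximum", "sum")


@dataclass(frozen=True)
class SubnetworkSpec:
    """An ordered tuple of >=2 distinct categories (the dimensional space)."""

    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError("a subnetwork needs at least 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"repeated category in {self.categories!r}")
        object.__setattr__(self, "categories", tuple(sorted(self.categories)))

    @property
    def label(self) -> str:
        return "x".join(self.categories)

    @property
    def n_dimensions(self) -> int:
        return len(self.categories)


@dataclass
class InteractionCell:
    """One cell of a subnetwork matrix.

    ``support`` holds the evidence: for a known cell, the per-document
    similarity records of its conjunction query; for a new cell, the
    winning closure triple. ``trace`` records the full inference history
    of a new cell.
    """

    entities: tuple[str, ...]
    status: str
    level: float
    iteration: int
    support: object = None
    trace: object = None


class Subnetwork:
    """A matrix of interaction cells over one category combination.

    Only non-absent cells are materialised in ``cells``; every tuple in
    the Cartesian product of the per-category axes is addressable and
    reads as absent when missing.
    """

    def __init__(
        self,
        spec: SubnetworkSpec,
        axes: Mapping[str, Sequence[str]],
        strategy: str = "average",
    ):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}")
        self.spec = spec
        self.axes: dict[str, tuple[str, ...]] = {
            cat: tuple(axes[cat]) for cat in spec.categories
        }
        self.strategy = strategy
        self.cells: dict[tuple[str, ...], InteractionCell] = {}

    @classmethod
    def from_known(
        cls,
        categories: Sequence[str],
        axes: Mapping[str, Sequence[str]],
        known_levels: Mapping[tuple[str, ...], float],
        strategy: str = "average",
    ) -> "Subnetwork":
        """Build a subnetwork directly from known cell levels.

        Convenience constructor for programmatic use (e.g. studying the
        closure on hand-made matrices without a corpus).
        """
        sub = cls(SubnetworkSpec(tuple(categories)), axes, strategy)
        for key, level in known_levels.items():
            sub.cells[tuple(key)] = InteractionCell(
                entities=tuple(key),
                status=KNOWN,
                level=level,
                iteration=0,
                support=[],
            )
        return sub

    @property
    def n_possible(self) -> int:
        return math.prod(len(self.axes[c]) for c in self.spec.categories)

    def possible_cells(self) -> Iterator[tuple[str, ...]]:
        """Every entity tuple of the matrix, in axis order."""
        return itertools.product(
            *(self.axes[c] for c in self.spec.categories)
        )

    def absent_cells(self) -> Iterator[tuple[str, ...]]:
        return (key for key in self.possible_cells() if key not in self.cells)

    def status(self, key: tuple[str, ...]) -> str:
        cell = self.cells.get(key)
        return ABSENT if cell is None else cell.status

    def level(self, key: tuple[str, ...]) -> float:
        cell = self.cells.get(key)
        return 0.0 if cell is None else cell.level


@dataclass
class Network:
    """All subnetworks built from one lexicon/corpus/strategy combination."""

    subnetworks: list[Subnetwork] = field(default_factory=list)

    def get(self, categories: Sequence[str]) -> Subnetwork:
        key = tuple(sorted(categories))
        for sub in self.subnetworks:
            if sub.spec.categories == key:
                return sub
        raise KeyError(f"no subnetwork over categories {key!r}")


def enumerate_subnetworks(categories: Sequence[str]) -> list[SubnetworkSpec]:
    """All combinations of >=2 distinct categories, canonically ordered.

    For c categories this yields 2^c - c - 1 subnetworks.
    """
    cats = sorted(set(categories))
    if len(cats) < 2:
        raise ValueError("need at least 2 categories to form subnetworks")
    return [
        SubnetworkSpec(combo)
        for size in range(2, len(cats) + 1)
        for combo in itertools.combinations(cats, size)
    ]


def count_possible_interactions(
    lexicon: Lexicon, specs: Iterable[SubnetworkSpec]
) -> int:
    """Total cell count: sum over subnetworks of the product of axis sizes."""
    sizes = lexicon.category_sizes()
    total = 0
    for spec in specs:
        for cat in spec.categories:
            if cat not in sizes:
                raise UnknownEntityError(f"category {cat!r} not in lexicon")
        total += math.prod(sizes[cat] for cat in spec.categories)
    return total


def aggregate_level(sims: Sequence[float], strategy: str) -> float:
    """Collapse the similarities of a cell's matching documents to a level."""
    if not sims:
        raise ValueError("a known interaction needs at least one document")
    if strategy == "average":
        return math.fsum(sims) / len(sims)
    if strategy == "maximum":
        return max(sims)
    if strategy == "sum":
        return math.fsum(sims)
    raise ValueError(f"unknown strategy {strategy!r}")


def build_known_network(
    docs: Sequence[Document],
    lexicon: Lexicon,
    strategy: str = "average",
    idf_base: float = math.e,
) -> Network:
    """Establish every known interaction of every subnetwork.

    For each cell whose entities all co-occur in at least one document,
    the cell's conjunction query is scored against its matching documents
    and the similarities are aggregated under the chosen strategy. Cells
    with no co-occurrence are left absent. Candidate cells are discovered
    from the documents (a cell can only be known if some single document
    contains all of its entities), so the full Cartesian product is never
    scanned.
    """
    index = count_occurrences(docs, lexicon)
    matrix = build_weight_matrix(index, base=idf_base)
    specs = enumerate_subnetworks(lexicon.categories)
    category_of = {
        cl.representative: cl.category for cl in lexicon.clusters
    }
    # Per document: entities grouped by category, for candidate generation.
    per_doc_by_cat: dict[str, dict[str, list[str]]] = {}
    for doc_id, per_doc in index.counts.items():
        grouped: dict[str, list[str]] = {}
        for rep in sorted(per_doc):
            grouped.setdefault(category_of[rep], []).append(rep)
        per_doc_by_cat[doc_id] = grouped

    net = Network()
    for spec in specs:
        axes = {cat: lexicon.reps_by_category(cat) for cat in spec.categories}
        sub = Subnetwork(spec, axes, strategy)
        candidates: set[tuple[str, ...]] = set()
        for grouped in per_doc_by_cat.values():
            if all(cat in grouped for cat in spec.categories):
                candidates.update(
                    itertools.product(
                        *(grouped[cat] for cat in spec.categories)
                    )
                )
        for key in sorted(candidates):
            query = ConjunctionQuery(entities=key)
            records: list[SimilarityRecord] = query_similarities(
                query, matrix, index
            )
            sub.cells[key] = InteractionCell(
                entities=key,
                status=KNOWN,
                level=aggregate_level([r.similarity for r in records], strategy),
                iteration=0,
                support=records,
            )
        net.subnetworks.append(sub)
    return net


def write_network_tsv(net: Network, handle: IO[str]) -> None:
    """Dump a network as TSV: one row per non-absent cell.

    Columns: subnetwork label, "|"-joined entity tuple, status, level
    (9 decimal places), iteration, support size. Rows are sorted, so the
    export of a deterministic build is byte-identical across runs.
    """
    handle.write("subnetwork\tentities\tstatus\tlevel\titeration\tsupport_size\n")
    for sub in net.subnetworks:
        for key in sorted(sub.cells):
            cell = sub.cells[key]
            if cell.status == KNOWN:
                support_size = len(cell.support or [])
            else:
                support_size = 3  # a new cell rests on one closure triple
            handle.write(
                f"{sub.spec.label}\t{'|'.join(key)}\t{cell.status}\t"
                f"{cell.level:.9f}\t{cell.iteration}\t{support_size}\n"
            )
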