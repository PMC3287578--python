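"""Temporal hold-out validation of inferred interactions.

The network is rebuilt on year-limited corpus slices (documents issued
up to December 31 of each year). An interaction predicted as *new* from
the slice of year y and established as *known* in the slice of year y+1
is a *confirmation*: a later document reports the co-occurrence the
closure anticipated. For each confirmation we record its 1-based rank in
year y's per-subnetwork new-interaction ranking, and summarise how many
confirmations fall within the top K of their subnetwork.

Confirmations are counted at interaction granularity (an interaction
confirmed by one or more later documents counts once); the number of
confirming documents is reported alongside.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import IO, Sequence

from .corpus import Document, Lexicon, filter_by_date
from .inference import run_network_inference
from .network import KNOWN, NEW, Network, build_known_network

__all__ = [
    "YearSlice",
    "Confirmation",
    "ValidationReport",
    "build_year_slices",
    "find_confirmations",
    "topk_distribution",
    "strategy_sweep",
    "write_validation_tsv",
    "write_validation_json",
]


@dataclass
class YearSlice:
    """A fully inferred network built from documents issued <= a year."""

    year: int
    network: Network
    n_documents: int


@dataclass(frozen=True)
class Confirmation:
    """A prediction of slice y that became known in a later slice."""

    subnetwork: tuple[str, ...]
    entities: tuple[str, ...]
    level_prior: float
    level_next: float
    supporting_docs_prior: int
    confirming_docs_next: int
    rank_prior: int


@dataclass
class ValidationReport:
    """Per-subnetwork confirmation and top-K membership counts."""

    k: int
    per_subnetwork: dict[tuple[str, ...], dict[str, int]] = field(
        default_factory=dict
    )
    total_confirmations: int = 0
    total_topk: int = 0
    percentage: float | None = None


def build_year_slices(
    docs: Sequence[Document],
    lexicon: Lexicon,
    strategy: str = "average",
    years: tuple[int, int] = (0, 0),
    idf_base: float = math.e,
    max_iterations: int = 100,
) -> list[YearSlice]:
    """One fully inferred network per year of the inclusive range.

    Each slice is rebuilt from scratch on the filtered corpus, so slice
    corpora are nested and known interactions are monotone across years.
    """
    first, last = years
    if first > last:
        raise ValueError(f"empty year range {years!r}")
    slices = []
    for year in range(first, last + 1):
        subset = filter_by_date(docs, year)
        net = build_known_network(
            subset, lexicon, strategy=strategy, idf_base=idf_base
        )
        run_network_inference(net, max_iterations=max_iterations)
        slices.append(YearSlice(year=year, network=net, n_documents=len(subset)))
    return slices


def _known_doc_ids(cell) -> set[str]:
    if cell is None or cell.status != KNOWN:
        return set()
    return {record.doc_id for record in cell.support or []}


def find_confirmations(
    slice_y: YearSlice, slice_next: YearSlice
) -> list[Confirmation]:
    """Interactions new in slice y that are known in the later slice.

    ``rank_prior`` is the cell's 1-based position in the year-y ranking
    of new interactions of its own subnetwork. ``supporting_docs_prior``
    counts the distinct documents behind the known cells of the winning
    closure triple in year y; ``confirming_docs_next`` counts the later
    slice's matching documents not present in year y.
    """
    confirmations: list[Confirmation] = []
    for sub_y in slice_y.network.subnetworks:
        sub_next = slice_next.network.get(sub_y.spec.categories)
        new_cells = [
            cell for cell in sub_y.cells.values() if cell.status == NEW
        ]
        new_cells.sort(key=lambda c: (-c.level, c.entities))
        for rank, cell in enumerate(new_cells, start=1):
            cell_next = sub_next.cells.get(cell.entities)
            if cell_next is None or cell_next.status != KNOWN:
                continue
            triple = cell.support
            prior_docs: set[str] = set()
            for support_key in triple.cells:
                prior_docs |= _known_doc_ids(sub_y.cells.get(support_key))
            next_docs = _known_doc_ids(cell_next)
            confirmations.append(
                Confirmation(
                    subnetwork=sub_y.spec.categories,
                    entities=cell.entities,
                    level_prior=cell.level,
                    level_next=cell_next.level,
                    supporting_docs_prior=len(prior_docs),
                    confirming_docs_next=len(next_docs),
                    rank_prior=rank,
                )
            )
    return confirmations


def topk_distribution(
    confirmations: Sequence[Confirmation], k: int
) -> ValidationReport:
    """Count confirmations ranked within the top K of their subnetwork.

    The overall percentage is 100 * sum(top-K) / sum(confirmations); it
    is reported as absent (None) when there are no confirmations.
    """
    report = ValidationReport(k=k)
    for conf in confirmations:
        entry = report.per_subnetwork.setdefault(
            conf.subnetwork, {"confirmed": 0, "topk": 0}
        )
        entry["confirmed"] += 1
        if conf.rank_prior <= k:
            entry["topk"] += 1
    report.total_confirmations = len(confirmations)
    report.total_topk = sum(
        e["topk"] for e in report.per_subnetwork.values()
    )
    if report.total_confirmations:
        report.percentage = (
            100.0 * report.total_topk / report.total_confirmations
        )
    return report


def strategy_sweep(
    docs: Sequence[Document],
    lexicon: Lexicon,
    year: int,
    k: int = 100,
    strategies: Sequence[str] = ("average", "maximum", "sum"),
    idf_base: float = math.e,
    max_iterations: int = 100,
) -> dict[str, tuple[list[Confirmation], ValidationReport]]:
    """Confirmations of year -> year+1 under each aggregation strategy.

    The confirmation *set* is strategy-independent (statuses depend only
    on co-occurrence and closure structure); the rank positions, and
    hence the top-K counts, differ per strategy.
    """
    results: dict[str, tuple[list[Confirmation], ValidationReport]] = {}
    for strategy in strategies:
        slices = build_year_slices(
            docs,
            lexicon,
            strategy=strategy,
            years=(year, year + 1),
            idf_base=idf_base,
            max_iterations=max_iterations,
        )
        confs = find_confirmations(slices[0], slices[1])
        results[strategy] = (confs, topk_distribution(confs, k))
    return results


def write_validation_tsv(
    sweep: dict[str, tuple[list[Confirmation], ValidationReport]],
    new_counts: dict[tuple[str, ...], int],
    handle: IO[str],
) -> None:
    """Per-subnetwork table: predictions, confirmations, top-K per strategy."""
    strategies = list(sweep)
    header = "subnetwork\tnew_in_year\tconfirmed"
    for s in strategies:
        header += f"\ttop{sweep[s][1].k}_{s}"
    handle.write(header + "\n")
    subnets = sorted(new_counts)
    first_strategy = strategies[0]
    confirmed_by_subnet: dict[tuple[str, ...], int] = {}
    for conf in sweep[first_strategy][0]:
        confirmed_by_subnet[conf.subnetwork] = (
            confirmed_by_subnet.get(conf.subnetwork, 0) + 1
        )
    for subnet in subnets:
        row = [
            "x".join(subnet),
            str(new_counts.get(subnet, 0)),
            str(confirmed_by_subnet.get(subnet, 0)),
        ]
        for s in strategies:
            per = sweep[s][1].per_subnetwork.get(subnet, {"topk": 0})
            row.append(str(per["topk"]))
        handle.write("\t".join(row) + "\n")


def write_validation_json(
    sweep: dict[str, tuple[list[Confirmation], ValidationReport]],
    handle: IO[str],
) -> None:
    payload = {}
    for strategy, (confs, report) in sweep.items():
        payload[strategy] = {
            "k": report.k,
            "total_confirmations": report.total_confirmations,
            "total_topk": report.total_topk,
            "percentage": report.percentage,
            "confirmations": [
                {
                    "subnetwork": list(c.subnetwork),
                    "entities": list(c.entities),
                    "level_prior": c.level_prior,
                    "level_next": c.level_next,
                    "supporting_docs_prior": c.supporting_docs_prior,
                    "confirming_docs_next": c.confirming_docs_next,
                    "rank_prior": c.rank_prior,
                }
                for c in confs
            ],
        }
    json.dump(payload, handle, indent=2)
    handle.write("\n")
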