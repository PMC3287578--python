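"""Category-constrained transitive-closure inference over a subnetwork.

The closure rule: IF entity x interacts with entities y and w AND entity
z interacts with y, THEN z may interact with w — where x and z belong to
one category and y and w to the complementary dimension(s). On an
n-dimensional subnetwork the rule is applied over every bipartition of
the categories into a pivot category (rows x, z) and the composite of
the remaining categories (columns y, w); all bipartitions' triples
compete.

A candidate new interaction scores the arithmetic mean (A+B+C)/3 of its
three supporting levels; among several candidates the highest mean wins.
Inference proceeds in synchronous iterations: iteration k uses only
cells established in iterations < k, and a cell inferred at iteration k
receives level best_mean / k, penalising late discoveries. Iteration
stops at a fixpoint (no absent cell has a valid triple) or when the
matrix is full.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Sequence

from .errors import HistoryError
from .network import ABSENT, KNOWN, NEW, InteractionCell, Network, Subnetwork

__all__ = [
    "ClosureTriple",
    "TraceEntry",
    "InferenceTrace",
    "RankedInteraction",
    "find_closure_triples",
    "candidate_level",
    "select_best_triple",
    "infer_iteration",
    "run_inference",
    "run_network_inference",
    "rank_interactions",
    "trace_history",
    "trace_to_dict",
    "write_trace_json",
    "write_ranking_tsv",
]

CellKey = tuple[str, ...]


@dataclass(frozen=True)
class ClosureTriple:
    """Three supporting cells (x,y), (x,w), (z,y) for a target (z,w).

    ``cells`` are full entity tuples in canonical category order, in role
    order. ``candidate_level`` is the mean of the three supporting levels,
    summed in sorted-cell order so that equivalent bipartition readings of
    the same support set produce bit-identical candidates.
    """

    pivot: str
    cells: tuple[CellKey, CellKey, CellKey]
    levels: tuple[float, float, float]
    candidate_level: float

    @property
    def sort_key(self) -> tuple[CellKey, ...]:
        return tuple(sorted(self.cells))


@dataclass(frozen=True)
class TraceEntry:
    iteration: int
    triple: ClosureTriple
    candidate_level: float
    accepted: bool


@dataclass
class InferenceTrace:
    """Every candidate triple examined for one new cell."""

    target: CellKey
    entries: list[TraceEntry] = field(default_factory=list)
    final_level: float = 0.0
    final_iteration: int = 0


def _drop(key: CellKey, pos: int) -> CellKey:
    return key[:pos] + key[pos + 1 :]


def _merge(row: str, col: CellKey, pos: int) -> CellKey:
    return col[:pos] + (row,) + col[pos:]


def _mean_sorted(
    levels_by_cell: dict[CellKey, float], cells: Iterable[CellKey]
) -> float:
    ordered = sorted(cells)
    return (
        levels_by_cell[ordered[0]]
        + levels_by_cell[ordered[1]]
        + levels_by_cell[ordered[2]]
    ) / 3.0


def find_closure_triples(
    sub: Subnetwork,
    target: CellKey,
    available: Callable[[CellKey], bool] | None = None,
) -> list[ClosureTriple]:
    """All closure triples supporting an absent target cell.

    ``available`` restricts which non-absent cells may support the
    inference (used for synchronous iteration snapshots). Triples whose
    three supporting cells coincide as a set — the same closure instance
    read from a different bipartition — are reported once.
    """
    if available is None:
        avail = set(sub.cells)
    else:
        avail = {k for k in sub.cells if available(k)}
    level_of = {k: sub.cells[k].level for k in avail}
    triples: dict[tuple[CellKey, ...], ClosureTriple] = {}
    cats = sub.spec.categories
    for pos, pivot in enumerate(cats):
        z = target[pos]
        w = _drop(target, pos)
        columns_of: dict[str, set[CellKey]] = {}
        for key in avail:
            columns_of.setdefault(key[pos], set()).add(_drop(key, pos))
        cols_z = columns_of.get(z, set())
        for x, cols_x in columns_of.items():
            if x == z or w not in cols_x:
                continue
            for y in cols_x & cols_z:
                if y == w:
                    continue
                cell_xy = _merge(x, y, pos)
                cell_xw = _merge(x, w, pos)
                cell_zy = _merge(z, y, pos)
                support = (cell_xy, cell_xw, cell_zy)
                dedupe_key = tuple(sorted(support))
                if dedupe_key in triples:
                    continue
                triples[dedupe_key] = ClosureTriple(
                    pivot=pivot,
                    cells=support,
                    levels=(
                        level_of[cell_xy],
                        level_of[cell_xw],
                        level_of[cell_zy],
                    ),
                    candidate_level=_mean_sorted(level_of, support),
                )
    return [triples[k] for k in sorted(triples)]


def candidate_level(triple: ClosureTriple) -> float:
    """The mean of the three supporting levels, (A+B+C)/3."""
    return triple.candidate_level


def select_best_triple(triples: Sequence[ClosureTriple]) -> ClosureTriple:
    """The triple with the highest candidate level.

    Ties break lexicographically on the sorted supporting entity tuples,
    making selection deterministic.
    """
    if not triples:
        raise ValueError("no closure triples to select from")
    return min(triples, key=lambda t: (-t.candidate_level, t.sort_key))


def _candidate_targets(sub: Subnetwork, snapshot: frozenset[CellKey]) -> set[CellKey]:
    """Absent cells that have at least one closure triple over ``snapshot``.

    Generated from the established structure (a target needs a pivot with
    x != z, w in columns(x) and a shared column y != w), so the full
    Cartesian product of the matrix is never scanned.
    """
    candidates: set[CellKey] = set()
    for pos in range(len(sub.spec.categories)):
        columns_of: dict[str, set[CellKey]] = {}
        for key in snapshot:
            columns_of.setdefault(key[pos], set()).add(_drop(key, pos))
        for x, cols_x in columns_of.items():
            for z, cols_z in columns_of.items():
                if x == z:
                    continue
                common = cols_x & cols_z
                if not common:
                    continue
                for w in cols_x:
                    target = _merge(z, w, pos)
                    if target in sub.cells:
                        continue
                    if common - {w}:
                        candidates.add(target)
    return candidates


def infer_iteration(sub: Subnetwork, k: int) -> set[CellKey]:
    """Run one synchronous inference iteration; returns the new cell keys.

    Only cells established in iterations < k may support an inference, so
    cells created within the same iteration never feed each other.
    """
    if k < 1:
        raise ValueError("iterations are numbered from 1")
    snapshot = frozenset(
        key for key, cell in sub.cells.items() if cell.iteration < k
    )
    additions: dict[CellKey, InteractionCell] = {}
    for target in sorted(_candidate_targets(sub, snapshot)):
        triples = find_closure_triples(
            sub, target, available=lambda key: key in snapshot
        )
        if not triples:
            continue
        best = select_best_triple(triples)
        trace = InferenceTrace(
            target=target,
            entries=[
                TraceEntry(k, t, t.candidate_level, t is best) for t in triples
            ],
            final_level=best.candidate_level / k,
            final_iteration=k,
        )
        additions[target] = InteractionCell(
            entities=target,
            status=NEW,
            level=best.candidate_level / k,
            iteration=k,
            support=best,
            trace=trace,
        )
    sub.cells.update(additions)
    return set(additions)


def run_inference(sub: Subnetwork, max_iterations: int = 100) -> Subnetwork:
    """Iterate the closure to fixpoint on one subnetwork (in place).

    Stops when an iteration adds nothing or no absent cell remains; known
    cells are never modified. ``max_iterations`` is a safety valve that
    warns if reached while progress was still being made.
    """
    for k in range(1, max_iterations + 1):
        added = infer_iteration(sub, k)
        if not added:
            return sub
        if len(sub.cells) == sub.n_possible:
            return sub
    warnings.warn(
        f"inference stopped at the {max_iterations}-iteration cap with "
        f"absent cells remaining in {sub.spec.label}",
        stacklevel=2,
    )
    return sub


def run_network_inference(
    net: Network, max_iterations: int = 100
) -> Network:
    for sub in net.subnetworks:
        run_inference(sub, max_iterations=max_iterations)
    return net


@dataclass(frozen=True)
class RankedInteraction:
    subnetwork: tuple[str, ...]
    entities: CellKey
    status: str
    level: float
    iteration: int


def rank_interactions(
    net: Network,
    status: str = "all",
    subnetworks: Sequence[Sequence[str]] | None = None,
    top_k: int | None = None,
) -> list[RankedInteraction]:
    """Interactions sorted by level descending (deterministic tie order).

    ``status`` filters on {known, new, all}; ``subnetworks`` restricts to
    the given category combinations. Ties break on subnetwork label then
    entity tuple.
    """
    if status not in (KNOWN, NEW, ABSENT, "all"):
        raise ValueError(f"unknown status filter {status!r}")
    wanted: set[tuple[str, ...]] | None = None
    if subnetworks is not None:
        wanted = {tuple(sorted(cats)) for cats in subnetworks}
    rows: list[RankedInteraction] = []
    for sub in net.subnetworks:
        if wanted is not None and sub.spec.categories not in wanted:
            continue
        for key, cell in sub.cells.items():
            if status != "all" and cell.status != status:
                continue
            rows.append(
                RankedInteraction(
                    subnetwork=sub.spec.categories,
                    entities=key,
                    status=cell.status,
                    level=cell.level,
                    iteration=cell.iteration,
                )
            )
    rows.sort(key=lambda r: (-r.level, r.subnetwork, r.entities))
    return rows[:top_k] if top_k is not None else rows


def trace_history(sub: Subnetwork, target: CellKey) -> InferenceTrace:
    """The recorded inference history of a new cell."""
    cell = sub.cells.get(tuple(target))
    if cell is None:
        raise HistoryError(f"cell {target!r} is absent; no inference history")
    if cell.status != NEW:
        raise HistoryError(
            f"cell {target!r} is {cell.status}; history exists only for "
            "new interactions"
        )
    return cell.trace


def trace_to_dict(trace: InferenceTrace) -> dict:
    iterations: dict[int, list[dict]] = {}
    for entry in trace.entries:
        iterations.setdefault(entry.iteration, []).append(
            {
                "cells": [list(c) for c in entry.triple.cells],
                "levels": list(entry.triple.levels),
                "average": entry.candidate_level,
                "accepted": entry.accepted,
            }
        )
    return {
        "target": list(trace.target),
        "iterations": [
            {"k": k, "triples": triples}
            for k, triples in sorted(iterations.items())
        ],
        "final_level": trace.final_level,
        "final_iteration": trace.final_iteration,
    }


def write_trace_json(trace: InferenceTrace, handle: IO[str]) -> None:
    json.dump(trace_to_dict(trace), handle, indent=2, sort_keys=False)
    handle.write("\n")


def write_ranking_tsv(
    rows: Sequence[RankedInteraction], handle: IO[str]
) -> None:
    handle.write("rank\tsubnetwork\tentities\tstatus\tlevel\titeration\n")
    for rank, row in enumerate(rows, start=1):
        handle.write(
            f"{rank}\t{'x'.join(row.subnetwork)}\t{'|'.join(row.entities)}\t"
            f"{row.status}\t{row.level:.9f}\t{row.iteration}\n"
        )
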