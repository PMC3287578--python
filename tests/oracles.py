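"""Independent reference implementations used as test oracles.

These deliberately use the most naive formulation possible — exhaustive
quadruple enumeration, per-document rescanning, scalar arithmetic — and
share no code with the package internals they check.
"""

from __future__ import annotations

import itertools
import math
import random


def _drop(key, pos):
    return key[:pos] + key[pos + 1 :]


def _merge(row, col, pos):
    return col[:pos] + (row,) + col[pos:]


def naive_closure_fixpoint(axes, known_levels):
    """Brute-force transitive-closure fixpoint on one subnetwork matrix.

    ``axes`` is a tuple of per-category entity tuples (canonical order);
    ``known_levels`` maps known cell tuples to levels. Returns a dict
    cell -> (status, iteration, level) for every cell of the matrix,
    computed by enumerating all (pivot, x, z, y, w) quadruples, picking
    the highest mean with lexicographic tie-break on the sorted support
    cells, and applying the synchronous staging and 1/k penalty.
    """
    state = {
        key: ("known", 0, level) for key, level in known_levels.items()
    }
    all_cells = list(itertools.product(*axes))
    k = 0
    while True:
        k += 1
        additions = {}
        for target in all_cells:
            if target in state:
                continue
            candidates = {}
            for pos in range(len(axes)):
                z = target[pos]
                w = _drop(target, pos)
                other_axes = [axes[i] for i in range(len(axes)) if i != pos]
                for x in axes[pos]:
                    if x == z:
                        continue
                    for y in itertools.product(*other_axes):
                        if y == w:
                            continue
                        cell_xy = _merge(x, y, pos)
                        cell_xw = _merge(x, w, pos)
                        cell_zy = _merge(z, y, pos)
                        if (
                            cell_xy in state
                            and cell_xw in state
                            and cell_zy in state
                        ):
                            support = tuple(
                                sorted((cell_xy, cell_xw, cell_zy))
                            )
                            mean = (
                                state[support[0]][2]
                                + state[support[1]][2]
                                + state[support[2]][2]
                            ) / 3.0
                            candidates[support] = mean
            if candidates:
                best_support, best_mean = min(
                    candidates.items(), key=lambda item: (-item[1], item[0])
                )
                additions[target] = ("new", k, best_mean / k)
        if not additions:
            break
        state.update(additions)
        if len(state) == len(all_cells):
            break
    for cell in all_cells:
        state.setdefault(cell, ("absent", 0, 0.0))
    return state


def scalar_tfidf(f, max_f, n_docs, n_x, base=math.e):
    """w = (f / max_f) * log_base(N / n_x), evaluated term by term."""
    if max_f == 0 or f == 0:
        return 0.0
    return (f / max_f) * (math.log(n_docs / n_x) / math.log(base))


def cooccurrence_scan(docs_entities, entity_tuple):
    """Documents (given as id -> set of entities) containing the whole tuple."""
    return {
        doc_id
        for doc_id, present in docs_entities.items()
        if all(e in present for e in entity_tuple)
    }


def random_known_levels(axes, density, rng: random.Random):
    """Random known cells with uniform levels over a matrix."""
    known = {}
    for cell in itertools.product(*axes):
        if rng.random() < density:
            known[cell] = rng.uniform(0.05, 1.0)
    return known


def make_axes(sizes, rng: random.Random | None = None):
    """Entity axes like (('a1','a2'), ('b1','b2','b3')) for given sizes."""
    letters = "abcdefgh"
    return tuple(
        tuple(f"{letters[i]}{j}" for j in range(1, size + 1))
        for i, size in enumerate(sizes)
    )
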