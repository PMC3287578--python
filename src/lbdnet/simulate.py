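"""Seeded synthetic lexicons and corpora with planted structure.

The generator emulates the shape of a dated biomedical document
collection: synonym-clustered entity names from several categories,
documents that mention a controlled set of entities 1-3 times each
amid filler words, and issue dates spread over a year range. Planted
co-occurrence tuples become known interactions; planted closure
patterns — the edges (x,y), (x,w), (z,y) present, (z,w) withheld —
become inferable new interactions, optionally confirmed by a document
published in a later year. Filler vocabulary is disjoint from every
lexicon name, so entity counts are exactly controllable and the
returned expected sets are exact ground truth for network construction
and closure inference.
"""

from __future__ import annotations

import datetime
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

import yaml

from .corpus import Document, EntityCluster, Lexicon

__all__ = [
    "PlantedKnown",
    "PlantedClosure",
    "SimulationConfig",
    "generate",
    "published_scale_config",
    "demo_config",
    "temporal_demo_config",
    "write_lexicon_json",
    "write_corpus_jsonl",
]

ExpectedSet = frozenset[tuple[tuple[str, ...], tuple[str, ...]]]


@dataclass(frozen=True)
class PlantedKnown:
    """A tuple of entities co-occurring in a fixed number of documents."""

    entities: tuple[str, ...]
    documents: int = 1


@dataclass(frozen=True)
class PlantedClosure:
    """A withheld interaction reachable by one closure step.

    Documents are generated for the pairs (x, y), (x, w) and (z, y);
    the pair (z, w) is withheld, making it inferable. With
    ``confirm_year`` set (strictly after the corpus year range), one
    document containing z and w is issued in that year, so temporal
    validation sees the prediction confirmed.
    """

    x: str
    z: str
    y: str
    w: str
    docs_per_edge: int = 1
    confirm_year: int | None = None


@dataclass
class SimulationConfig:
    categories: dict[str, int] = field(default_factory=dict)
    synonyms_per_cluster: int = 2
    n_documents: int = 20
    year_range: tuple[int, int] = (2000, 2004)
    planted_known: list[PlantedKnown] = field(default_factory=list)
    planted_closures: list[PlantedClosure] = field(default_factory=list)
    filler_vocabulary_size: int = 40
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a mapping at top level")
        known = [
            PlantedKnown(
                entities=tuple(item["entities"]),
                documents=int(item.get("documents", 1)),
            )
            for item in data.get("planted_known", [])
        ]
        closures = [
            PlantedClosure(
                x=item["x"],
                z=item["z"],
                y=item["y"],
                w=item["w"],
                docs_per_edge=int(item.get("docs_per_edge", 1)),
                confirm_year=item.get("confirm_year"),
            )
            for item in data.get("planted_closures", [])
        ]
        year_range = tuple(data.get("year_range", (2000, 2004)))
        return cls(
            categories=dict(data.get("categories", {})),
            synonyms_per_cluster=int(data.get("synonyms_per_cluster", 2)),
            n_documents=int(data.get("n_documents", 20)),
            year_range=(int(year_range[0]), int(year_range[1])),
            planted_known=known,
            planted_closures=closures,
            filler_vocabulary_size=int(
                data.get("filler_vocabulary_size", 40)
            ),
            seed=int(data.get("seed", 0)),
        )


def _build_lexicon(config: SimulationConfig) -> Lexicon:
    clusters = []
    for cat in sorted(config.categories):
        for i in range(1, config.categories[cat] + 1):
            rep = f"{cat}{i:02d}"
            synonyms = {rep} | {
                f"{rep} syn{j}"
                for j in range(1, config.synonyms_per_cluster)
            }
            clusters.append(
                EntityCluster(
                    representative=rep,
                    category=cat,
                    synonyms=frozenset(synonyms),
                )
            )
    return Lexicon(clusters)


def _drop(key: tuple[str, ...], pos: int) -> tuple[str, ...]:
    return key[:pos] + key[pos + 1 :]


def _merge(row: str, col: tuple[str, ...], pos: int) -> tuple[str, ...]:
    return col[:pos] + (row,) + col[pos:]


def _closure_fixpoint(
    known: set[tuple[str, ...]], n_dims: int
) -> set[tuple[str, ...]]:
    """Status-only transitive-closure fixpoint over one subnetwork.

    Independent of iteration staging: synchronous and asynchronous
    application reach the same final set because the rule is monotone.
    """
    state = set(known)
    while True:
        additions: set[tuple[str, ...]] = set()
        for pos in range(n_dims):
            columns_of: dict[str, set[tuple[str, ...]]] = {}
            for key in state:
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
                        if target in state:
                            continue
                        if common - {w}:
                            additions.add(target)
        if not additions:
            return state
        state |= additions


def _validate_tuple(
    lexicon: Lexicon, entities: Sequence[str]
) -> tuple[str, ...]:
    cats = []
    for rep in entities:
        if rep not in lexicon:
            raise ValueError(f"planted entity {rep!r} is not in the lexicon")
        cats.append(lexicon.category_of(rep))
    if len(set(cats)) != len(cats):
        raise ValueError(
            f"planted tuple {tuple(entities)!r} repeats a category"
        )
    order = sorted(range(len(entities)), key=lambda i: cats[i])
    return tuple(entities[i] for i in order)


def generate(
    config: SimulationConfig,
) -> tuple[Lexicon, list[Document], ExpectedSet, ExpectedSet]:
    """Generate (lexicon, documents, expected known, expected inferable).

    The expected sets are flat sets of (subnetwork categories, entity
    tuple) pairs, both in canonical category order: every planted
    co-occurrence projected onto each subnetwork it covers, and the
    closure-fixpoint consequences of those knowns. Generation is a pure
    function of the config (including its seed).
    """
    lexicon = _build_lexicon(config)
    rng = random.Random(config.seed)

    plan: list[tuple[tuple[str, ...], int | None]] = []
    for planted in config.planted_known:
        key = _validate_tuple(lexicon, planted.entities)
        if planted.documents < 1:
            raise ValueError(f"planted tuple {key!r} requests 0 documents")
        plan.extend([(key, None)] * planted.documents)
    confirm_plan: list[tuple[tuple[str, ...], int]] = []
    for closure in config.planted_closures:
        for pair in ((closure.x, closure.y), (closure.x, closure.w),
                     (closure.z, closure.y)):
            key = _validate_tuple(lexicon, pair)
            plan.extend([(key, None)] * closure.docs_per_edge)
        if lexicon.category_of(closure.x) != lexicon.category_of(closure.z):
            raise ValueError("closure entities x and z must share a category")
        if lexicon.category_of(closure.y) != lexicon.category_of(closure.w):
            raise ValueError("closure entities y and w must share a category")
        if closure.confirm_year is not None:
            if closure.confirm_year <= config.year_range[1]:
                raise ValueError(
                    "confirm_year must fall after the corpus year range"
                )
            confirm_plan.append(
                (_validate_tuple(lexicon, (closure.z, closure.w)),
                 closure.confirm_year)
            )

    n_planted = len(plan) + len(confirm_plan)
    if n_planted > config.n_documents:
        raise ValueError(
            f"planted structure needs {n_planted} documents but only "
            f"{config.n_documents} requested"
        )

    filler = [f"xfiller{i:03d}" for i in range(config.filler_vocabulary_size)]
    all_names = {
        name.casefold() for cl in lexicon.clusters for name in cl.synonyms
    }
    assert not all_names & set(filler), "filler vocabulary must be disjoint"

    full_plan: list[tuple[tuple[str, ...], int | None]] = list(plan)
    full_plan.extend((key, year) for key, year in confirm_plan)
    full_plan.extend([((), None)] * (config.n_documents - n_planted))
    rng.shuffle(full_plan)

    docs: list[Document] = []
    for i, (entities, year) in enumerate(full_plan):
        units: list[str] = []
        for rep in entities:
            synonyms = sorted(lexicon.cluster(rep).synonyms)
            for _ in range(rng.randint(1, 3)):
                units.append(rng.choice(synonyms))
        for _ in range(rng.randint(5, 15)):
            units.append(rng.choice(filler))
        rng.shuffle(units)
        if year is None:
            year = rng.randint(*config.year_range)
        date = datetime.date(year, rng.randint(1, 12), rng.randint(1, 28))
        docs.append(
            Document(id=f"DOC{i:05d}", date=date, text=" ".join(units))
        )

    # Ground truth: planted tuples projected onto every subnetwork they
    # cover, then closed under the transitive rule per subnetwork.
    planted_tuples = {key for key, _ in full_plan if key}
    by_category = {
        key: {lexicon.category_of(rep): rep for rep in key}
        for key in planted_tuples
    }
    expected_known: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    from .network import enumerate_subnetworks  # local import: no cycle

    specs = enumerate_subnetworks(lexicon.categories)
    for spec in specs:
        for key, cat_map in by_category.items():
            if all(cat in cat_map for cat in spec.categories):
                expected_known.add(
                    (
                        spec.categories,
                        tuple(cat_map[cat] for cat in spec.categories),
                    )
                )
    expected_new: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for spec in specs:
        known_here = {
            ents for cats, ents in expected_known if cats == spec.categories
        }
        closed = _closure_fixpoint(known_here, len(spec.categories))
        expected_new.update(
            (spec.categories, ents) for ents in closed - known_here
        )
    return lexicon, docs, frozenset(expected_known), frozenset(expected_new)


def published_scale_config(seed: int = 0) -> SimulationConfig:
    """A config whose lexicon matches the published network shape.

    Four categories with 22/22/20/23 clusters (87 entity clusters in
    total), which yields 11 subnetworks and 266,528 possible
    interactions. The corpus itself stays small: a handful of planted
    structures so the full pipeline can run end to end.
    """
    return SimulationConfig(
        categories={"disease": 22, "drug": 22, "gene": 20, "target": 23},
        synonyms_per_cluster=2,
        n_documents=40,
        year_range=(2000, 2004),
        planted_known=[
            PlantedKnown(entities=("disease01", "drug01"), documents=2),
            PlantedKnown(entities=("gene02", "target03"), documents=1),
            PlantedKnown(
                entities=("disease02", "drug02", "gene01"), documents=1
            ),
        ],
        planted_closures=[
            PlantedClosure(
                x="drug05", z="drug06", y="target05", w="target06"
            ),
            PlantedClosure(
                x="gene10", z="gene11", y="disease10", w="disease11"
            ),
        ],
        filler_vocabulary_size=60,
        seed=seed,
    )


def demo_config(seed: int = 0) -> SimulationConfig:
    """A small two-category corpus with one planted closure pattern."""
    return SimulationConfig(
        categories={"disease": 4, "drug": 4},
        synonyms_per_cluster=2,
        n_documents=15,
        year_range=(2001, 2003),
        planted_known=[
            PlantedKnown(entities=("disease03", "drug03"), documents=2),
        ],
        planted_closures=[
            PlantedClosure(
                x="drug01", z="drug02", y="disease01", w="disease02"
            ),
        ],
        filler_vocabulary_size=30,
        seed=seed,
    )


def temporal_demo_config(seed: int = 0) -> SimulationConfig:
    """Two-year corpus with a withheld-then-published co-occurrence."""
    return SimulationConfig(
        categories={"disease": 3, "drug": 3},
        synonyms_per_cluster=2,
        n_documents=12,
        year_range=(2002, 2003),
        planted_closures=[
            PlantedClosure(
                x="drug01",
                z="drug02",
                y="disease01",
                w="disease02",
                confirm_year=2004,
            ),
        ],
        filler_vocabulary_size=25,
        seed=seed,
    )


def write_lexicon_json(lexicon: Lexicon, handle: IO[str]) -> None:
    payload = [
        {
            "representative": cl.representative,
            "category": cl.category,
            "synonyms": sorted(cl.synonyms),
        }
        for cl in lexicon.clusters
    ]
    json.dump(payload, handle, indent=2, ensure_ascii=False)
    handle.write("\n")


def write_corpus_jsonl(docs: Iterable[Document], handle: IO[str]) -> None:
    for doc in docs:
        handle.write(
            json.dumps(
                {
                    "id": doc.id,
                    "date": doc.date.isoformat(),
                    "text": doc.text,
                },
                ensure_ascii=False,
            )
            + "\n"
        )
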