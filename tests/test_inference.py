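"""Transitive-closure inference: triples, iteration, penalty, ranking."""

import random

import pytest

from lbdnet.errors import HistoryError
from lbdnet.inference import (
    ClosureTriple,
    find_closure_triples,
    infer_iteration,
    rank_interactions,
    run_inference,
    select_best_triple,
    trace_history,
    trace_to_dict,
)
from lbdnet.network import KNOWN, NEW, Network, Subnetwork
from oracles import make_axes, naive_closure_fixpoint, random_known_levels

TOL = 1e-9


def make_sub(sizes, known_levels, categories=None):
    axes = make_axes(sizes)
    if categories is None:
        categories = [f"cat{i}" for i in range(len(sizes))]
    return Subnetwork.from_known(
        categories,
        dict(zip(sorted(categories), axes)),
        known_levels,
    )


def assert_matches_oracle(sub, axes):
    oracle = naive_closure_fixpoint(
        axes,
        {
            k: c.level
            for k, c in sub.cells.items()
            if c.status == KNOWN and c.iteration == 0
        },
    )
    for key in sub.possible_cells():
        status, iteration, level = oracle[key]
        assert sub.status(key) == status, key
        cell = sub.cells.get(key)
        if cell is not None:
            assert cell.iteration == iteration, key
            assert cell.level == level, key  # bit-identical arithmetic


class TestFindClosureTriples:
    def test_two_by_two_single_triple(self):
        sub = make_sub(
            (2, 2),
            {("a1", "b1"): 0.6, ("a1", "b2"): 0.9, ("a2", "b1"): 0.3},
        )
        triples = find_closure_triples(sub, ("a2", "b2"))
        assert len(triples) == 1
        assert set(triples[0].cells) == {
            ("a1", "b1"), ("a1", "b2"), ("a2", "b1")
        }
        assert triples[0].candidate_level == pytest.approx(0.6, abs=TOL)

    def test_two_known_cells_cannot_close(self):
        sub = make_sub((2, 2), {("a1", "b1"): 0.6, ("a1", "b2"): 0.9})
        assert find_closure_triples(sub, ("a2", "b2")) == []

    def test_random_matrices_match_exhaustive_quadruple_enumeration(self):
        rng = random.Random(7)
        for _ in range(30):
            axes = make_axes((rng.randint(2, 5), rng.randint(2, 5)))
            known = random_known_levels(axes, 0.5, rng)
            sub = make_sub(tuple(len(a) for a in axes), known)
            for target in sub.possible_cells():
                if target in sub.cells:
                    continue
                got = {
                    tuple(sorted(t.cells)) for t in
                    find_closure_triples(sub, target)
                }
                # oracle: enumerate all (x, y) quadruple combinations
                expected = set()
                rows, cols = axes
                z, w = target
                for x in rows:
                    for y in cols:
                        if x == z or y == w:
                            continue
                        support = ((x, y), (x, w), (z, y))
                        if all(c in known for c in support):
                            expected.add(tuple(sorted(support)))
                assert got == expected


class TestSelectBestTriple:
    def make_triple(self, cells, levels):
        ordered = tuple(sorted(cells))
        by_cell = dict(zip(cells, levels))
        mean = (
            by_cell[ordered[0]] + by_cell[ordered[1]] + by_cell[ordered[2]]
        ) / 3.0
        return ClosureTriple(
            pivot="cat0", cells=cells, levels=levels, candidate_level=mean
        )

    def test_highest_average_wins(self):
        low = self.make_triple(
            (("a1", "b1"), ("a1", "b2"), ("a2", "b1")),
            (0.8761, 0.8761, 0.8761),
        )
        high = self.make_triple(
            (("a1", "b1"), ("a1", "b3"), ("a2", "b1")),
            (0.9757, 0.9757, 0.9757),
        )
        assert select_best_triple([low, high]) is high

    def test_single_candidate_is_identity(self):
        only = self.make_triple(
            (("a1", "b1"), ("a1", "b2"), ("a2", "b1")), (0.5, 0.5, 0.5)
        )
        assert select_best_triple([only]) is only

    def test_tie_breaks_lexicographically_on_support(self):
        first = self.make_triple(
            (("a1", "b1"), ("a1", "b2"), ("a2", "b1")), (0.5, 0.5, 0.5)
        )
        second = self.make_triple(
            (("a1", "b1"), ("a1", "b3"), ("a2", "b1")), (0.5, 0.5, 0.5)
        )
        assert select_best_triple([second, first]) is first

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_best_triple([])


class TestInferIteration:
    def test_hand_mean_on_two_by_two(self):
        sub = make_sub(
            (2, 2),
            {("a1", "b1"): 0.6, ("a1", "b2"): 0.9, ("a2", "b1"): 0.3},
        )
        added = infer_iteration(sub, 1)
        assert added == {("a2", "b2")}
        cell = sub.cells[("a2", "b2")]
        assert cell.status == NEW
        assert cell.iteration == 1
        assert cell.level == pytest.approx((0.6 + 0.9 + 0.3) / 3, abs=TOL)

    def test_penalty_divides_by_iteration_number(self):
        sub = make_sub(
            (2, 2),
            {("a1", "b1"): 0.9, ("a1", "b2"): 0.9, ("a2", "b1"): 0.9},
        )
        # simulate the same candidate first reachable only at iteration 3
        added = infer_iteration(sub, 3)
        assert added == {("a2", "b2")}
        assert sub.cells[("a2", "b2")].level == pytest.approx(0.3, abs=TOL)

    def test_full_matrix_adds_nothing(self):
        sub = make_sub(
            (2, 2),
            {
                ("a1", "b1"): 0.5, ("a1", "b2"): 0.5,
                ("a2", "b1"): 0.5, ("a2", "b2"): 0.5,
            },
        )
        assert infer_iteration(sub, 1) == set()


class TestRunInference:
    def test_fully_known_matrix_unchanged(self):
        levels = {
            ("a1", "b1"): 0.5, ("a1", "b2"): 0.6,
            ("a2", "b1"): 0.7, ("a2", "b2"): 0.8,
        }
        sub = make_sub((2, 2), dict(levels))
        run_inference(sub)
        assert {k: c.level for k, c in sub.cells.items()} == levels
        assert all(c.status == KNOWN for c in sub.cells.values())

    def test_planted_chain_needs_two_iterations_with_halved_mean(self):
        # knowns leave (a3, b2) reachable only via cells inferred at k=1
        known = {
            ("a1", "b1"): 0.9,
            ("a1", "b2"): 0.8,
            ("a2", "b1"): 0.7,
            ("a2", "b3"): 0.6,
            ("a3", "b3"): 0.5,
        }
        sub = make_sub((3, 3), dict(known))
        run_inference(sub)
        lvl_a2b2 = (0.9 + 0.8 + 0.7) / 3.0
        lvl_a1b3 = (0.7 + 0.6 + 0.9) / 3.0
        lvl_a3b1 = (0.6 + 0.7 + 0.5) / 3.0
        for key, (it, lvl) in {
            ("a2", "b2"): (1, lvl_a2b2),
            ("a1", "b3"): (1, lvl_a1b3),
            ("a3", "b1"): (1, lvl_a3b1),
        }.items():
            assert sub.cells[key].iteration == it
            assert sub.cells[key].level == pytest.approx(lvl, abs=TOL)
        # at k=2 the best triple for (a3, b2) is (a1,b1),(a1,b2),(a3,b1)
        late = sub.cells[("a3", "b2")]
        assert late.iteration == 2
        assert late.level == pytest.approx(
            (0.9 + 0.8 + lvl_a3b1) / 3.0 / 2.0, abs=TOL
        )

    def test_random_2d_matrices_match_naive_fixpoint_oracle(self):
        rng = random.Random(11)
        for _ in range(40):
            axes = make_axes((rng.randint(2, 6), rng.randint(2, 6)))
            known = random_known_levels(axes, rng.uniform(0.2, 0.7), rng)
            sub = make_sub(tuple(len(a) for a in axes), known)
            run_inference(sub)
            assert_matches_oracle(sub, axes)

    def test_random_3d_matrices_match_naive_fixpoint_oracle(self):
        rng = random.Random(13)
        for _ in range(10):
            axes = make_axes(
                (rng.randint(2, 4), rng.randint(2, 4), rng.randint(2, 4))
            )
            known = random_known_levels(axes, rng.uniform(0.2, 0.5), rng)
            sub = make_sub(tuple(len(a) for a in axes), known)
            run_inference(sub)
            assert_matches_oracle(sub, axes)

    def test_fixpoint_leaves_no_inferable_absent_cell(self):
        rng = random.Random(17)
        axes = make_axes((4, 4))
        known = random_known_levels(axes, 0.3, rng)
        sub = make_sub((4, 4), known)
        run_inference(sub)
        for key in sub.possible_cells():
            if key not in sub.cells:
                assert find_closure_triples(sub, key) == []

    def test_known_cells_never_overwritten(self):
        known = {("a1", "b1"): 0.6, ("a1", "b2"): 0.9, ("a2", "b1"): 0.3}
        sub = make_sub((2, 2), dict(known))
        run_inference(sub)
        for key, level in known.items():
            assert sub.cells[key].status == KNOWN
            assert sub.cells[key].level == level


class TestRanking:
    def build_net(self):
        sub = make_sub(
            (2, 2),
            {("a1", "b1"): 0.9, ("a1", "b2"): 0.5, ("a2", "b1"): 0.7},
        )
        run_inference(sub)
        return Network(subnetworks=[sub])

    def test_top_k_selects_highest_levels(self):
        net = self.build_net()
        rows = rank_interactions(net, status="all", top_k=2)
        assert [r.entities for r in rows] == [("a1", "b1"), ("a2", "b1")]

    def test_status_filter_and_empty_result(self):
        net = self.build_net()
        assert rank_interactions(net, status="new")[0].entities == ("a2", "b2")
        assert (
            rank_interactions(net, subnetworks=[("cat0", "cat1")], status="new")
            == rank_interactions(net, status="new")
        )

    def test_order_matches_independent_sort(self):
        rng = random.Random(23)
        axes = make_axes((5, 5))
        known = random_known_levels(axes, 0.5, rng)
        sub = make_sub((5, 5), known)
        run_inference(sub)
        net = Network(subnetworks=[sub])
        rows = rank_interactions(net, status="all")
        expected = sorted(
            ((c.level, k) for k, c in sub.cells.items()),
            key=lambda t: (-t[0], t[1]),
        )
        assert [(r.level, r.entities) for r in rows] == expected


class TestTraceHistory:
    def test_trace_lists_all_candidates_and_marks_the_max(self):
        # two distinct triples support (a3, b2); the higher mean wins
        sub = make_sub(
            (3, 2),
            {
                ("a1", "b1"): 0.9, ("a1", "b2"): 0.9,
                ("a2", "b1"): 0.9, ("a2", "b2"): 0.3,
                ("a3", "b1"): 0.6,
            },
        )
        run_inference(sub)
        trace = trace_history(sub, ("a3", "b2"))
        assert len(trace.entries) == 2
        accepted = [e for e in trace.entries if e.accepted]
        assert len(accepted) == 1
        assert accepted[0].candidate_level == max(
            e.candidate_level for e in trace.entries
        )
        assert trace.final_level == sub.cells[("a3", "b2")].level
        assert trace.final_iteration == sub.cells[("a3", "b2")].iteration

    def test_single_candidate_trace(self):
        sub = make_sub(
            (2, 2),
            {("a1", "b1"): 0.6, ("a1", "b2"): 0.9, ("a2", "b1"): 0.3},
        )
        run_inference(sub)
        trace = trace_history(sub, ("a2", "b2"))
        assert len(trace.entries) == 1
        assert trace.entries[0].accepted

    def test_known_or_absent_cells_have_no_history(self):
        sub = make_sub((2, 2), {("a1", "b1"): 0.6})
        run_inference(sub)
        with pytest.raises(HistoryError):
            trace_history(sub, ("a1", "b1"))
        with pytest.raises(HistoryError):
            trace_history(sub, ("a2", "b2"))

    def test_trace_json_round_trip_structure(self):
        sub = make_sub(
            (2, 2),
            {("a1", "b1"): 0.6, ("a1", "b2"): 0.9, ("a2", "b1"): 0.3},
        )
        run_inference(sub)
        payload = trace_to_dict(trace_history(sub, ("a2", "b2")))
        assert payload["target"] == ["a2", "b2"]
        assert payload["final_iteration"] == 1
        (block,) = payload["iterations"]
        assert block["k"] == 1
        assert block["triples"][0]["accepted"] is True
        assert block["triples"][0]["average"] == pytest.approx(
            0.6, abs=TOL
        )
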