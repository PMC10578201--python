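"""Move/remove separation heuristic: schedule, hand traces, and guarantees."""

from __future__ import annotations

import random

import pytest

import homopart as hp
from homopart.partition import PartitionAssignment
from homopart.separation import SeparationConfig

from oracles import minimum_separating_removal


def manual_assignment(sim, mapping, k):
    labels = sim.labels()
    return PartitionAssignment(mapping=dict(mapping), k=k, labels=labels)


def cross_edges(sim, assignment):
    return [
        (u, v)
        for u, v, _ in sim.edges()
        if assignment.mapping[u] is not None
        and assignment.mapping[v] is not None
        and assignment.mapping[u] != assignment.mapping[v]
    ]


class TestRemovalQuota:
    @pytest.mark.parametrize(
        "c, i, expected",
        [
            (50, 1, 1),      # raw value 50*(-2)+1 = -99, clamped to 1
            (50, 100, 1),    # log term zero
            (50, 1000, 51),  # log term one
            (1, 1, 1),
            (1000, 10, 1),
            (10, 1000, 11),
        ],
    )
    def test_schedule_values(self, c, i, expected):
        assert hp.removal_quota(c, i) == expected

    def test_full_grid_matches_formula(self):
        import math

        for c in (1, 10, 50, 1000):
            for i in (1, 10, 100, 1000):
                raw = math.floor(c * math.log10(i / 100)) + 1
                assert hp.removal_quota(c, i) == max(1, raw)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hp.removal_quota(0, 1)
        with pytest.raises(ValueError):
            hp.removal_quota(5, 0)


class TestSeparate:
    def test_already_separated_is_identity(self, two_cliques_graph):
        a = manual_assignment(
            two_cliques_graph,
            {"a": 0, "b": 0, "c": 0, "d": 1, "e": 1, "f": 1},
            2,
        )
        final, trace = hp.separate(two_cliques_graph, a)
        assert final.mapping == a.mapping
        assert trace.records == []

    def test_bridge_resolved_by_moving(self):
        """v's single cross edge outweighs its zero within edges: v moves to
        partition 0 and nothing is removed."""
        # z keeps partition 1 non-empty so success is not fold loss
        sim = hp.generate_edge_fixture(
            ["u", "w", "v", "z"], [("u", "w", 0.9), ("u", "v", 0.8)], 0.5
        )
        a = manual_assignment(sim, {"u": 0, "w": 0, "v": 1, "z": 1}, 2)
        final, trace = hp.separate(sim, a)
        assert final.mapping["v"] == 0
        assert final.retention_fraction() == 1.0
        assert trace.total_removed() == 0

    def test_moving_prevents_removal(self):
        # x in P0 with one within edge and one edge to y in P1; y has only
        # the cross edge, so y moves to P0 and retention stays 100%
        sim = hp.generate_edge_fixture(
            ["x", "x2", "y", "z"], [("x", "x2", 0.9), ("x", "y", 0.8)], 0.5
        )
        a = manual_assignment(sim, {"x": 0, "x2": 0, "y": 1, "z": 1}, 2)
        final, trace = hp.separate(sim, a)
        assert final.mapping["y"] == 0
        assert final.retention_fraction() == 1.0

    def test_no_moving_removes_exactly_one(self):
        sim = hp.generate_edge_fixture(
            ["x", "x2", "y", "z"], [("x", "x2", 0.9), ("x", "y", 0.8)], 0.5
        )
        a = manual_assignment(sim, {"x": 0, "x2": 0, "y": 1, "z": 1}, 2)
        final, trace = hp.separate(sim, a, SeparationConfig(allow_moves=False))
        assert trace.total_removed() == 1
        assert final.mapping["x"] is None  # x has 1 cross + ranked first
        assert cross_edges(sim, final) == []

    def test_success_leaves_zero_cross_edges(self):
        rng = random.Random(3)
        for _ in range(25):
            n = rng.randint(4, 18)
            ids = [f"n{i}" for i in range(n)]
            edges = [
                (ids[i], ids[j], round(rng.uniform(0.6, 0.95), 4))
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.25
            ]
            sim = hp.generate_edge_fixture(ids, edges, 0.5)
            a = manual_assignment(sim, {x: i % 2 for i, x in enumerate(ids)}, 2)
            try:
                final, trace = hp.separate(sim, a)
            except hp.FoldLossError:
                continue
            assert cross_edges(sim, final) == []
            # trace invariant: c positive on all but the closing record
            if trace.records:
                assert all(r.c > 0 for r in trace.records[:-1])
                assert trace.records[-1].c == 0

    def test_determinism(self):
        rng = random.Random(8)
        ids = [f"n{i}" for i in range(12)]
        edges = [
            (ids[i], ids[j], round(rng.uniform(0.6, 0.95), 4))
            for i in range(12)
            for j in range(i + 1, 12)
            if rng.random() < 0.4
        ]
        sim1 = hp.generate_edge_fixture(ids, edges, 0.5)
        sim2 = hp.generate_edge_fixture(ids, list(edges), 0.5)
        mapping = {x: i % 3 for i, x in enumerate(ids)}
        cfg = SeparationConfig(allow_fold_loss=True)
        r1 = hp.separate(sim1, manual_assignment(sim1, mapping, 3), cfg)
        r2 = hp.separate(sim2, manual_assignment(sim2, mapping, 3), cfg)
        assert r1[0].mapping == r2[0].mapping
        assert r1[1].records == r2[1].records

    def test_quota_never_below_exhaustive_minimum(self):
        """With moving off, the heuristic cannot remove fewer sequences than
        the exhaustive minimal removal that separates the partitions."""
        rng = random.Random(21)
        for _ in range(30):
            n = rng.randint(4, 9)
            ids = [f"n{i}" for i in range(n)]
            edges = [
                (ids[i], ids[j], 0.9)
                for i in range(n)
                for j in range(i + 1, n)
                if rng.random() < 0.35
            ]
            sim = hp.generate_edge_fixture(ids, edges, 0.5)
            mapping = {x: i % 2 for i, x in enumerate(ids)}
            a = manual_assignment(sim, mapping, 2)
            cfg = SeparationConfig(allow_moves=False, allow_fold_loss=True)
            final, trace = hp.separate(sim, a, cfg)
            minimum = minimum_separating_removal(
                ids, [(u, v) for u, v, _ in sim.edges()], mapping
            )
            assert trace.total_removed() >= minimum
            assert cross_edges(sim, final) == []

    def test_fold_loss_detected(self):
        # complete bipartite violation, both sides singletons: separation
        # must empty one side of a 2-fold split
        sim = hp.generate_edge_fixture(["a", "b"], [("a", "b", 0.99)], 0.5)
        a = manual_assignment(sim, {"a": 0, "b": 1}, 2)
        with pytest.raises(hp.FoldLossError):
            hp.separate(sim, a, SeparationConfig(allow_moves=False))

    def test_fold_loss_downgraded_to_warning(self):
        sim = hp.generate_edge_fixture(["a", "b"], [("a", "b", 0.99)], 0.5)
        a = manual_assignment(sim, {"a": 0, "b": 1}, 2)
        cfg = SeparationConfig(allow_moves=False, allow_fold_loss=True)
        with pytest.warns(UserWarning, match="emptied"):
            final, _ = hp.separate(sim, a, cfg)
        assert final.retention_fraction() == 0.5

    def test_non_convergence_guard(self):
        # max_iterations=1 with several removals required trips the guard
        ids = [f"n{i}" for i in range(8)]
        edges = [(a, b, 0.9) for i, a in enumerate(ids) for b in ids[i + 1:]]
        sim = hp.generate_edge_fixture(ids, edges, 0.5)
        a = manual_assignment(sim, {x: i % 2 for i, x in enumerate(ids)}, 2)
        with pytest.raises(hp.ConvergenceError):
            hp.separate(sim, a, SeparationConfig(allow_moves=False, max_iterations=1))


class TestSeparateWithPriority:
    def _bridge(self, low_priority):
        sim = hp.generate_edge_fixture(
            ["a", "b", "p", "q"],
            [("a", "b", 0.9), ("p", "q", 0.9), ("b", "p", 0.8)],
            0.5,
            priorities={x: x not in low_priority for x in "abpq"},
        )
        a = manual_assignment(sim, {"a": 0, "b": 0, "p": 1, "q": 1}, 2)
        return sim, a

    def test_all_high_priority_equals_plain_separate(self):
        sim, a = self._bridge(low_priority=set())
        cfg = SeparationConfig(allow_moves=False)
        plain = hp.separate(sim, a, cfg)
        prio = hp.separate_with_priority(sim, a, cfg)
        assert plain[0].mapping == prio[0].mapping

    def test_low_priority_bridge_removed_first(self):
        sim, a = self._bridge(low_priority={"p"})
        cfg = SeparationConfig(allow_moves=False)
        final, trace = hp.separate_with_priority(sim, a, cfg)
        assert final.mapping["p"] is None
        assert all(final.mapping[x] is not None for x in "abq")

    def test_unrestrained_phase_continues_on_high_priority_conflicts(self):
        # low-priority pool cannot fix the b-p bridge when only 'a' is low
        sim, a = self._bridge(low_priority={"a"})
        cfg = SeparationConfig(allow_moves=False)
        final, trace = hp.separate_with_priority(sim, a, cfg)
        assert cross_edges(sim, final) == []
        # 'a' has no cross edges: the restrained phase removed nothing,
        # phase 2 removed one of the bridge endpoints
        assert final.mapping["a"] == 0
        assert trace.total_removed() == 1
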