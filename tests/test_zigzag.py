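"""Zigzag adjacency inference, greedy chaining and reference ordering."""

from wgdkit.synteny import Anchor, CollinearBlock
from wgdkit.zigzag import (
    AdjacencyEdge,
    ReferenceAnchor,
    canonical_edge,
    chain_superscaffolds,
    infer_adjacencies,
    order_by_reference,
    superscaffold_adjacencies,
)


def block(witness, counterpart, w_ranks, c_ranks, orientation="+", ks=0.05, bid="b"):
    anchors = [
        Anchor(f"{witness}:{r}", f"{counterpart}:{c}", r, c, ks)
        for r, c in zip(w_ranks, c_ranks)
    ]
    return CollinearBlock(
        block_id=bid,
        scaffold_a=witness,
        scaffold_b=counterpart,
        anchors=anchors,
        orientation=orientation,
        median_ks=ks,
        span_a=(min(w_ranks) * 100, max(w_ranks) * 100 + 9),
        span_b=(min(c_ranks) * 100, max(c_ranks) * 100 + 9),
    )


class TestInferAdjacencies:
    def test_two_blocks_one_edge(self):
        """A witness carrying blocks to B (genes 1-10) then C (genes 12-20)
        implies B and C are adjacent."""
        blocks = [
            block("A", "B", range(1, 11), range(10), bid="b1"),
            block("A", "C", range(12, 21), range(9), bid="b2"),
        ]
        edges = infer_adjacencies(blocks)
        assert len(edges) == 1
        e = edges[0]
        assert e.key == canonical_edge("B", "+", "C", "+")
        assert e.evidence == 1
        assert e.witnesses == ["A"]

    def test_single_block_no_edges(self):
        assert infer_adjacencies([block("A", "B", range(5), range(5))]) == []

    def test_two_witnesses_merge_evidence(self):
        blocks = [
            block("A1", "B", range(0, 5), range(5, 10), bid="b1"),
            block("A1", "C", range(6, 11), range(5), bid="b2"),
            block("A2", "B", range(0, 5), range(5, 10), bid="b3"),
            block("A2", "C", range(6, 11), range(5), bid="b4"),
        ]
        edges = infer_adjacencies(blocks)
        assert len(edges) == 1
        assert edges[0].evidence == 2
        assert sorted(edges[0].witnesses) == ["A1", "A2"]

    def test_junction_gap_filter(self):
        blocks = [
            block("A", "B", range(0, 5), range(5), bid="b1"),
            block("A", "C", range(30, 35), range(5), bid="b2"),
        ]
        assert infer_adjacencies(blocks, max_junction_gap=10) == []
        assert len(infer_adjacencies(blocks, max_junction_gap=30)) == 1

    def test_minus_orientation_flips_sign(self):
        blocks = [
            block("A", "B", range(0, 5), range(5, 10), orientation="-", bid="b1"),
            block("A", "C", range(6, 11), range(5), bid="b2"),
        ]
        edges = infer_adjacencies(blocks)
        assert edges[0].key == canonical_edge("B", "-", "C", "+")

    def test_empty_input(self):
        assert infer_adjacencies([]) == []


def edge(x, sx, y, sy, witnesses):
    return AdjacencyEdge(x, sx, y, sy, witnesses=list(witnesses))


class TestChaining:
    def test_linear_chain(self):
        edges = [edge("B", "+", "C", "+", ["w1"]), edge("C", "+", "D", "+", ["w2"])]
        supers = chain_superscaffolds(edges)
        paths = [s.members for s in supers if len(s.members) > 1]
        assert len(paths) == 1
        assert paths[0] in ([("B", "+"), ("C", "+"), ("D", "+")],
                            [("D", "-"), ("C", "-"), ("B", "-")])

    def test_conflict_resolved_by_evidence(self):
        edges = [
            edge("B", "+", "C", "+", ["w1", "w2", "w3"]),
            edge("B", "+", "X", "+", ["w4"]),  # same free end of B, less evidence
        ]
        supers = chain_superscaffolds(edges, all_scaffolds=["B", "C", "X"])
        adj = superscaffold_adjacencies(supers)
        assert canonical_edge("B", "+", "C", "+") in adj
        assert canonical_edge("B", "+", "X", "+") not in adj

    def test_three_cycle_broken_into_path(self):
        edges = [
            edge("B", "+", "C", "+", ["w1"]),
            edge("C", "+", "D", "+", ["w2"]),
            edge("D", "+", "B", "+", ["w3"]),
        ]
        supers = chain_superscaffolds(edges)
        multi = [s for s in supers if len(s.members) > 1]
        assert len(multi) == 1
        assert len(multi[0].members) == 3  # a path of 3, not a cycle

    def test_vertex_disjoint_paths(self):
        edges = [
            edge("A", "+", "B", "+", ["w"] * 3),
            edge("B", "+", "C", "+", ["w"] * 2),
            edge("B", "-", "D", "+", ["w"]),  # other end of B
            edge("C", "+", "A", "+", ["w"]),  # would close a cycle
        ]
        supers = chain_superscaffolds(edges)
        seen = {}
        for s in supers:
            for sid, _sign in s.members:
                seen[sid] = seen.get(sid, 0) + 1
        assert all(v == 1 for v in seen.values())

    def test_singletons_emitted(self):
        supers = chain_superscaffolds([], all_scaffolds=["S1", "S2"])
        assert sorted(s.members[0][0] for s in supers) == ["S1", "S2"]


class TestOrderByReference:
    def _anchors(self, sid, chrom, ranks, start0=0):
        return [
            ReferenceAnchor(sid, f"{sid}:g{i}", chrom, r, gene_start=start0 + i * 100)
            for i, r in enumerate(ranks)
        ]

    def test_rank_ordering_same_group(self):
        anchors = self._anchors("S1", "dc1", [100, 110, 120]) + self._anchors(
            "S2", "dc1", [300, 310, 320]
        )
        supers = order_by_reference(["S1", "S2"], anchors, [])
        assert len(supers) == 1
        assert [m[0] for m in supers[0].members] == ["S1", "S2"]
        assert supers[0].homeolog_group == "A"

    def test_wgd_linked_scaffolds_split_into_homeolog_groups(self):
        anchors = self._anchors("S1", "dc1", [100, 110, 120]) + self._anchors(
            "S2", "dc1", [100, 110, 120]
        )
        linked = [block("S1", "S2", range(3), range(3))]
        supers = order_by_reference(["S1", "S2"], anchors, linked)
        groups = {s.homeolog_group: [m[0] for m in s.members] for s in supers}
        assert set(groups) == {"A", "B"}
        assert groups["A"] == ["S1"] and groups["B"] == ["S2"]

    def test_anchor_tie_unplaced(self):
        anchors = self._anchors("S1", "dc1", [1, 2, 3]) + self._anchors(
            "S1", "dc2", [1, 2, 3]
        )
        supers = order_by_reference(["S1"], anchors, [])
        assert supers == []

    def test_orientation_from_rank_trend(self):
        fwd = self._anchors("S1", "dc1", [10, 20, 30])
        rev = self._anchors("S2", "dc1", [130, 120, 110])
        supers = order_by_reference(["S1", "S2"], fwd + rev, [])
        signs = dict(supers[0].members)
        assert signs["S1"] == "+" and signs["S2"] == "-"

    def test_odd_cycle_resolved_by_dropping_weakest(self):
        anchors = (
            self._anchors("S1", "dc1", [1, 2, 3])
            + self._anchors("S2", "dc1", [4, 5, 6])
            + self._anchors("S3", "dc1", [7, 8])  # fewest anchors
        )
        triangle = [
            block("S1", "S2", range(3), range(3)),
            block("S2", "S3", range(3), range(3)),
            block("S3", "S1", range(3), range(3)),
        ]
        supers = order_by_reference(["S1", "S2", "S3"], anchors, triangle)
        placed = {m[0] for s in supers for m in s.members}
        assert "S3" not in placed
        assert placed == {"S1", "S2"}
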