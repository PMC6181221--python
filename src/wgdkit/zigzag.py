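"""Zigzag scaffold-adjacency inference and superscaffold construction.

After a recent WGD every chromosome exists in two homeologous copies.  When a
single counterpart ("witness") scaffold carries two collinear blocks to two
*different* scaffolds back-to-back, those two scaffolds were adjacent in the
homeologous copy — the zigzag argument.  Edges inferred this way are merged
across witnesses, resolved greedily by evidence into vertex-disjoint signed
paths (superscaffolds), and scaffolds can alternatively be ordered against an
outgroup reference genome with homeologs separated by 2-colouring the
recent-block graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, NamedTuple

from .simgenome import AnnotatedGenome
from .synteny import (
    CollinearBlock,
    GenePosition,
    SyntenyParams,
    classify_blocks,
    find_collinear_blocks,
)

__all__ = [
    "AdjacencyEdge",
    "Superscaffold",
    "ReferenceAnchor",
    "infer_adjacencies",
    "chain_superscaffolds",
    "iterative_zigzag",
    "superscaffold_adjacencies",
    "order_by_reference",
    "canonical_edge",
    "NonBipartiteHomeologGraph",
]


@dataclass
class AdjacencyEdge:
    """Signed adjacency: laying scaffold_x (sign_x applied) then scaffold_y
    (sign_y applied) left-to-right reconstructs a consistent strand."""

    scaffold_x: str
    sign_x: str
    scaffold_y: str
    sign_y: str
    witnesses: list[str] = field(default_factory=list)
    junction_gaps: list[int] = field(default_factory=list)

    @property
    def evidence(self) -> int:
        return len(self.witnesses)

    @property
    def key(self) -> tuple[str, str, str, str]:
        return canonical_edge(self.scaffold_x, self.sign_x, self.scaffold_y, self.sign_y)


def _flip(sign: str) -> str:
    return "-" if sign == "+" else "+"


def canonical_edge(x: str, sx: str, y: str, sy: str) -> tuple[str, str, str, str]:
    """Canonical form of a signed edge, invariant under reversal
    (x,sx,y,sy) == (y,-sy,x,-sx)."""
    if (x, sx, y, sy) <= (y, _flip(sy), x, _flip(sx)):
        return (x, sx, y, sy)
    return (y, _flip(sy), x, _flip(sx))


@dataclass
class Superscaffold:
    id: str
    members: list[tuple[str, str]]  # ordered (scaffold_id, sign)
    source: str  # 'zigzag' or 'reference'
    reference_chromosome: str | None = None
    homeolog_group: str | None = None


@dataclass(frozen=True)
class ReferenceAnchor:
    scaffold_id: str
    gene_id: str
    ref_chromosome: str
    ref_rank: int
    gene_start: int = 0  # position of the gene on its scaffold, for orientation


class _WitnessBlock(NamedTuple):
    counterpart: str
    lo_rank: int  # anchor rank range on the witness
    hi_rank: int
    orientation: str  # orientation of (witness -> counterpart)


def _blocks_by_witness(blocks: Iterable[CollinearBlock]) -> dict[str, list[_WitnessBlock]]:
    by_witness: dict[str, list[_WitnessBlock]] = {}
    for b in blocks:
        ranks_a = [a.rank_a for a in b.anchors]
        ranks_b = [a.rank_b for a in b.anchors]
        by_witness.setdefault(b.scaffold_a, []).append(
            _WitnessBlock(b.scaffold_b, min(ranks_a), max(ranks_a), b.orientation)
        )
        by_witness.setdefault(b.scaffold_b, []).append(
            _WitnessBlock(b.scaffold_a, min(ranks_b), max(ranks_b), b.orientation)
        )
    return by_witness


def infer_adjacencies(
    recent_blocks: Iterable[CollinearBlock],
    max_junction_gap: int = 10,
    max_junction_overlap: int = 1,
) -> list[AdjacencyEdge]:
    """Infer scaffold adjacencies from consecutive blocks on witness scaffolds.

    For each witness, its recent blocks are ordered along the witness by span
    midpoint; each consecutive pair hitting two distinct counterpart scaffolds
    with at most `max_junction_gap` unanchored witness genes between them
    yields one signed edge.  Blocks overlapping by more than
    `max_junction_overlap` genes on the witness are two homeologous copies of
    the same region, not neighbours, and yield no edge.  Duplicate edges are
    merged with witnesses accumulated.
    """
    merged: dict[tuple[str, str, str, str], AdjacencyEdge] = {}
    for witness, wblocks in sorted(_blocks_by_witness(recent_blocks).items()):
        wblocks = sorted(wblocks, key=lambda w: (w.lo_rank + w.hi_rank) / 2.0)
        for prev, nxt in zip(wblocks, wblocks[1:]):
            if prev.counterpart == nxt.counterpart:
                continue
            gap = nxt.lo_rank - prev.hi_rank - 1
            if gap > max_junction_gap or gap < -(max_junction_overlap + 1):
                continue
            gap = max(gap, 0)
            # sign convention: the junction-facing end of the earlier block's
            # counterpart is its high-rank end iff the block orientation is '+'
            edge_key = canonical_edge(
                prev.counterpart, prev.orientation, nxt.counterpart, nxt.orientation
            )
            edge = merged.get(edge_key)
            if edge is None:
                edge = AdjacencyEdge(*edge_key)
                merged[edge_key] = edge
            edge.witnesses.append(witness)
            edge.junction_gaps.append(gap)
    return [merged[k] for k in sorted(merged)]


# ---------------------------------------------------------------------------
# greedy chaining into vertex-disjoint signed paths


def chain_superscaffolds(
    edges: Iterable[AdjacencyEdge],
    scaffold_lengths: dict[str, int] | None = None,
    all_scaffolds: Iterable[str] | None = None,
) -> list[Superscaffold]:
    """Resolve edges greedily into superscaffolds (vertex-disjoint paths).

    Edges are ranked by descending evidence (ties: larger combined scaffold
    length, then lexical ids); an edge is retained only when both scaffold
    ends it uses are still free and it would not close a cycle.  Unplaced
    scaffolds are emitted as singletons when `all_scaffolds` is given.
    """
    lengths = scaffold_lengths or {}

    def _rank(e: AdjacencyEdge):
        combined = lengths.get(e.scaffold_x, 0) + lengths.get(e.scaffold_y, 0)
        return (-e.evidence, -combined, e.key)

    # physical ends: (scaffold, 'H'|'T'); sign '+' means laid head..tail
    def junction_ends(e: AdjacencyEdge):
        end_x = (e.scaffold_x, "T" if e.sign_x == "+" else "H")
        end_y = (e.scaffold_y, "H" if e.sign_y == "+" else "T")
        return end_x, end_y

    used_ends: dict[tuple[str, str], tuple[str, str]] = {}
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    retained: list[AdjacencyEdge] = []
    for e in sorted(edges, key=_rank):
        ex, ey = junction_ends(e)
        if ex in used_ends or ey in used_ends:
            continue
        rx, ry = find(e.scaffold_x), find(e.scaffold_y)
        if rx == ry:
            continue  # would close a cycle
        parent[rx] = ry
        used_ends[ex] = ey
        used_ends[ey] = ex
        retained.append(e)

    # walk the paths
    degree: dict[str, int] = {}
    for e in retained:
        degree[e.scaffold_x] = degree.get(e.scaffold_x, 0) + 1
        degree[e.scaffold_y] = degree.get(e.scaffold_y, 0) + 1
    visited: set[str] = set()
    supers: list[Superscaffold] = []
    counter = 1

    def other_end(end: tuple[str, str]) -> tuple[str, str]:
        sid, side = end
        return (sid, "H" if side == "T" else "T")

    for start in sorted(degree, key=lambda s: (degree[s], s)):
        if start in visited or degree[start] == 2:
            continue
        # orient the start scaffold so its used end faces right
        used = [side for side in ("H", "T") if (start, side) in used_ends]
        members: list[tuple[str, str]] = []
        cur_sid = start
        cur_right = (start, used[0])
        members.append((start, "+" if used[0] == "T" else "-"))
        visited.add(start)
        while cur_right in used_ends:
            nxt = used_ends[cur_right]
            nxt_sid, nxt_side = nxt
            if nxt_sid in visited:
                break
            members.append((nxt_sid, "+" if nxt_side == "H" else "-"))
            visited.add(nxt_sid)
            cur_right = other_end(nxt)
            cur_sid = nxt_sid
        supers.append(Superscaffold(f"ss{counter:04d}", members, "zigzag"))
        counter += 1
    if all_scaffolds is not None:
        for sid in sorted(set(all_scaffolds) - visited):
            supers.append(Superscaffold(f"ss{counter:04d}", [(sid, "+")], "zigzag"))
            counter += 1
    return supers


# ---------------------------------------------------------------------------
# iterative zigzag extension

_UNIT_GAP = 100  # virtual bp between members of a growing unit


def _unit_positions(
    units: dict[str, list[tuple[str, str]]],
    scaffold_genes: dict[str, list[tuple[str, int, int]]],
    scaffold_len: dict[str, int],
) -> dict[str, GenePosition]:
    """Gene positions on virtual coordinate systems defined by signed units."""
    pos: dict[str, GenePosition] = {}
    for uid, members in units.items():
        offset = 0
        rank = 0
        for sid, sign in members:
            genes = scaffold_genes[sid]
            if sign == "-":
                L = scaffold_len[sid]
                genes = [(g, L - e, L - s) for g, s, e in reversed(genes)]
            for g, s, e in genes:
                pos[g] = GenePosition(uid, rank, offset + s, offset + e)
                rank += 1
            offset += scaffold_len[sid] + _UNIT_GAP
    return pos


def iterative_zigzag(
    genome: AnnotatedGenome,
    pairs: Iterable[tuple[str, str, float]],
    params: SyntenyParams | None = None,
    max_junction_gap: int = 10,
    max_rounds: int = 8,
) -> list[Superscaffold]:
    """Alternating zigzag extension of scaffolds via their WGD counterparts.

    One zigzag pass can only join scaffolds whose junction is spanned by a
    counterpart scaffold.  Extension iterates the pass: after each round the
    retained adjacencies merge scaffolds into longer units, the longer units
    witness junctions that single scaffolds could not span, and the next
    round recovers further adjacencies — alternating between the two
    homeologous copies until a fixpoint (or `max_rounds`).  Members of the
    returned superscaffolds are the original scaffolds with signs.
    """
    params = params or SyntenyParams()
    pairs = list(pairs)
    scaffold_genes = {
        sid: [(g.gene_id, g.start, g.end) for g in genes]
        for sid, genes in genome.genes_by_scaffold().items()
    }
    scaffold_len = {sid: len(seq) for sid, seq in genome.scaffolds}
    units: dict[str, list[tuple[str, str]]] = {
        sid: [(sid, "+")] for sid in scaffold_len
    }
    for _ in range(max_rounds):
        pos = _unit_positions(units, scaffold_genes, scaffold_len)
        blocks = find_collinear_blocks(pos, pairs, params)
        recent = classify_blocks(blocks, params).recent
        edges = infer_adjacencies(recent, max_junction_gap=max_junction_gap)
        unit_len = {
            uid: sum(scaffold_len[s] for s, _ in mem) for uid, mem in units.items()
        }
        chains = chain_superscaffolds(edges, unit_len, units.keys())
        if all(len(c.members) == 1 for c in chains):
            break
        new_units: dict[str, list[tuple[str, str]]] = {}
        for i, chain in enumerate(chains, start=1):
            merged: list[tuple[str, str]] = []
            for uid, usign in chain.members:
                mem = units[uid]
                if usign == "-":
                    mem = [(s, _flip(sg)) for s, sg in reversed(mem)]
                merged.extend(mem)
            new_units[f"zz{i:04d}" if len(chain.members) > 1 else merged[0][0]] = merged
        units = new_units
    out = []
    for i, (uid, members) in enumerate(sorted(units.items()), start=1):
        out.append(Superscaffold(f"ss{i:04d}", members, "zigzag"))
    return out


def superscaffold_adjacencies(
    superscaffolds: Iterable[Superscaffold],
) -> set[tuple[str, str, str, str]]:
    """Canonical signed adjacency keys implied by superscaffold member order."""
    keys = set()
    for ss in superscaffolds:
        for (x, sx), (y, sy) in zip(ss.members, ss.members[1:]):
            keys.add(canonical_edge(x, sx, y, sy))
    return keys


# ---------------------------------------------------------------------------
# reference-guided homeolog-separated ordering


class NonBipartiteHomeologGraph(RuntimeError):
    """Raised when homeolog 2-colouring fails after conflict resolution."""

    def __init__(self, odd_cycle: list[str]):
        self.odd_cycle = odd_cycle
        super().__init__(f"homeolog graph is not bipartite; odd cycle: {odd_cycle}")


def _two_colour(nodes: list[str], edges: set[tuple[str, str]]):
    """BFS 2-colouring; returns (colours, odd_cycle or None)."""
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        if u in adj and v in adj:
            adj[u].add(v)
            adj[v].add(u)
    colours: dict[str, int] = {}
    parent: dict[str, str | None] = {}
    for root in sorted(adj):
        if root in colours:
            continue
        colours[root] = 0
        parent[root] = None
        queue = [root]
        while queue:
            u = queue.pop(0)
            for v in sorted(adj[u]):
                if v not in colours:
                    colours[v] = 1 - colours[u]
                    parent[v] = u
                    queue.append(v)
                elif colours[v] == colours[u]:
                    # reconstruct the odd cycle through u and v
                    pu = _path_to_root(u, parent)
                    pv = _path_to_root(v, parent)
                    common = set(pu) & set(pv)
                    cyc = []
                    for x in pu:
                        cyc.append(x)
                        if x in common:
                            break
                    meet = cyc[-1]
                    tail = []
                    for x in pv:
                        if x == meet:
                            break
                        tail.append(x)
                    cyc.extend(reversed(tail))
                    return colours, cyc
    return colours, None


def _path_to_root(node: str, parent: dict[str, str | None]) -> list[str]:
    path = [node]
    while parent[path[-1]] is not None:
        path.append(parent[path[-1]])
    return path


def order_by_reference(
    scaffolds: Iterable[str],
    anchors: Iterable[ReferenceAnchor],
    recent_blocks: Iterable[CollinearBlock],
    max_conflict_drops: int = 10,
) -> list[Superscaffold]:
    """Reference-guided, homeolog-separated superscaffolds.

    Each scaffold goes to the reference chromosome holding the majority of its
    anchors (ties -> unplaced).  Scaffolds on one reference chromosome are
    split into two homeolog groups by 2-colouring the graph whose edges are
    recent-WGD blocks between them; an odd cycle is resolved by dropping its
    lowest-anchor-count scaffold to unplaced (raising
    NonBipartiteHomeologGraph if conflicts persist).  Within each group,
    scaffolds are ordered by median anchor rank and oriented by the sign of
    the rank-vs-position trend.
    """
    scaffolds = sorted(set(scaffolds))
    anchors = list(anchors)
    by_scaffold: dict[str, list[ReferenceAnchor]] = {s: [] for s in scaffolds}
    for a in anchors:
        if a.scaffold_id in by_scaffold:
            by_scaffold[a.scaffold_id].append(a)
    assignment: dict[str, str] = {}
    anchor_count: dict[str, int] = {}
    for sid in scaffolds:
        tallies: dict[str, int] = {}
        for a in by_scaffold[sid]:
            tallies[a.ref_chromosome] = tallies.get(a.ref_chromosome, 0) + 1
        if not tallies:
            continue
        best = max(tallies.values())
        winners = sorted(c for c, n in tallies.items() if n == best)
        if len(winners) > 1:
            continue  # tie -> unplaced
        assignment[sid] = winners[0]
        anchor_count[sid] = best
    block_edges: set[tuple[str, str]] = {
        (b.scaffold_a, b.scaffold_b) for b in recent_blocks if b.scaffold_a != b.scaffold_b
    }
    supers: list[Superscaffold] = []
    counter = 1
    for chrom in sorted(set(assignment.values())):
        members = sorted(s for s, c in assignment.items() if c == chrom)
        for _ in range(max_conflict_drops + 1):
            colours, odd_cycle = _two_colour(members, block_edges)
            if odd_cycle is None:
                break
            drop = min(odd_cycle, key=lambda s: (anchor_count.get(s, 0), s))
            members = [s for s in members if s != drop]
        else:
            raise NonBipartiteHomeologGraph(odd_cycle)
        if odd_cycle is not None:
            raise NonBipartiteHomeologGraph(odd_cycle)
        groups: dict[int, list[str]] = {0: [], 1: []}
        for s in members:
            groups[colours[s]].append(s)
        # deterministic labelling: the group holding the lexically smallest
        # scaffold is 'A'
        if groups[0] and groups[1] and min(groups[1]) < min(groups[0]):
            groups = {0: groups[1], 1: groups[0]}
        for colour, label in ((0, "A"), (1, "B")):
            sids = groups[colour]
            if not sids:
                continue
            ordered = sorted(
                sids, key=lambda s: (median(a.ref_rank for a in by_scaffold[s]), s)
            )
            signed = [(s, _orientation_from_trend(by_scaffold[s])) for s in ordered]
            supers.append(
                Superscaffold(
                    f"ref{counter:04d}",
                    signed,
                    "reference",
                    reference_chromosome=chrom,
                    homeolog_group=label,
                )
            )
            counter += 1
    return supers


def _orientation_from_trend(anchors: list[ReferenceAnchor]) -> str:
    """Sign of the (gene position on scaffold) vs (reference rank) trend."""
    if len(anchors) < 2:
        return "+"
    pts = sorted((a.gene_start, a.ref_rank) for a in anchors)
    n = len(pts)
    mean_x = sum(p[0] for p in pts) / n
    mean_y = sum(p[1] for p in pts) / n
    cov = sum((x - mean_x) * (y - mean_y) for x, y in pts)
    return "+" if cov >= 0 else "-"
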