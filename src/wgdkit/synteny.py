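"""Collinear-block detection: chain homologous anchor pairs into blocks
between scaffolds and classify blocks by median Ks.

Chaining follows the MCScanX idiom simplified to anchor-count scoring: per
scaffold pair and orientation, a longest-chain dynamic programme links anchors
whose ranks advance by at most `max_gap` genes on both scaffolds; chains
shorter than `min_anchors` are discarded and every anchor belongs to at most
one block.  Blocks with median anchor Ks below `ks_recent` (strictly) are the
recent-WGD blocks used downstream for zigzag scaffold ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, NamedTuple

from .simgenome import AnnotatedGenome

__all__ = [
    "SyntenyParams",
    "Anchor",
    "CollinearBlock",
    "GenePosition",
    "gene_positions",
    "BlockClassification",
    "find_collinear_blocks",
    "classify_blocks",
    "block_stats",
]


@dataclass(frozen=True)
class SyntenyParams:
    min_anchors: int = 5
    max_gap: int = 25
    ks_recent: float = 0.2
    strict_gt: bool = False  # read "more than five" literally (> min_anchors)

    def __post_init__(self):
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if self.max_gap < 1:
            raise ValueError("max_gap must be >= 1")
        if self.ks_recent <= 0:
            raise ValueError("ks_recent must be > 0")

    def passes(self, n_anchors: int) -> bool:
        return n_anchors > self.min_anchors if self.strict_gt else n_anchors >= self.min_anchors


class Anchor(NamedTuple):
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int
    ks: float


@dataclass
class CollinearBlock:
    block_id: str
    scaffold_a: str
    scaffold_b: str
    anchors: list[Anchor]
    orientation: str  # '+' or '-'
    median_ks: float
    span_a: tuple[int, int]
    span_b: tuple[int, int]

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


class GenePosition(NamedTuple):
    """Location of a gene: scaffold, gene rank along it, bp interval."""

    scaffold: str
    rank: int
    start: int
    end: int


def gene_positions(genome: AnnotatedGenome) -> dict[str, GenePosition]:
    pos: dict[str, GenePosition] = {}
    for sid, genes in genome.genes_by_scaffold().items():
        for rank, g in enumerate(genes):
            pos[g.gene_id] = GenePosition(sid, rank, g.start, g.end)
    return pos


_GenePos = GenePosition


def _collapse_tandems(
    pairs: list[tuple[str, str, float]], pos: dict[str, _GenePos], max_tandem_gap: int = 1
) -> dict[str, str]:
    """Map each member of a tandem array (consecutive homologs on one
    scaffold) to the array's first member."""
    rep: dict[str, str] = {}
    for ga, gb, _ks in pairs:
        pa, pb = pos[ga], pos[gb]
        if pa.scaffold == pb.scaffold and abs(pa.rank - pb.rank) <= max_tandem_gap:
            first, second = (ga, gb) if pa.rank <= pb.rank else (gb, ga)
            root = rep.get(first, first)
            rep[second] = root
    return rep


def _chain_dp(
    anchors: list[Anchor], orientation: str, max_gap: int
) -> list[int]:
    """Best chain (indices into `anchors`, sorted by rank_a) for one orientation.

    Score = anchor count; ties broken toward the chain with the smaller start
    rank on scaffold_a.  Ranks must advance strictly on both scaffolds
    (increasing on b for '+', decreasing for '-') with rank gaps <= max_gap.
    """
    n = len(anchors)
    best_len = [1] * n
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            da = anchors[i].rank_a - anchors[j].rank_a
            if da <= 0 or da > max_gap:
                continue
            if orientation == "+":
                db = anchors[i].rank_b - anchors[j].rank_b
            else:
                db = anchors[j].rank_b - anchors[i].rank_b
            if db <= 0 or db > max_gap:
                continue
            if best_len[j] + 1 > best_len[i]:
                best_len[i] = best_len[j] + 1
                prev[i] = j
    if not best_len:
        return []
    end = max(range(n), key=lambda i: (best_len[i], -anchors[i].rank_a))
    chain = []
    while end != -1:
        chain.append(end)
        end = prev[end]
    chain.reverse()
    return chain


def find_collinear_blocks(
    genome: AnnotatedGenome | dict[str, GenePosition],
    pairs: Iterable[tuple[str, str, float]],
    params: SyntenyParams | None = None,
) -> list[CollinearBlock]:
    """Chain homolog pairs (gene_a, gene_b, Ks) into collinear blocks.

    `genome` may be an AnnotatedGenome or a precomputed gene->GenePosition
    mapping (used when genes live on virtual coordinate systems such as
    superscaffolds).  Self-pairs are excluded and tandem arrays collapsed to
    their first member before anchoring.  Blocks are extracted greedily per
    scaffold pair: the best chain in either orientation is emitted, its
    anchors removed, and the search repeated until no chain passes the
    anchor-count filter.
    """
    params = params or SyntenyParams()
    pos = genome if isinstance(genome, dict) else gene_positions(genome)
    pairs = list(pairs)
    for ga, gb, _ks in pairs:
        for g in (ga, gb):
            if g not in pos:
                raise ValueError(f"anchor gene {g} has no scaffold position")
    rep = _collapse_tandems(pairs, pos)
    by_pair: dict[tuple[str, str], list[Anchor]] = {}
    seen: set[tuple[str, str]] = set()
    for ga, gb, ks in pairs:
        ga = rep.get(ga, ga)
        gb = rep.get(gb, gb)
        if ga == gb:
            continue
        pa, pb = pos[ga], pos[gb]
        # orient the scaffold pair canonically
        if (pb.scaffold, pb.rank) < (pa.scaffold, pa.rank):
            ga, gb, pa, pb = gb, ga, pb, pa
        key = (ga, gb)
        if key in seen:
            continue
        seen.add(key)
        by_pair.setdefault((pa.scaffold, pb.scaffold), []).append(
            Anchor(ga, gb, pa.rank, pb.rank, ks)
        )
    blocks: list[CollinearBlock] = []
    counter = 1
    for (sa, sb), anchors in sorted(by_pair.items()):
        pool = sorted(anchors, key=lambda a: (a.rank_a, a.rank_b))
        while True:
            candidates = []
            for orient in ("+", "-"):
                idx = _chain_dp(pool, orient, params.max_gap)
                if idx:
                    candidates.append((len(idx), orient, idx))
            if not candidates:
                break
            # longer chain wins; ties favour '+' then smaller start rank
            candidates.sort(
                key=lambda c: (-c[0], c[1] != "+", pool[c[2][0]].rank_a)
            )
            length, orient, idx = candidates[0]
            if not params.passes(length):
                break
            chosen = [pool[i] for i in idx]
            blocks.append(_make_block(f"blk{counter:04d}", sa, sb, chosen, orient, pos))
            counter += 1
            used = set(idx)
            pool = [a for i, a in enumerate(pool) if i not in used]
    return blocks


def _make_block(
    block_id: str,
    sa: str,
    sb: str,
    anchors: list[Anchor],
    orientation: str,
    pos: dict[str, _GenePos],
) -> CollinearBlock:
    finite = [a.ks for a in anchors if a.ks == a.ks and math.isfinite(a.ks)]
    med = median(finite) if finite else float("nan")
    starts_a = [pos[a.gene_a].start for a in anchors]
    ends_a = [pos[a.gene_a].end for a in anchors]
    starts_b = [pos[a.gene_b].start for a in anchors]
    ends_b = [pos[a.gene_b].end for a in anchors]
    return CollinearBlock(
        block_id=block_id,
        scaffold_a=sa,
        scaffold_b=sb,
        anchors=anchors,
        orientation=orientation,
        median_ks=med,
        span_a=(min(starts_a), max(ends_a)),
        span_b=(min(starts_b), max(ends_b)),
    )


@dataclass
class BlockClassification:
    recent: list[CollinearBlock] = field(default_factory=list)
    ancient: list[CollinearBlock] = field(default_factory=list)
    unclassified: list[CollinearBlock] = field(default_factory=list)


def classify_blocks(
    blocks: Iterable[CollinearBlock], params: SyntenyParams | None = None
) -> BlockClassification:
    """Split blocks at the recent-WGD Ks threshold (strict median_ks < ks_recent)."""
    params = params or SyntenyParams()
    out = BlockClassification()
    for b in blocks:
        if b.median_ks != b.median_ks:  # NaN: no finite anchor Ks
            out.unclassified.append(b)
        elif b.median_ks < params.ks_recent:
            out.recent.append(b)
        else:
            out.ancient.append(b)
    return out


def block_stats(blocks: Iterable[CollinearBlock]) -> dict:
    """Summary: block count, distinct scaffolds, total anchor-spanned bp,
    distinct genes covered (each counted once)."""
    blocks = list(blocks)
    scaffolds: set[str] = set()
    genes: set[str] = set()
    intervals: dict[str, list[tuple[int, int]]] = {}
    for b in blocks:
        scaffolds.update((b.scaffold_a, b.scaffold_b))
        intervals.setdefault(b.scaffold_a, []).append(b.span_a)
        intervals.setdefault(b.scaffold_b, []).append(b.span_b)
        for a in b.anchors:
            genes.add(a.gene_a)
            genes.add(a.gene_b)
    total_bp = 0
    for spans in intervals.values():
        spans.sort()
        cur_start, cur_end = spans[0]
        for s, e in spans[1:]:
            if s > cur_end:
                total_bp += cur_end - cur_start
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        total_bp += cur_end - cur_start
    return {
        "block_count": len(blocks),
        "n_scaffolds": len(scaffolds),
        "total_span_bp": total_bp,
        "genes_covered": len(genes),
    }
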