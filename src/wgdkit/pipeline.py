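"""End-to-end conveniences chaining homology -> codon alignment -> NG86.

These glue functions run the standard desk-scale analysis path: translate all
CDSs, find reciprocal homolog pairs, thread codon alignments, and estimate
Ka/Ks per pair — producing the anchor table consumed by the synteny and
zigzag stages and the Ks table consumed by dating.
"""

from __future__ import annotations

import pandas as pd

from .homology import (
    align_protein_pair,
    all_vs_all_hits,
    proteins_from_genome,
    translate_cds,
)
from .kaks import KaKsResult, codon_align, kaks_table, ng86
from .simgenome import AnnotatedGenome

__all__ = ["reciprocal_pairs", "ks_for_pairs", "homolog_ks_table"]


def reciprocal_pairs(genome: AnnotatedGenome, **hit_kwargs) -> list[tuple[str, str]]:
    """Unordered gene pairs with similarity hits in both directions."""
    hits = all_vs_all_hits(proteins_from_genome(genome), **hit_kwargs)
    directed = {(h.query_id, h.subject_id) for h in hits}
    return sorted({tuple(sorted(p)) for p in directed if (p[1], p[0]) in directed})


def ks_for_pairs(
    genome: AnnotatedGenome, pairs: list[tuple[str, str]]
) -> tuple[list[KaKsResult], list[float]]:
    """NG86 for each gene pair via protein alignment + codon threading."""
    cds = {g.gene_id: g.cds for g in genome.genes}
    results: list[KaKsResult] = []
    coverages: list[float] = []
    for a, b in pairs:
        pa = translate_cds(cds[a], a)
        pb = translate_cds(cds[b], b)
        if pa.sequence == pb.sequence:
            rows = (pa.sequence, pb.sequence)
        else:
            rows, _hit = align_protein_pair(pa, pb)
        aln = codon_align(cds[a], cds[b], rows, a, b)
        results.append(ng86(aln))
        coverages.append(aln.coverage(cds[a], cds[b]))
    return results, coverages


def homolog_ks_table(
    genome: AnnotatedGenome, min_coverage: float = 0.5, **hit_kwargs
) -> pd.DataFrame:
    """Reciprocal homolog pairs of a genome with their NG86 estimates."""
    pairs = reciprocal_pairs(genome, **hit_kwargs)
    results, coverages = ks_for_pairs(genome, pairs)
    return kaks_table(results, min_coverage=min_coverage, coverages=coverages)
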