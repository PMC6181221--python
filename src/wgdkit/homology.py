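"""Homolog detection by all-vs-all protein similarity and reciprocal-hit
clustering.

The similarity engine is an exact affine-gap global alignment with free end
gaps under BLOSUM62 — a deterministic desk-scale surrogate for a heuristic
sequence search.  Hits can also be imported from a 12-column tabular search
output produced externally.  Families are connected components of the
reciprocal-hit graph (single linkage).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .simgenome import AnnotatedGenome, GeneModel

__all__ = [
    "ProteinRecord",
    "SimilarityHit",
    "GeneFamily",
    "translate_cds",
    "align_protein_pair",
    "all_vs_all_hits",
    "reciprocal_clusters",
    "proteins_from_genome",
]


@dataclass(frozen=True)
class ProteinRecord:
    gene_id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.gene_id}: empty protein")
        if "*" in self.sequence:
            raise ValueError(f"{self.gene_id}: internal stop symbol")


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    score: float
    identity: float
    query_coverage: float
    subject_coverage: float
    aln_len: int = 0
    mismatches: int = 0
    gap_opens: int = 0


@dataclass(frozen=True)
class GeneFamily:
    family_id: str
    members: frozenset[str]


def translate_cds(gene: GeneModel | str, gene_id: str = "?") -> ProteinRecord:
    """Standard-code translation of a CDS; trailing stop stripped."""
    if isinstance(gene, GeneModel):
        cds, gene_id = gene.cds, gene.gene_id
    else:
        cds = gene
    if len(cds) % 3:
        raise ValueError(f"{gene_id}: CDS length {len(cds)} not a multiple of 3")
    aa = str(Seq(cds).translate())
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(
            f"{gene_id}: internal stop codon at codon index {aa.index('*')}"
        )
    return ProteinRecord(gene_id, aa)


def proteins_from_genome(genome: AnnotatedGenome) -> list[ProteinRecord]:
    return [translate_cds(g) for g in genome.genes]


def _make_aligner(
    matrix: str = "BLOSUM62", gap_open: float = -11.0, gap_extend: float = -1.0
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    # free end gaps on both sequences (attribute names changed across
    # Biopython releases)
    try:
        aligner.end_insertion_score = 0.0
        aligner.end_deletion_score = 0.0
    except AttributeError:
        aligner.target_end_gap_score = 0.0
        aligner.query_end_gap_score = 0.0
    return aligner


def align_protein_pair(
    a: ProteinRecord,
    b: ProteinRecord,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> tuple[tuple[str, str], SimilarityHit]:
    """Optimal global alignment with free end gaps; returns (gapped rows, hit).

    The score is the dynamic-programming optimum under the stated scoring.
    Identity is matches over aligned (non-gap) columns; coverage is aligned
    columns over each sequence's length.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("cannot align an empty sequence")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    aln = aligner.align(a.sequence, b.sequence)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = aligned_cols = gap_opens = 0
    in_gap = False
    for x, y in zip(row_a, row_b):
        if x == "-" or y == "-":
            if not in_gap:
                gap_opens += 1
            in_gap = True
            continue
        in_gap = False
        aligned_cols += 1
        if x == y:
            matches += 1
    identity = matches / aligned_cols if aligned_cols else 0.0
    hit = SimilarityHit(
        query_id=a.gene_id,
        subject_id=b.gene_id,
        score=float(aln.score),
        identity=identity,
        query_coverage=aligned_cols / len(a.sequence),
        subject_coverage=aligned_cols / len(b.sequence),
        aln_len=len(row_a),
        mismatches=aligned_cols - matches,
        gap_opens=gap_opens,
    )
    return (row_a, row_b), hit


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all_hits(
    proteins: Iterable[ProteinRecord],
    min_identity: float = 0.4,
    min_coverage: float = 0.5,
    top_n: int = 5,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 3,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> list[SimilarityHit]:
    """Directional hits for every query, ranked by score (gene_id tiebreak).

    An exact word prefilter (pairs must share >= prefilter_min_shared
    amino-acid prefilter_k-mers) skips hopeless alignments; set
    prefilter_min_shared=0 to align every pair exhaustively.
    """
    prots = sorted(proteins, key=lambda p: p.gene_id)
    if len(prots) < 2:
        raise ValueError("need at least two proteins")
    kmers = {p.gene_id: _kmer_set(p.sequence, prefilter_k) for p in prots}
    per_query: dict[str, list[SimilarityHit]] = {p.gene_id: [] for p in prots}
    for i in range(len(prots)):
        for j in range(i + 1, len(prots)):
            a, b = prots[i], prots[j]
            if (
                prefilter_min_shared
                and len(kmers[a.gene_id] & kmers[b.gene_id]) < prefilter_min_shared
            ):
                continue
            _aln, hit = align_protein_pair(a, b, matrix, gap_open, gap_extend)
            if hit.identity < min_identity:
                continue
            if hit.query_coverage < min_coverage or hit.subject_coverage < min_coverage:
                continue
            per_query[a.gene_id].append(hit)
            per_query[b.gene_id].append(
                SimilarityHit(
                    query_id=b.gene_id,
                    subject_id=a.gene_id,
                    score=hit.score,
                    identity=hit.identity,
                    query_coverage=hit.subject_coverage,
                    subject_coverage=hit.query_coverage,
                    aln_len=hit.aln_len,
                    mismatches=hit.mismatches,
                    gap_opens=hit.gap_opens,
                )
            )
    out: list[SimilarityHit] = []
    for qid in sorted(per_query):
        ranked = sorted(per_query[qid], key=lambda h: (-h.score, h.subject_id))
        out.extend(ranked[:top_n])
    return out


def reciprocal_clusters(
    hits: Iterable[SimilarityHit], all_genes: Iterable[str] | None = None
) -> list[GeneFamily]:
    """Families = connected components of the reciprocal-hit graph.

    An undirected edge joins two genes when hits exist in both directions.
    Genes without any reciprocal partner become singleton families.  The
    result is invariant under input permutation (members and family numbering
    are sorted).
    """
    directed = {(h.query_id, h.subject_id) for h in hits}
    genes = {g for pair in directed for g in pair}
    if all_genes is not None:
        genes |= set(all_genes)
    graph = nx.Graph()
    graph.add_nodes_from(genes)
    for q, s in directed:
        if (s, q) in directed:
            graph.add_edge(q, s)
    components = sorted(
        (sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0]
    )
    return [
        GeneFamily(f"fam{idx:05d}", frozenset(members))
        for idx, members in enumerate(components, start=1)
    ]
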