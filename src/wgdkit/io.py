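"""Readers/writers for the standard interchange formats.

FASTA via Bio.SeqIO; GFF3 with 1-based inclusive coordinates; FASTQ with
constant quality for simulated reads; 12-column tabular hit files compatible
with common sequence-search output; TSV truth/Ks/edge tables via pandas; AGP
v2.1 for superscaffolds.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codon import revcomp
from .homology import SimilarityHit
from .simgenome import AnnotatedGenome, GeneModel, SimulationTruth
from .zigzag import AdjacencyEdge, Superscaffold

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_fastq",
    "read_fastq",
    "write_truth_tables",
    "write_hits_tsv",
    "read_hits_tsv",
    "write_edges_tsv",
    "write_agp",
    "superscaffold_fasta",
]


def write_fasta(scaffolds: Iterable[tuple[str, str]], path) -> None:
    records = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in scaffolds]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_gff3(genome: AnnotatedGenome, path, source: str = "wgdkit") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome.provenance:
            fh.write(f"# provenance: {genome.provenance}\n")
        for sid, seq in genome.scaffolds:
            fh.write(f"##sequence-region {sid} 1 {len(seq)}\n")
        for sid, genes in genome.genes_by_scaffold().items():
            for g in genes:
                attrs = f"ID={g.gene_id}"
                if g.family_id:
                    attrs += f";family={g.family_id}"
                fh.write(
                    f"{sid}\t{source}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def read_gff3(path, scaffolds: list[tuple[str, str]]) -> AnnotatedGenome:
    """Rebuild an AnnotatedGenome from scaffolds + a gene-level GFF3."""
    seqs = dict(scaffolds)
    genes: list[GeneModel] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            sid, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            sub = seqs[sid][start:end]
            cds = sub if strand == "+" else revcomp(sub)
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", f"{sid}:{start}"),
                    scaffold_id=sid,
                    start=start,
                    end=end,
                    strand=strand,
                    cds=cds,
                    family_id=attrs.get("family"),
                )
            )
    return AnnotatedGenome(scaffolds, genes, provenance=f"read from {path}")


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fastq")]


def write_truth_tables(truth: SimulationTruth, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(truth.duplicate_pairs, columns=["gene_a", "gene_b", "target_ks"]).to_csv(
        outdir / "truth_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(truth.adjacency, columns=["scaffold_a", "scaffold_b", "orientation"]).to_csv(
        outdir / "truth_adjacency.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(truth.repeat_gp.items()), columns=["family", "genome_fraction"]
    ).to_csv(outdir / "truth_gp.tsv", sep="\t", index=False)


_HIT_COLUMNS = [
    "query",
    "subject",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def write_hits_tsv(hits: Iterable[SimilarityHit], path) -> None:
    rows = []
    for h in hits:
        rows.append(
            (
                h.query_id,
                h.subject_id,
                round(h.identity * 100, 2),
                h.aln_len,
                h.mismatches,
                h.gap_opens,
                1,
                h.aln_len,
                1,
                h.aln_len,
                ".",
                h.score,
            )
        )
    pd.DataFrame(rows, columns=_HIT_COLUMNS).to_csv(path, sep="\t", index=False, header=False)


def read_hits_tsv(path, query_len: dict[str, int] | None = None) -> list[SimilarityHit]:
    """Import externally computed 12-column tabular hits.

    Coverages are computed from the alignment length when sequence lengths
    are supplied, else conservatively set to 1.0.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=_HIT_COLUMNS)
    hits = []
    for r in df.itertuples(index=False):
        qlen = (query_len or {}).get(r.query)
        slen = (query_len or {}).get(r.subject)
        qcov = min(r.length / qlen, 1.0) if qlen else 1.0
        scov = min(r.length / slen, 1.0) if slen else 1.0
        hits.append(
            SimilarityHit(
                query_id=str(r.query),
                subject_id=str(r.subject),
                score=float(r.bitscore),
                identity=float(r.pident) / 100.0,
                query_coverage=qcov,
                subject_coverage=scov,
                aln_len=int(r.length),
                mismatches=int(r.mismatch),
                gap_opens=int(r.gapopen),
            )
        )
    return hits


def write_edges_tsv(edges: Iterable[AdjacencyEdge], path) -> None:
    rows = [
        (
            e.scaffold_x,
            e.sign_x,
            e.scaffold_y,
            e.sign_y,
            e.evidence,
            ",".join(e.witnesses),
        )
        for e in edges
    ]
    pd.DataFrame(
        rows, columns=["scaffold_x", "sign_x", "scaffold_y", "sign_y", "evidence", "witnesses"]
    ).to_csv(path, sep="\t", index=False)


def write_agp(
    superscaffolds: Iterable[Superscaffold],
    scaffold_lengths: dict[str, int],
    path,
    gap_size: int = 100,
) -> None:
    """AGP v2.1: component lines with orientation, U gap lines of type
    scaffold with evidence align_genus."""
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for ss in superscaffolds:
            pos = 1
            part = 1
            for i, (sid, sign) in enumerate(ss.members):
                ln = scaffold_lengths[sid]
                fh.write(
                    f"{ss.id}\t{pos}\t{pos + ln - 1}\t{part}\tW\t{sid}\t1\t{ln}\t{sign}\n"
                )
                pos += ln
                part += 1
                if i < len(ss.members) - 1:
                    fh.write(
                        f"{ss.id}\t{pos}\t{pos + gap_size - 1}\t{part}\tU\t{gap_size}"
                        f"\tscaffold\tyes\talign_genus\n"
                    )
                    pos += gap_size
                    part += 1


def superscaffold_fasta(
    superscaffolds: Iterable[Superscaffold],
    scaffolds: dict[str, str],
    gap_size: int = 100,
) -> list[tuple[str, str]]:
    out = []
    for ss in superscaffolds:
        parts = []
        for sid, sign in ss.members:
            seq = scaffolds[sid]
            parts.append(seq if sign == "+" else revcomp(seq))
        out.append((ss.id, ("N" * gap_size).join(parts)))
    return out
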