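"""Synthetic allotetraploid genome simulator with ground-truth tables.

Generates an ancestral gene-dense genome, duplicates it by a whole-genome
duplication (WGD) at a chosen synonymous divergence, fragments chromosomes
into scaffolds (recording the true adjacencies), inserts repeat families at
chosen genome proportions, and simulates uniform-coverage WGS reads.  Every
operation records truth tables so downstream inference (homology, Ka/Ks,
synteny, zigzag ordering, repeat and presence/absence quantification) can be
scored against a known answer.

Mutations are codon-aware.  Synonymous events at each codon position are
modelled as a complete-graph random walk on the set of codons reachable by a
synonymous change at that position, with the Poisson event rate calibrated per
site-degeneracy class so that the Nei-Gojobori estimator with Jukes-Cantor
correction is unbiased for the requested Ks (see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._codon import (
    SENSE_CODONS,
    codon_sites,
    nonsynonymous_alternatives,
    revcomp,
    split_codons,
    synonymous_alternatives,
    translate_codon,
)

__all__ = [
    "GeneModel",
    "AnnotatedGenome",
    "SimulationTruth",
    "simulate_ancestral_genome",
    "apply_wgd",
    "fragment_into_scaffolds",
    "insert_repeats",
    "simulate_reads",
    "delete_genes",
]

KS_SATURATION_LIMIT = 3.0


@dataclass(frozen=True)
class GeneModel:
    """A gene model anchored on a scaffold; coordinates 0-based half-open."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    cds: str
    family_id: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class AnnotatedGenome:
    """Scaffold sequences plus ordered gene models."""

    scaffolds: list[tuple[str, str]]
    genes: list[GeneModel]
    provenance: str = ""

    def sequence(self, scaffold_id: str) -> str:
        for sid, seq in self.scaffolds:
            if sid == scaffold_id:
                return seq
        raise KeyError(scaffold_id)

    def genes_by_scaffold(self) -> dict[str, list[GeneModel]]:
        out: dict[str, list[GeneModel]] = {sid: [] for sid, _ in self.scaffolds}
        for g in self.genes:
            out[g.scaffold_id].append(g)
        for sid in out:
            out[sid].sort(key=lambda g: g.start)
        return out

    @property
    def total_length(self) -> int:
        return sum(len(s) for _, s in self.scaffolds)

    def validate(self) -> None:
        """Check structural invariants; raises AssertionError on violation."""
        seqs = dict(self.scaffolds)
        for sid, gs in self.genes_by_scaffold().items():
            prev_end = -1
            for g in gs:
                assert g.end <= len(seqs[sid]), f"{g.gene_id} exceeds scaffold"
                assert g.start >= prev_end, f"{g.gene_id} overlaps previous gene"
                prev_end = g.end
                embedded = seqs[sid][g.start : g.end]
                cds = embedded if g.strand == "+" else revcomp(embedded)
                assert cds == g.cds, f"{g.gene_id}: CDS does not match scaffold"
                for codon in split_codons(cds):
                    assert translate_codon(codon) != "*", (
                        f"{g.gene_id}: internal stop codon"
                    )


@dataclass
class SimulationTruth:
    """Oracle tables recorded by the simulator."""

    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    adjacency: list[tuple[str, str, str]] = field(default_factory=list)
    repeat_gp: dict[str, float] = field(default_factory=dict)
    genome_size: int = 0


# ---------------------------------------------------------------------------
# ancestral genome


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """A stop-free CDS: ATG followed by random sense codons."""
    codons = ["ATG"]
    idx = rng.integers(0, len(SENSE_CODONS), size=n_codons - 1)
    codons.extend(SENSE_CODONS[i] for i in idx)
    return "".join(codons)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_ancestral_genome(
    n_chromosomes: int,
    genes_per_chromosome: int,
    mean_gene_len: int = 1120,
    mean_intergenic_len: int = 500,
    seed: int = 0,
) -> AnnotatedGenome:
    """Generate a gene-dense ancestral genome.

    Genes are stop-codon-free CDSs placed in order along each chromosome with
    geometric intergenic spacers.  The default mean CDS length (1120 bp)
    mirrors a typical plant gene complement; intergenic spacers are kept
    desk-scale.  Output is byte-identical for identical parameters and seed.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValueError("n_chromosomes and genes_per_chromosome must be >= 1")
    if mean_gene_len < 30 or mean_intergenic_len < 30:
        raise ValueError("mean lengths must be >= 30 bp")
    rng = np.random.default_rng(seed)
    scaffolds: list[tuple[str, str]] = []
    genes: list[GeneModel] = []
    for ci in range(1, n_chromosomes + 1):
        chrom = f"chr{ci}"
        parts: list[str] = []
        pos = 0
        for gi in range(1, genes_per_chromosome + 1):
            spacer = int(rng.geometric(1.0 / mean_intergenic_len))
            parts.append(_random_dna(rng, spacer))
            pos += spacer
            n_codons = max(10, int(round(rng.normal(mean_gene_len / 3.0, mean_gene_len / 12.0))))
            cds = _random_cds(rng, n_codons)
            strand = "+" if rng.random() < 0.5 else "-"
            embedded = cds if strand == "+" else revcomp(cds)
            parts.append(embedded)
            genes.append(
                GeneModel(
                    gene_id=f"g{ci}_{gi}",
                    scaffold_id=chrom,
                    start=pos,
                    end=pos + len(cds),
                    strand=strand,
                    cds=cds,
                )
            )
            pos += len(cds)
        parts.append(_random_dna(rng, int(rng.geometric(1.0 / mean_intergenic_len))))
        scaffolds.append((chrom, "".join(parts)))
    return AnnotatedGenome(scaffolds, genes, provenance=f"ancestral seed={seed}")


# ---------------------------------------------------------------------------
# WGD with calibrated codon-aware divergence


def _calibrated_event_rate(n_alternatives: int, target_ks: float) -> float:
    """Total (both lineages) Poisson event rate for one codon position.

    For a site whose synonymous codon set is a complete graph on c+1 states,
    a random walk with Poisson(mu) total events gives
        P(differ) = c/(c+1) * (1 - exp(-mu*(c+1)/c)).
    We set P(differ) = (c/3) * D where D = 3/4*(1 - exp(-4/3*Ks)) is the
    Jukes-Cantor expectation, so NG86's pS = Sd/S has expectation D and the
    corrected Ks recovers target_ks.
    """
    c = n_alternatives
    if c == 0:
        return 0.0
    big_d = 0.75 * (1.0 - math.exp(-4.0 / 3.0 * target_ks))
    arg = 1.0 - (c + 1) / 3.0 * big_d
    if arg <= 0:  # unreachable for target_ks < 3 but guard anyway
        raise ValueError("target Ks saturates this site class")
    return -c / (c + 1) * math.log(arg)


def _mutate_cds_pair(
    cds: str, target_ks: float, ka_ks_ratio: float, rng: np.random.Generator
) -> tuple[str, str]:
    """Diverge a CDS into two descendant copies at expected NG86 Ks=target_ks."""
    codons_a = split_codons(cds)
    codons_b = list(codons_a)
    target_ka = ka_ks_ratio * target_ks
    for i, anc in enumerate(codons_a):
        for copy in (0, 1):
            cur = anc
            # synonymous events, calibrated per position degeneracy
            for pos in range(3):
                alts = synonymous_alternatives(anc, pos)
                if not alts:
                    continue
                mu = _calibrated_event_rate(len(alts), target_ks)
                n_events = rng.poisson(mu / 2.0)
                for _ in range(n_events):
                    choices = synonymous_alternatives(cur, pos)
                    if choices:
                        cur = choices[rng.integers(0, len(choices))]
            # nonsynonymous events: plain Poisson on nonsynonymous sites
            if target_ka > 0:
                _, n_sites = codon_sites(anc)
                n_events = rng.poisson(n_sites * target_ka / 2.0)
                for _ in range(n_events):
                    pos = int(rng.integers(0, 3))
                    choices = nonsynonymous_alternatives(cur, pos)
                    if choices:
                        cur = choices[rng.integers(0, len(choices))]
            if copy == 0:
                codons_a[i] = cur
            else:
                codons_b[i] = cur
    return "".join(codons_a), "".join(codons_b)


def _decompose(genome: AnnotatedGenome, scaffold_id: str):
    """Split a scaffold into alternating intergenic / gene sequence parts.

    Returns (parts, genes) where parts = [ig0, gene0, ig1, gene1, ..., igN]
    and genes are the ordered gene models of the scaffold.
    """
    seq = genome.sequence(scaffold_id)
    gs = genome.genes_by_scaffold()[scaffold_id]
    parts: list[str] = []
    pos = 0
    for g in gs:
        parts.append(seq[pos : g.start])
        parts.append(seq[g.start : g.end])
        pos = g.end
    parts.append(seq[pos:])
    return parts, gs


def _reassemble(
    scaffold_id: str, intergenic: list[str], genes: list[GeneModel]
) -> tuple[str, list[GeneModel]]:
    """Rebuild a scaffold from intergenic parts and gene models (CDS may be new)."""
    assert len(intergenic) == len(genes) + 1
    parts: list[str] = []
    out_genes: list[GeneModel] = []
    pos = 0
    for ig, g in zip(intergenic, genes):
        parts.append(ig)
        pos += len(ig)
        embedded = g.cds if g.strand == "+" else revcomp(g.cds)
        parts.append(embedded)
        out_genes.append(replace(g, scaffold_id=scaffold_id, start=pos, end=pos + len(embedded)))
        pos += len(embedded)
    parts.append(intergenic[-1])
    return "".join(parts), out_genes


def apply_wgd(
    genome: AnnotatedGenome,
    target_ks: float,
    ka_ks_ratio: float = 0.3,
    retention: float = 1.0,
    seed: int = 0,
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Duplicate every chromosome and diverge the gene copies to Ks=target_ks.

    Both descendant copies are mutated (half the divergence on each lineage).
    A fraction (1 - retention) of the duplicated genes is deleted from the new
    copy, uniformly at random; retained pairs are recorded as truth.
    """
    if target_ks < 0:
        raise ValueError("target_ks must be >= 0")
    if target_ks > KS_SATURATION_LIMIT:
        raise ValueError(
            f"target_ks={target_ks} is in the saturation regime (> {KS_SATURATION_LIMIT})"
        )
    if not 0.0 <= retention <= 1.0:
        raise ValueError("retention must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    new_scaffolds: list[tuple[str, str]] = []
    new_genes: list[GeneModel] = []
    for sid, _seq in genome.scaffolds:
        parts, gs = _decompose(genome, sid)
        intergenic = parts[0::2]
        genes_a: list[GeneModel] = []
        genes_b: list[GeneModel] = []
        keep_b: list[bool] = []
        for g in gs:
            cds_a, cds_b = _mutate_cds_pair(g.cds, target_ks, ka_ks_ratio, rng)
            kept = bool(rng.random() < retention)
            keep_b.append(kept)
            genes_a.append(replace(g, cds=cds_a))
            if kept:
                genes_b.append(replace(g, gene_id=g.gene_id + "_d", cds=cds_b))
                truth.duplicate_pairs.append((g.gene_id, g.gene_id + "_d", target_ks))
        sid_b = sid + "_d"
        seq_a, placed_a = _reassemble(sid, intergenic, genes_a)
        intergenic_b = [ig for ig, k in zip(intergenic[:-1], keep_b) if k]
        # intergenic segments of deleted genes are excised together with the gene
        intergenic_b.append(intergenic[-1])
        seq_b, placed_b = _reassemble(sid_b, intergenic_b, genes_b)
        new_scaffolds.append((sid, seq_a))
        new_scaffolds.append((sid_b, seq_b))
        new_genes.extend(placed_a)
        new_genes.extend(placed_b)
    out = AnnotatedGenome(
        new_scaffolds,
        new_genes,
        provenance=genome.provenance + f"; wgd ks={target_ks} seed={seed}",
    )
    truth.genome_size = out.total_length
    return out, truth


# ---------------------------------------------------------------------------
# fragmentation


def fragment_into_scaffolds(
    genome: AnnotatedGenome,
    breaks_per_chromosome: int,
    min_fragment: int = 1,
    seed: int = 0,
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Break each chromosome at intergenic midpoints into scaffolds.

    k breaks yield k+1 scaffolds and k truth adjacency records.  Total
    sequence length is conserved and no gene is split.
    """
    if min_fragment < 1:
        raise ValueError("min_fragment must be >= 1")
    if breaks_per_chromosome < 0:
        raise ValueError("breaks_per_chromosome must be >= 0")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    new_scaffolds: list[tuple[str, str]] = []
    new_genes: list[GeneModel] = []
    by_scaffold = genome.genes_by_scaffold()
    for sid, seq in genome.scaffolds:
        gs = by_scaffold[sid]
        k = breaks_per_chromosome
        if k == 0 or not gs:
            new_scaffolds.append((sid, seq))
            new_genes.extend(gs)
            continue
        # candidate breakpoints: midpoints of gaps between consecutive genes
        candidates = [
            (gs[i].end + gs[i + 1].start) // 2
            for i in range(len(gs) - 1)
            if gs[i + 1].start > gs[i].end
        ]
        if k > len(candidates):
            raise ValueError(
                f"chromosome {sid}: {k} breaks requested but only "
                f"{len(candidates)} intergenic gaps available"
            )
        breaks = None
        for _ in range(200):
            chosen = sorted(rng.choice(len(candidates), size=k, replace=False))
            pts = [candidates[i] for i in chosen]
            bounds = [0] + pts + [len(seq)]
            if all(b - a >= min_fragment for a, b in zip(bounds, bounds[1:])):
                breaks = pts
                break
        if breaks is None:
            raise ValueError(
                f"chromosome {sid}: cannot place {k} breaks with min_fragment={min_fragment}"
            )
        bounds = [0] + breaks + [len(seq)]
        prev_name = None
        for fi, (a, b) in enumerate(zip(bounds, bounds[1:]), start=1):
            name = f"{sid}_s{fi}"
            new_scaffolds.append((name, seq[a:b]))
            for g in gs:
                if a <= g.start and g.end <= b:
                    new_genes.append(replace(g, scaffold_id=name, start=g.start - a, end=g.end - a))
            if prev_name is not None:
                truth.adjacency.append((prev_name, name, "++"))
            prev_name = name
    out = AnnotatedGenome(
        new_scaffolds,
        new_genes,
        provenance=genome.provenance + f"; fragmented k={breaks_per_chromosome} seed={seed}",
    )
    truth.genome_size = out.total_length
    return out, truth


# ---------------------------------------------------------------------------
# repeats


def _mutate_copy(consensus: str, divergence: float, rng: np.random.Generator) -> str:
    if divergence <= 0:
        return consensus
    arr = np.frombuffer(consensus.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < divergence)
    lookup = {ord(b): [ord(x) for x in "ACGT" if x != b] for b in "ACGT"}
    for i in hits:
        opts = lookup.get(int(arr[i]))
        if opts:
            arr[i] = opts[rng.integers(0, 3)]
    return arr.tobytes().decode()


def insert_repeats(
    genome: AnnotatedGenome,
    families: dict[str, tuple[str, float]],
    copy_divergence: float = 0.01,
    seed: int = 0,
) -> tuple[AnnotatedGenome, SimulationTruth]:
    """Insert mutated repeat copies at intergenic positions.

    `families` maps family name -> (consensus sequence, target genome
    proportion of the *final* genome).  Realized proportions are recorded in
    the truth table and land within +-0.5 percentage points of the target.
    """
    targets = {f: gp for f, (_c, gp) in families.items() if gp > 0}
    for f, (cons, gp) in families.items():
        if gp < 0 or gp >= 1:
            raise ValueError(f"family {f}: target_gp must lie in [0, 1)")
        if gp > 0 and len(cons) < 50:
            raise ValueError(f"family {f}: consensus must be >= 50 bp")
    total_gp = sum(targets.values())
    if total_gp >= 0.9:
        raise ValueError("summed target_gp must be < 0.9")
    rng = np.random.default_rng(seed)
    truth = SimulationTruth()
    g0 = genome.total_length
    if not targets:
        truth.genome_size = g0
        return genome, truth
    g_final = g0 / (1.0 - total_gp)
    # per-scaffold part lists: [ig0, gene0, ig1, ..., igN]
    decomposed = {sid: _decompose(genome, sid) for sid, _ in genome.scaffolds}
    inserted: dict[str, int] = {}
    # insertion slots weighted by scaffold count of intergenic segments
    sids = [sid for sid, _ in genome.scaffolds]
    for fam in sorted(targets):
        consensus, _gp = families[fam]
        need = int(round(targets[fam] * g_final))
        placed = 0
        while placed < need:
            copy = _mutate_copy(consensus, copy_divergence, rng)
            if need - placed < len(copy):
                copy = copy[: need - placed]
                if not copy:
                    break
            sid = sids[rng.integers(0, len(sids))]
            parts, _gs = decomposed[sid]
            ig_indices = list(range(0, len(parts), 2))
            slot = ig_indices[rng.integers(0, len(ig_indices))]
            seg = parts[slot]
            off = int(rng.integers(0, len(seg) + 1))
            parts[slot] = seg[:off] + copy + seg[off:]
            placed += len(copy)
        inserted[fam] = placed
    new_scaffolds: list[tuple[str, str]] = []
    new_genes: list[GeneModel] = []
    for sid, _seq in genome.scaffolds:
        parts, gs = decomposed[sid]
        seq, placed_genes = _reassemble(sid, parts[0::2], gs)
        new_scaffolds.append((sid, seq))
        new_genes.extend(placed_genes)
    out = AnnotatedGenome(
        new_scaffolds,
        new_genes,
        provenance=genome.provenance + f"; repeats seed={seed}",
    )
    truth.genome_size = out.total_length
    truth.repeat_gp = {f: inserted[f] / out.total_length for f in inserted}
    return out, truth


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genome: AnnotatedGenome,
    coverage: float,
    read_len: int = 100,
    error_rate: float = 0.0,
    paired: bool = False,
    insert_size: int | None = None,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate uniform-coverage WGS reads; returns [(read_id, sequence), ...].

    Read count is round(coverage * genome_bp / read_len) (per mate when
    paired); start positions are uniform over valid positions and substitution
    errors are i.i.d. at `error_rate`.  Deterministic per seed.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    for sid, seq in genome.scaffolds:
        if read_len > len(seq):
            raise ValueError(f"read_len {read_len} exceeds scaffold {sid} ({len(seq)} bp)")
    if paired:
        insert_size = insert_size or 3 * read_len
        if insert_size < read_len:
            raise ValueError("insert_size must be >= read_len")
    rng = np.random.default_rng(seed)
    genome_bp = genome.total_length
    n_reads = int(round(coverage * genome_bp / read_len))
    span = insert_size if paired else read_len
    sids, seqs = zip(*genome.scaffolds)
    weights = np.array([max(len(s) - span + 1, 0) for s in seqs], dtype=float)
    if weights.sum() == 0:
        raise ValueError("no scaffold long enough for the requested fragment span")
    probs = weights / weights.sum()
    scaffold_idx = rng.choice(len(sids), size=n_reads, p=probs)
    fracs = rng.random(n_reads)
    strands = rng.random(n_reads) < 0.5
    reads: list[tuple[str, str]] = []

    def _with_errors(s: str) -> str:
        if error_rate <= 0:
            return s
        arr = np.frombuffer(s.encode(), dtype=np.uint8).copy()
        hits = np.flatnonzero(rng.random(arr.size) < error_rate)
        for i in hits:
            cur = chr(arr[i])
            opts = [x for x in "ACGT" if x != cur]
            arr[i] = ord(opts[rng.integers(0, 3)])
        return arr.tobytes().decode()

    for ri in range(n_reads):
        si = int(scaffold_idx[ri])
        seq = seqs[si]
        start = int(fracs[ri] * (len(seq) - span + 1))
        fwd = strands[ri]
        if paired:
            frag = seq[start : start + span]
            if not fwd:
                frag = revcomp(frag)
            r1 = _with_errors(frag[:read_len])
            r2 = _with_errors(revcomp(frag[-read_len:]))
            reads.append((f"rd{ri}/{sids[si]}:{start}:{'+' if fwd else '-'}/1", r1))
            reads.append((f"rd{ri}/{sids[si]}:{start}:{'+' if fwd else '-'}/2", r2))
        else:
            sub = seq[start : start + read_len]
            if not fwd:
                sub = revcomp(sub)
            reads.append(
                (f"rd{ri}/{sids[si]}:{start}:{'+' if fwd else '-'}", _with_errors(sub))
            )
    return reads


# ---------------------------------------------------------------------------
# helpers for presence/absence experiments


def delete_genes(genome: AnnotatedGenome, gene_ids: set[str]) -> AnnotatedGenome:
    """Excise the named genes (model + embedded sequence) from the genome."""
    new_scaffolds: list[tuple[str, str]] = []
    new_genes: list[GeneModel] = []
    for sid, _seq in genome.scaffolds:
        parts, gs = _decompose(genome, sid)
        intergenic = parts[0::2]
        kept_ig: list[str] = []
        kept_genes: list[GeneModel] = []
        carry = ""
        for ig, g in zip(intergenic[:-1], gs):
            if g.gene_id in gene_ids:
                carry += ig
            else:
                kept_ig.append(carry + ig)
                kept_genes.append(g)
                carry = ""
        kept_ig.append(carry + intergenic[-1])
        seq, placed = _reassemble(sid, kept_ig, kept_genes)
        new_scaffolds.append((sid, seq))
        new_genes.extend(placed)
    return AnnotatedGenome(
        new_scaffolds, new_genes, provenance=genome.provenance + "; genes deleted"
    )
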