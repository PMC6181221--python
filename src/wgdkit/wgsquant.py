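"""Assembly-free quantification from low-coverage WGS reads.

Three estimators that need no genome assembly:

* genome size from the k-mer frequency spectrum (G = retained k-mer total /
  homozygous peak depth, error-depth tail excluded);
* repeat genome proportion (GP) per family by masking read bases that share
  runs of exact canonical k-mers with the family consensus,
  GP(%) = masked read bp / total read bp x 100, and absolute repeat amount
  GP x G;
* gene presence/absence from breadth of read coverage over each CDS.

The masking step is an exact-k-mer surrogate for alignment-based repeat
masking: adequate for young, high-identity repeat families, and deterministic.
A minimal exact-seed read mapper is included for synthetic experiments; real
alignments should be supplied as SAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._codon import revcomp

__all__ = [
    "KmerHistogram",
    "GenomeSizeEstimate",
    "GPEstimate",
    "PresenceCall",
    "kmer_histogram",
    "estimate_genome_size",
    "mask_reads",
    "genome_proportion",
    "repeat_amount",
    "map_reads_to_cds",
    "cds_breadth",
    "cds_breadth_from_sam",
    "call_presence",
]

_BASE_CODE = np.full(256, 4, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical k-mer codes for every window; -1 where a window has a non-ACGT."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 4).any(axis=1)
    pw_f = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    fwd = win @ pw_f
    pw_r = 4 ** np.arange(k, dtype=np.int64)
    rev = (3 - win) @ pw_r
    canon = np.minimum(fwd, rev)
    canon[~valid] = -1
    return canon


def _reads_as_seqs(reads) -> list[str]:
    out = []
    for r in reads:
        if isinstance(r, str):
            out.append(r)
        else:  # (id, seq) or (id, seq, qual)
            out.append(r[1])
    return out


@dataclass
class KmerHistogram:
    k: int
    counts: dict[int, int]  # depth c -> number of distinct k-mers

    @property
    def total_kmers(self) -> int:
        return sum(c * n for c, n in self.counts.items())


@dataclass
class GenomeSizeEstimate:
    size_bp: float
    peak_depth: int
    excluded_error_depth: int
    method: str = "kmer"


def kmer_histogram(reads, k: int = 23) -> KmerHistogram:
    """Exact canonical k-mer frequency spectrum of a read set."""
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids self-reverse-complement k-mers)")
    seqs = _reads_as_seqs(reads)
    if any(len(s) < k for s in seqs):
        raise ValueError(f"k={k} exceeds the shortest read length")
    chunks = []
    for s in seqs:
        codes = _kmer_codes(_encode(s), k)
        chunks.append(codes[codes >= 0])
    allc = np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    if allc.size == 0:
        raise ValueError("no valid k-mers in input")
    _, per_kmer = np.unique(allc, return_counts=True)
    depths, n_kmers = np.unique(per_kmer, return_counts=True)
    return KmerHistogram(k, {int(d): int(n) for d, n in zip(depths, n_kmers)})


def estimate_genome_size(
    hist: KmerHistogram, error_depth_cutoff: int | str = "auto"
) -> GenomeSizeEstimate:
    """Genome size G = total retained k-mers / homozygous peak depth.

    Depths at or below the error cutoff (auto = first local minimum of the
    depth spectrum, 0 when the spectrum rises from depth 1) are excluded; the
    peak depth is the argmax of lightly smoothed c*count(c) above the cutoff.
    """
    max_depth = max(hist.counts)
    dense = np.zeros(max_depth + 1, dtype=float)
    for c, n in hist.counts.items():
        dense[c] = n
    if error_depth_cutoff == "auto":
        cutoff = 0
        for c in range(1, max_depth):
            if dense[c] > 0 and dense[c] <= dense[c + 1]:
                cutoff = c
                break
            if dense[c] > 0 and c + 1 <= max_depth and dense[c] > dense[c + 1]:
                continue
    else:
        cutoff = int(error_depth_cutoff)
    mass = np.arange(max_depth + 1) * dense
    smoothed = np.convolve(mass, np.ones(3) / 3.0, mode="same")
    region = smoothed[cutoff + 1 :]
    if region.size == 0 or region.max() <= 0:
        raise ValueError("no interior k-mer coverage mode; increase coverage")
    peak_depth = int(np.argmax(region)) + cutoff + 1
    # smoothing spreads a sharp peak over neighbours; snap to the raw maximum
    lo, hi = max(cutoff + 1, peak_depth - 1), min(max_depth, peak_depth + 1)
    peak_depth = int(lo + np.argmax(mass[lo : hi + 1]))
    retained_total = float(mass[cutoff + 1 :].sum())
    return GenomeSizeEstimate(retained_total / peak_depth, peak_depth, cutoff)


# ---------------------------------------------------------------------------
# repeat genome proportion


@dataclass
class GPEstimate:
    family: str
    masked_bp: int
    total_bp: int
    genome_size_bp: float | None = None

    @property
    def gp_percent(self) -> float:
        return genome_proportion(self.masked_bp, self.total_bp)

    @property
    def repeat_amount_bp(self) -> float | None:
        if self.genome_size_bp is None:
            return None
        return repeat_amount(self.gp_percent, self.genome_size_bp)


def genome_proportion(masked_bp: float, total_bp: float) -> float:
    """GP (%) = masked read length / total read length x 100."""
    if total_bp <= 0:
        raise ValueError("total_bp must be > 0")
    if masked_bp > total_bp:
        raise ValueError("masked_bp cannot exceed total_bp")
    return masked_bp / total_bp * 100.0


def repeat_amount(gp_percent: float, genome_size: float) -> float:
    """Absolute repeat content in bp: GP x genome size."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    return gp_percent / 100.0 * genome_size


def mask_reads(
    reads,
    repeat_library: dict[str, str],
    match_k: int = 17,
    min_run: int = 2,
) -> tuple[dict[str, int], int]:
    """Mask read bases shared with repeat-family consensus sequences.

    A read base is masked for family F when it lies in a maximal run of at
    least `min_run` consecutive canonical `match_k`-mers present in F's
    consensus.  Overlapping family claims resolve to the longer run (ties:
    lexically smaller family id).  Returns ({family: masked_bp}, total_bp).
    """
    for fam, cons in repeat_library.items():
        if len(cons) < match_k:
            raise ValueError(f"family {fam}: consensus shorter than match_k")
    seqs = _reads_as_seqs(reads)
    total_bp = sum(len(s) for s in seqs)
    if not seqs:
        return ({f: 0 for f in repeat_library}, 0)
    # concatenate reads with k 'N's so k-mers and runs cannot span reads
    sep = np.full(match_k, 4, dtype=np.int64)
    parts = []
    for s in seqs:
        parts.append(_encode(s))
        parts.append(sep)
    concat = np.concatenate(parts[:-1])
    read_base = np.ones(concat.size, dtype=bool)
    pos = 0
    for s in seqs:
        pos += len(s)
        read_base[pos : pos + match_k] = False
        pos += match_k
    codes = _kmer_codes(concat, match_k)
    families = sorted(repeat_library)
    best_len = np.zeros(concat.size, dtype=np.int32)
    best_fam = np.full(concat.size, -1, dtype=np.int16)
    for fi, fam in enumerate(families):
        fam_codes = np.unique(_kmer_codes(_encode(repeat_library[fam]), match_k))
        fam_codes = fam_codes[fam_codes >= 0]
        hit = np.isin(codes, fam_codes) & (codes >= 0)
        if not hit.any():
            continue
        # maximal runs of consecutive matching k-mer start positions
        padded = np.concatenate(([False], hit, [False]))
        d = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(d == 1)
        ends = np.flatnonzero(d == -1)  # exclusive
        for s, e in zip(starts, ends):
            run = e - s
            if run < min_run:
                continue
            b0, b1 = s, e - 1 + match_k  # masked base interval [b0, b1)
            better = best_len[b0:b1] < run
            best_len[b0:b1][better] = run
            best_fam[b0:b1][better] = fi
    masked = {f: 0 for f in families}
    claimed = best_fam >= 0
    claimed &= read_base
    if claimed.any():
        fams_hit, counts = np.unique(best_fam[claimed], return_counts=True)
        for fi, n in zip(fams_hit, counts):
            masked[families[int(fi)]] = int(n)
    return masked, total_bp


# ---------------------------------------------------------------------------
# CDS breadth of coverage and presence/absence


@dataclass
class PresenceCall:
    gene_id: str
    cds_len: int
    covered_bp: int
    call: str | None = None  # 'present' / 'absent'
    threshold: float | None = None

    @property
    def breadth(self) -> float:
        return self.covered_bp / self.cds_len if self.cds_len else 0.0


def _union_length(intervals: list[tuple[int, int]]) -> int:
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    cs, ce = intervals[0]
    for s, e in intervals[1:]:
        if s > ce:
            total += ce - cs
            cs, ce = s, e
        else:
            ce = max(ce, e)
    return total + (ce - cs)


def map_reads_to_cds(
    reads,
    cds: dict[str, str],
    seed_k: int = 31,
    seed_step: int = 8,
) -> dict[str, list[tuple[int, int]]]:
    """Exact-seed placement of reads onto CDS sequences (synthetic data only).

    For each read (both strands) seeds of length `seed_k` are tried every
    `seed_step` bases until one matches a unique CDS position; the read then
    claims the ungapped interval implied by the seed.  Returns per-gene
    aligned intervals.
    """
    index: dict[int, tuple[str, int] | None] = {}
    for gid, seq in cds.items():
        codes = _encode(seq)
        n = len(seq) - seed_k + 1
        if n <= 0:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, seed_k)
        pw = 4 ** np.arange(seed_k - 1, -1, -1, dtype=np.int64)
        fwd = win @ pw
        valid = ~(win == 4).any(axis=1)
        for p in range(n):
            if not valid[p]:
                continue
            key = int(fwd[p])
            index[key] = None if key in index else (gid, p)
    pw = 4 ** np.arange(seed_k - 1, -1, -1, dtype=np.int64)
    hits: dict[str, list[tuple[int, int]]] = {gid: [] for gid in cds}
    for r in _reads_as_seqs(reads):
        placed = False
        for variant in (r, revcomp(r)):
            codes = _encode(variant)
            n = len(variant) - seed_k + 1
            if n <= 0:
                break
            offsets = list(range(0, n, seed_step))
            if offsets[-1] != n - 1:
                offsets.append(n - 1)
            for off in offsets:
                win = codes[off : off + seed_k]
                if (win == 4).any():
                    continue
                key = int(win @ pw)
                entry = index.get(key)
                if entry is None:
                    continue
                gid, p = entry
                start = p - off
                end = start + len(variant)
                start = max(start, 0)
                end = min(end, len(cds[gid]))
                if end > start:
                    hits[gid].append((start, end))
                placed = True
                break
            if placed:
                break
    return hits


def cds_breadth(
    intervals_by_gene: dict[str, list[tuple[int, int]]], cds: dict[str, str]
) -> list[PresenceCall]:
    """Breadth of coverage per CDS from aligned read intervals (union)."""
    out = []
    for gid in sorted(cds):
        covered = _union_length(list(intervals_by_gene.get(gid, [])))
        out.append(PresenceCall(gid, len(cds[gid]), covered))
    return out


def cds_breadth_from_sam(
    sam_path: str, cds: dict[str, str], min_mapq: int = 1
) -> list[PresenceCall]:
    """Breadth of coverage from a SAM file (primary alignments, MAPQ >= 1)."""
    import pysam

    intervals: dict[str, list[tuple[int, int]]] = {gid: [] for gid in cds}
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < min_mapq:
                continue
            ref = aln.reference_name
            if ref not in intervals:
                raise ValueError(f"alignment reference {ref!r} not in the gene set")
            intervals[ref].extend(aln.get_blocks())
    return cds_breadth(intervals, cds)


def call_presence(
    records: Sequence[PresenceCall], threshold: float = 0.5
) -> list[PresenceCall]:
    """present <=> breadth >= threshold."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    out = []
    for r in records:
        call = "present" if r.breadth >= threshold else "absent"
        out.append(PresenceCall(r.gene_id, r.cds_len, r.covered_bp, call, threshold))
    return out
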