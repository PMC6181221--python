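"""Codon-aware pairwise divergence: Nei-Gojobori (1986) Ka/Ks and Kimura
two-parameter nucleotide distance.

NG86 counts fractional synonymous (S) and nonsynonymous (N) sites per codon,
counts synonymous/nonsynonymous differences (Sd, Nd) by averaging over all
shortest mutational pathways between differing codons (pathways through stop
codons excluded, equal weights), and applies the Jukes-Cantor correction

    Ks = -(3/4) * ln(1 - (4/3) * pS),   pS = Sd / S

(and analogously Ka).  The estimator saturates when the log argument is
non-positive; such pairs are flagged rather than assigned a distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._codon import (
    codon_pair_differences,
    codon_sites,
    split_codons,
    translate_codon,
)

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "NucDistance",
    "codon_align",
    "ng86",
    "k2p",
    "kaks_table",
]

GAP_CODON = "---"


@dataclass
class CodonAlignment:
    """Aligned codon columns for two CDSs; a column is (codon|'---', codon|'---')."""

    gene_a: str
    gene_b: str
    columns: list[tuple[str, str]]

    def __post_init__(self):
        for ca, cb in self.columns:
            if ca == GAP_CODON and cb == GAP_CODON:
                raise ValueError("column pairs two gaps")

    @property
    def ungapped_columns(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b in self.columns if a != GAP_CODON and b != GAP_CODON]

    def coverage(self, cds_a: str, cds_b: str) -> float:
        """Aligned (ungapped) codon columns over the shorter CDS's codon count."""
        shorter = min(len(cds_a), len(cds_b)) // 3
        return len(self.ungapped_columns) / shorter if shorter else 0.0


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float
    Ks: float
    status: str  # 'ok' or 'saturated'

    @property
    def pS(self) -> float:
        return self.Sd / self.S if self.S else float("nan")

    @property
    def pN(self) -> float:
        return self.Nd / self.N if self.N else float("nan")


@dataclass
class NucDistance:
    P: float
    Q: float
    d: float
    model: str = "K2P"
    status: str = "ok"


def codon_align(
    cds_a: str,
    cds_b: str,
    protein_alignment: tuple[str, str],
    gene_a: str = "a",
    gene_b: str = "b",
) -> CodonAlignment:
    """Thread two CDSs through a gapped protein alignment (back-translation).

    `protein_alignment` is a pair of equal-length gapped amino-acid strings
    whose ungapped rows must equal the CDS translations.
    """
    row_a, row_b = protein_alignment
    if len(row_a) != len(row_b):
        raise ValueError("alignment rows differ in length")
    codons_a = split_codons(cds_a)
    codons_b = split_codons(cds_b)
    ia = ib = 0
    columns: list[tuple[str, str]] = []
    for col, (aa, ab) in enumerate(zip(row_a, row_b)):
        if aa == "-":
            ca = GAP_CODON
        else:
            if ia >= len(codons_a) or translate_codon(codons_a[ia]) != aa:
                raise ValueError(f"CDS a does not match protein alignment at column {col}")
            ca = codons_a[ia]
            ia += 1
        if ab == "-":
            cb = GAP_CODON
        else:
            if ib >= len(codons_b) or translate_codon(codons_b[ib]) != ab:
                raise ValueError(f"CDS b does not match protein alignment at column {col}")
            cb = codons_b[ib]
            ib += 1
        columns.append((ca, cb))
    if ia != len(codons_a) or ib != len(codons_b):
        # allow a trailing stop codon on either CDS
        rem_a = codons_a[ia:]
        rem_b = codons_b[ib:]
        if any(translate_codon(c) != "*" for c in rem_a + rem_b):
            raise ValueError("CDS extends beyond the protein alignment")
    return CodonAlignment(gene_a, gene_b, columns)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """Nei-Gojobori site/difference counting with Jukes-Cantor correction."""
    cols = alignment.ungapped_columns
    if not cols:
        raise ValueError("alignment has no ungapped codon columns")
    s_a = n_a = s_b = n_b = 0.0
    sd = nd = 0.0
    for ca, cb in cols:
        sa, na = codon_sites(ca)
        sb, nb = codon_sites(cb)
        s_a += sa
        n_a += na
        s_b += sb
        n_b += nb
        dsd, dnd = codon_pair_differences(ca, cb)
        sd += dsd
        nd += dnd
    S = (s_a + s_b) / 2.0
    N = (n_a + n_b) / 2.0
    pS = sd / S if S > 0 else 0.0
    pN = nd / N if N > 0 else 0.0
    status = "ok"
    ks = ka = float("nan")
    if 1.0 - 4.0 / 3.0 * pS > 0 and 1.0 - 4.0 / 3.0 * pN > 0:
        ks = -0.75 * math.log(1.0 - 4.0 / 3.0 * pS)
        ka = -0.75 * math.log(1.0 - 4.0 / 3.0 * pN)
    else:
        status = "saturated"
    return KaKsResult(alignment.gene_a, alignment.gene_b, S, N, sd, nd, ka, ks, status)


# ---------------------------------------------------------------------------
# Kimura 2-parameter distance

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES and b in _PURINES) or (a in _PYRIMIDINES and b in _PYRIMIDINES)


def k2p(seq_a: str, seq_b: str) -> NucDistance:
    """Kimura two-parameter distance between two aligned nucleotide sequences.

    Sequences must have equal length (align beforehand; gaps '-' and
    ambiguity codes are excluded column-wise).  Saturated pairs (log argument
    <= 0) are returned with status='saturated' and d=nan.
    """
    a = seq_a.upper().replace("U", "T")
    b = seq_b.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for x, y in zip(a, b):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if _is_transition(x, y):
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P = ts / n
    Q = tv / n
    arg1 = 1.0 - 2.0 * P - Q
    arg2 = 1.0 - 2.0 * Q
    if arg1 <= 0 or arg2 <= 0:
        return NucDistance(P, Q, float("nan"), "K2P", "saturated")
    d = -0.5 * math.log(arg1) - 0.25 * math.log(arg2)
    return NucDistance(P, Q, d, "K2P", "ok")


# ---------------------------------------------------------------------------
# batch interface

KS_TABLE_COLUMNS = ["gene_a", "gene_b", "S", "N", "Sd", "Nd", "Ka", "Ks", "status"]


def kaks_table(
    results: list[KaKsResult],
    min_coverage: float = 0.5,
    coverages: list[float] | None = None,
) -> pd.DataFrame:
    """Assemble NG86 results into the standard Ks table.

    Pairs whose alignment covered less than `min_coverage` of the shorter CDS
    (when coverages are supplied) are flagged status='low_coverage' so that
    distribution building excludes them.
    """
    rows = []
    for i, r in enumerate(results):
        status = r.status
        if coverages is not None and coverages[i] < min_coverage:
            status = "low_coverage"
        rows.append((r.gene_a, r.gene_b, r.S, r.N, r.Sd, r.Nd, r.Ka, r.Ks, status))
    return pd.DataFrame(rows, columns=KS_TABLE_COLUMNS)
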