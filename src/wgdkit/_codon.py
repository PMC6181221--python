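"""Codon-level bookkeeping shared by the simulator and the Ka/Ks estimator.

Standard genetic code only. Synonymous-site fractions follow the classic
Nei-Gojobori counting convention: at each codon position the synonymous
fraction is (number of synonymous single-nucleotide alternatives)/3, with
changes that create a stop codon counted as nonsynonymous, so per-codon
synonymous + nonsynonymous sites always total 3.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import permutations, product

NUCLEOTIDES = "TCAG"

#: codon -> amino acid (one letter), '*' for stop
GENETIC_CODE: dict[str, str] = {}
_aas = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, (_n1, _n2, _n3) in enumerate(product(NUCLEOTIDES, repeat=3)):
    GENETIC_CODE[_n1 + _n2 + _n3] = _aas[_i]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c in GENETIC_CODE if c not in STOP_CODONS))


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon.upper().replace("U", "T")]


@lru_cache(maxsize=None)
def synonymous_alternatives(codon: str, pos: int) -> tuple[str, ...]:
    """Sense codons reachable from `codon` by a synonymous change at `pos`."""
    aa = GENETIC_CODE[codon]
    out = []
    for nt in "ACGT":
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt not in STOP_CODONS and GENETIC_CODE[alt] == aa:
            out.append(alt)
    return tuple(out)


@lru_cache(maxsize=None)
def nonsynonymous_alternatives(codon: str, pos: int) -> tuple[str, ...]:
    """Sense codons reachable from `codon` by a nonsynonymous change at `pos`.

    Stop codons are excluded (they are counted as nonsynonymous *sites* but are
    never legal mutation targets in the simulator).
    """
    aa = GENETIC_CODE[codon]
    out = []
    for nt in "ACGT":
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt not in STOP_CODONS and GENETIC_CODE[alt] != aa:
            out.append(alt)
    return tuple(out)


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) fractional site counts for one codon.

    Per position the synonymous fraction is c/3 where c is the number of
    synonymous single-nucleotide alternatives; the two fractions sum to 3.
    """
    codon = codon.upper().replace("U", "T")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site decomposition")
    s = sum(len(synonymous_alternatives(codon, p)) / 3.0 for p in range(3))
    return s, 3.0 - s


def _pathway_steps(c1: str, c2: str, order: tuple[int, ...]):
    """Yield (from_codon, to_codon) steps changing positions of c1 to c2 in `order`."""
    cur = c1
    for pos in order:
        nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
        yield cur, nxt
        cur = nxt


@lru_cache(maxsize=None)
def codon_pair_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two sense codons.

    All shortest mutational pathways between the codons are enumerated; each
    step is classified synonymous/nonsynonymous; pathways passing through a
    stop codon are excluded and the remainder averaged with equal weights.
    If every pathway passes through a stop codon (possible only for 2-3
    differences), all pathways are used with stop-crossing steps counted as
    nonsynonymous.
    """
    c1 = c1.upper().replace("U", "T")
    c2 = c2.upper().replace("U", "T")
    if c1 in STOP_CODONS or c2 in STOP_CODONS:
        raise ValueError("stop codons are not comparable")
    diff_pos = tuple(p for p in range(3) if c1[p] != c2[p])
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        sd = nd = 0
        through_stop = False
        for a, b in _pathway_steps(c1, c2, order):
            if b in STOP_CODONS or a in STOP_CODONS:
                through_stop = True
                nd += 1
            elif GENETIC_CODE[a] == GENETIC_CODE[b]:
                sd += 1
            else:
                nd += 1
        (blocked if through_stop else valid).append((sd, nd))
    pool = valid if valid else blocked
    sd_avg = sum(p[0] for p in pool) / len(pool)
    nd_avg = sum(p[1] for p in pool) / len(pool)
    return sd_avg, nd_avg


def split_codons(cds: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
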