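"""Independent brute-force oracles used by the tests.

Deliberately written from first principles (own genetic-code handling, own
dynamic programme) so they share no code path with the package.
"""

from __future__ import annotations

import math
from itertools import permutations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_oracle(cds_a: str, cds_b: str) -> dict:
    """Nei-Gojobori counting by exhaustive per-codon pathway enumeration."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    S = N = Sd = Nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        for codon in (ca, cb):
            s = 0.0
            for pos in range(3):
                for nt in "ACGT":
                    if nt == codon[pos]:
                        continue
                    alt = codon[:pos] + nt + codon[pos + 1 :]
                    if alt not in _STOPS and _aa(alt) == _aa(codon):
                        s += 1.0 / 3.0
            S += s / 2.0
            N += (3.0 - s) / 2.0
        diff = [p for p in range(3) if ca[p] != cb[p]]
        if not diff:
            continue
        paths = []
        for order in permutations(diff):
            cur = ca
            sd = nd = 0
            stop_hit = False
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in _STOPS or cur in _STOPS:
                    stop_hit = True
                    nd += 1
                elif _aa(cur) == _aa(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((stop_hit, sd, nd))
        clean = [(sd, nd) for stop, sd, nd in paths if not stop]
        pool = clean if clean else [(sd, nd) for _stop, sd, nd in paths]
        Sd += sum(p[0] for p in pool) / len(pool)
        Nd += sum(p[1] for p in pool) / len(pool)
    pS = Sd / S
    pN = Nd / N
    out = {"S": S, "N": N, "Sd": Sd, "Nd": Nd}
    if 1 - 4 * pS / 3 > 0 and 1 - 4 * pN / 3 > 0:
        out["Ks"] = -0.75 * math.log(1 - 4 * pS / 3)
        out["Ka"] = -0.75 * math.log(1 - 4 * pN / 3)
        out["status"] = "ok"
    else:
        out["status"] = "saturated"
    return out


def random_sense_cds(rng: np.random.Generator, n_codons: int) -> str:
    codons = []
    bases = "ACGT"
    while len(codons) < n_codons:
        c = "".join(bases[i] for i in rng.integers(0, 4, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def gotoh_score_oracle(
    a: str,
    b: str,
    matrix_name: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> float:
    """Quadratic-space affine-gap global alignment score with free end gaps.

    Gap scoring matches an open-and-extend convention where a length-L gap
    costs gap_open + (L-1)*gap_extend.
    """
    mat = substitution_matrices.load(matrix_name)
    n, m = len(a), len(b)
    NEG = -1e18
    # M: a[i] aligned to b[j]; X: gap in b (a consumed); Y: gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading end gap in b
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # free leading end gap in a
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + sub
            # internal gaps pay affine penalties
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
        # free trailing gap in b: allow X to stay at column m for free
    best = NEG
    # free trailing end gaps: the optimum may end anywhere on the last row or
    # column with the remainder gapped for free
    for i in range(n + 1):
        for state in (M, X, Y):
            best = max(best, state[i][m])
    for j in range(m + 1):
        for state in (M, X, Y):
            best = max(best, state[n][j])
    return best
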