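"""Independent brute-force oracles used by unit and acceptance tests.

Each oracle recomputes a quantity by a route deliberately different from
the library implementation: exhaustive scans, full enumeration, external
alignment (edlib), or direct term-by-term summation.
"""

from __future__ import annotations

import itertools
import math

import edlib

from lncproteo.folding import MIN_HAIRPIN, can_pair, structure_energy, _to_rna
from lncproteo.orfs import STOP_CODONS, translate
from lncproteo.peptides import EquivalenceTable


# ---------------------------------------------------------------------------
# ORF scan: test every position as a start

def brute_force_orfs(seq: str, min_protein_aa: int) -> set[tuple[int, int, int]]:
    """(frame, start, end) of qualifying ORFs, 5'-most AUG per (frame, stop).

    Every position is tested as a start; the first in-frame stop closes
    the ORF; among AUGs sharing a stop, only the smallest start survives.
    """
    hits: dict[tuple[int, int], int] = {}
    n = len(seq)
    for start in range(n - 2):
        if seq[start:start + 3] != "ATG":
            continue
        pos = start
        while pos + 3 <= n:
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                end = pos + 3
                protein_len = (end - start) // 3 - 1
                if protein_len >= min_protein_aa:
                    key = (start % 3, end)
                    if key not in hits or start < hits[key]:
                        hits[key] = start
                break
            pos += 3
    return {(frame, start, end) for (frame, end), start in hits.items()}


def codon_lookup_translate(seq: str) -> str:
    """Independent 3-frame codon translation via a literal 64-codon table."""
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    table = {a + b + c: aas[i * 16 + j * 4 + k]
             for i, a in enumerate(bases)
             for j, b in enumerate(bases)
             for k, c in enumerate(bases)}
    out = []
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else table[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# semi-global alignment distance: min over substrings of edlib NW distance

def brute_force_min_diffs(peptide: str, protein: str,
                          equivalences: EquivalenceTable) -> int:
    cp = equivalences.collapse(peptide)
    cq = equivalences.collapse(protein)
    best = len(cp)
    for i in range(len(cq)):
        for j in range(i + 1, len(cq) + 1):
            d = edlib.align(cp, cq[i:j], mode="NW", task="distance")["editDistance"]
            if d < best:
                best = d
                if best == 0:
                    return 0
    return best


# ---------------------------------------------------------------------------
# Fisher exact: full hypergeometric enumeration

def enumerate_fisher_p(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, c1 = a + b, a + c

    def pmf(x: int) -> float:
        return (math.comb(r1, x) * math.comb(n - r1, c1 - x)) / math.comb(n, c1)

    p_obs = pmf(a)
    total = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        p = pmf(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# KS two-sample: exhaustive permutation over pooled assignments

def ks_d(x: list[float], y: list[float]) -> float:
    values = sorted(set(x) | set(y))
    nx, ny = len(x), len(y)
    best = 0.0
    for v in values:
        fx = sum(1 for e in x if e <= v) / nx
        fy = sum(1 for e in y if e <= v) / ny
        best = max(best, abs(fx - fy))
    return best


def permutation_ks_p(x: list[float], y: list[float]) -> float:
    pooled = list(x) + list(y)
    nx = len(x)
    d_obs = ks_d(x, y)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        if ks_d(xs, ys) >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


# ---------------------------------------------------------------------------
# tryptic digestion: enumerate all substrings, check boundaries and interior

def brute_force_digest(protein: str, missed: int) -> set[str]:
    def is_site(i: int) -> bool:  # cleavage between i and i+1
        return protein[i] in "KR" and (i + 1 == len(protein) or protein[i + 1] != "P")

    n = len(protein)
    peptides = set()
    for i in range(n):
        for j in range(i + 1, n + 1):
            if i > 0 and not is_site(i - 1):
                continue
            if j < n and not is_site(j - 1):
                continue
            interior = sum(1 for k in range(i, j - 1) if is_site(k))
            if interior <= missed:
                peptides.add(protein[i:j])
    return peptides


# ---------------------------------------------------------------------------
# RNA folding: enumerate every nested structure

def enumerate_mfe(seq: str) -> float:
    seq = _to_rna(seq)
    n = len(seq)

    def gen(i: int, j: int):
        if i > j:
            yield []
            return
        yield from gen(i + 1, j)
        for k in range(i + MIN_HAIRPIN + 1, j + 1):
            if can_pair(seq[i], seq[k]):
                for inside in gen(i + 1, k - 1):
                    for outside in gen(k + 1, j):
                        yield [(i, k)] + inside + outside

    return min((structure_energy(seq, s) for s in gen(0, n - 1)), default=0.0)
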