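"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately re-derive each quantity by the most literal method
available (exhaustive enumeration, closed forms, rational arithmetic) and
share no code with the package implementations they check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

_CODON_TABLE = {}
_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    from Bio.Data.CodonTable import standard_dna_table
    if codon in _STOPS:
        return "*"
    return standard_dna_table.forward_table[codon]


def ng86_sites(codon: str) -> tuple[float, float]:
    """(syn, nonsyn) sites of a codon: per position the synonymous fraction
    over non-stop single-base changes; one site per position."""
    s = 0.0
    for p in range(3):
        syn = valid = 0
        for b in _BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if alt in _STOPS:
                continue
            valid += 1
            if _aa(alt) == _aa(codon):
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def ng86_pair_proportions(seq_a: str, seq_b: str) -> tuple[float, float]:
    """(pN, pS) for two aligned coding sequences by exhaustive pathway
    enumeration per codon (stop-avoiding paths, averaged)."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    S = N = 0.0
    Sd = Nd = 0.0
    for ci in range(len(seq_a) // 3):
        a = seq_a[3 * ci:3 * ci + 3]
        b = seq_b[3 * ci:3 * ci + 3]
        sa, na = ng86_sites(a)
        sb, nb = ng86_sites(b)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        diff = [p for p in range(3) if a[p] != b[p]]
        if not diff:
            continue
        paths = []
        for order in itertools.permutations(diff):
            cur = a
            sd = nd = 0
            blocked = False
            for p in order:
                nxt = cur[:p] + b[p] + cur[p + 1:]
                if nxt in _STOPS:
                    blocked = True
                    break
                if _aa(cur) == _aa(nxt):
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            if not blocked:
                paths.append((sd, nd))
        if not paths:
            for order in itertools.permutations(diff):
                cur = a
                sd = nd = 0
                for p in order:
                    nxt = cur[:p] + b[p] + cur[p + 1:]
                    if _aa(cur) == _aa(nxt):
                        sd += 1
                    else:
                        nd += 1
                    cur = nxt
                paths.append((sd, nd))
        Sd += sum(p[0] for p in paths) / len(paths)
        Nd += sum(p[1] for p in paths) / len(paths)
    return (Nd / N if N else 0.0), (Sd / S if S else 0.0)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher's exact p by full enumeration with exact rationals."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0

    def prob(k: int) -> Fraction:
        return (Fraction(math.comb(r1, k)) * math.comb(r2, c1 - k)
                / math.comb(n, c1))

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = prob(k)
        if pk <= p_obs:
            total += pk
    return float(total)


def tn93_distance(seq1: str, seq2: str) -> float:
    """Independent TN93 evaluation, written directly from the closed-form
    estimator with averaged pair frequencies."""
    pairs = [(x, y) for x, y in zip(seq1, seq2)
             if x in _BASES and y in _BASES]
    n = len(pairs)
    freq = {b: 0 for b in _BASES}
    P1 = P2 = Q = 0
    for x, y in pairs:
        freq[x] += 1
        freq[y] += 1
        if x != y:
            pair = {x, y}
            if pair == {"A", "G"}:
                P1 += 1
            elif pair == {"C", "T"}:
                P2 += 1
            else:
                Q += 1
    gA, gC, gG, gT = (freq[b] / (2 * n) for b in _BASES)
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = P1 / n, P2 / n, Q / n
    if P1 == P2 == Q == 0:
        return 0.0
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)
    term = 0.0
    if k1 > 0:
        term += -k1 * math.log(1 - P1 / k1 - Q / (2 * gR))
    if k2 > 0:
        term += -k2 * math.log(1 - P2 / k2 - Q / (2 * gY))
    term += -k3 * math.log(1 - Q / (2 * gR * gY))
    return term


def random_additive_matrix(rng, n_taxa: int):
    """A random additive distance matrix built from an explicit random
    binary tree, plus the tree's pairwise path lengths."""
    import numpy as np

    nodes = list(range(n_taxa))
    edges = {}
    next_id = n_taxa
    active = nodes[:]
    parent = {}
    while len(active) > 1:
        i = active.pop(int(rng.integers(0, len(active))))
        j = active.pop(int(rng.integers(0, len(active))))
        for child in (i, j):
            parent[child] = next_id
            edges[child] = float(rng.uniform(0.1, 2.0))
        active.append(next_id)
        next_id += 1

    def path_to_root(v):
        out = []
        while v in parent:
            out.append(v)
            v = parent[v]
        out.append(v)
        return out

    D = np.zeros((n_taxa, n_taxa))
    for a in range(n_taxa):
        for b in range(a + 1, n_taxa):
            pa = path_to_root(a)
            pb = path_to_root(b)
            common = set(pa) & set(pb)
            d = sum(edges[v] for v in pa if v not in common)
            d += sum(edges[v] for v in pb if v not in common)
            D[a, b] = D[b, a] = d
    return D
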