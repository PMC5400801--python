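"""Distance phylogenetics: TN93 distances, neighbor-joining, nonparametric
bootstrap, and domain-by-domain (segment) analyses.

The TN93 model distinguishes the two transition classes (purine A↔G,
pyrimidine C↔T) and transversions under unequal base frequencies estimated
from each pair; neighbor-joining is the canonical agglomeration with a
lowest-index tie-break, consistent on additive matrices.  Segment trees
split a fixed alignment at user-supplied breakpoints (exon/intron features
or explicit coordinates) and report how the nearest neighbor of designated
query taxa moves between segments — the readout used to spot interlocus
recombinants.  Distances use complete deletion within each segment; indel
columns are excluded from distances but reported as binary characters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from skbio import TreeNode

_BASES = "ACGT"
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


class SaturationError(ValueError):
    """The pair is too divergent for a finite TN93 distance."""


@dataclass
class DistanceMatrix:
    taxa: list[str]
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(m < 0) or np.any(np.isnan(m)):
            raise ValueError("distances must be finite and non-negative")
        self.matrix = m


def tamura_nei_distance(seq1: str, seq2: str) -> float:
    """TN93 maximum-likelihood distance for one aligned pair.

    Pairwise gap deletion; base frequencies estimated from the two
    sequences.  Saturated pairs (non-positive log argument) raise
    :class:`SaturationError` rather than returning NaN.
    """
    pairs = [(a, b) for a, b in zip(seq1.upper(), seq2.upper())
             if a in _BASES and b in _BASES]
    n = len(pairs)
    if n == 0:
        raise ValueError("no comparable ungapped sites")
    counts = {b: 0 for b in _BASES}
    p1 = p2 = q = 0
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
        if a != b:
            if a in _PURINES and b in _PURINES:
                p1 += 1
            elif a in _PYRIMIDINES and b in _PYRIMIDINES:
                p2 += 1
            else:
                q += 1
    tot = 2 * n
    gA, gC, gG, gT = (counts[b] / tot for b in _BASES)
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / n, p2 / n, q / n

    if P1 == P2 == Q == 0:
        return 0.0
    if gR == 0 or gY == 0:
        raise SaturationError("degenerate base composition")
    k1 = 2 * gA * gG / gR
    k2 = 2 * gC * gT / gY
    k3 = 2 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY)

    def safe_log(x: float) -> float:
        if x <= 0:
            raise SaturationError("substitution saturation: log of "
                                  f"non-positive argument {x:.4g}")
        return math.log(x)

    d = 0.0
    if k1 > 0:
        d += -k1 * safe_log(1 - P1 / k1 - Q / (2 * gR))
    elif P1 > 0:
        raise SaturationError("transitions observed with zero purine product")
    if k2 > 0:
        d += -k2 * safe_log(1 - P2 / k2 - Q / (2 * gY))
    elif P2 > 0:
        raise SaturationError("transitions observed with zero pyrimidine product")
    d += -k3 * safe_log(1 - Q / (2 * gR * gY))
    return d


def p_distance(seq1: str, seq2: str) -> float:
    pairs = [(a, b) for a, b in zip(seq1.upper(), seq2.upper())
             if a in _BASES and b in _BASES]
    if not pairs:
        raise ValueError("no comparable ungapped sites")
    return sum(a != b for a, b in pairs) / len(pairs)


def alignment_distance_matrix(alignment: Sequence[tuple[str, str]],
                              fallback_to_p: bool = True) -> DistanceMatrix:
    """Pairwise TN93 matrix; saturated pairs fall back to the p-distance
    when allowed (used inside bootstrap replicates) and raise otherwise."""
    taxa = [t for t, _ in alignment]
    n = len(taxa)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = tamura_nei_distance(alignment[i][1], alignment[j][1])
            except SaturationError:
                if not fallback_to_p:
                    raise
                d = p_distance(alignment[i][1], alignment[j][1])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(taxa, m)


def build_nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor-joining with a lowest-index pair tie-break.

    On additive matrices the output tree's patristic metric equals the
    input.  The tree is returned rooted at the final join for convenience;
    it represents an unrooted topology.
    """
    n = len(dm.taxa)
    if n < 2:
        raise ValueError("need at least two taxa")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in dm.taxa]
    D = dm.matrix.copy()
    active = list(range(n))

    while len(active) > 2:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best: Optional[tuple[float, int, int]] = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                qij = (m - 2) * D[i, j] - r[i] - r[j]
                if best is None or qij < best[0] - 1e-12:
                    best = (qij, i, j)
        _, i, j = best
        li = D[i, j] / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        newD = np.zeros((D.shape[0] + 1, D.shape[0] + 1))
        newD[:D.shape[0], :D.shape[0]] = D
        u = D.shape[0]
        for k in active:
            if k in (i, j):
                continue
            duk = (D[i, k] + D[j, k] - D[i, j]) / 2
            newD[u, k] = newD[k, u] = duk
        D = newD
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j = active
    root = TreeNode()
    nodes[i].length = D[i, j] / 2
    nodes[j].length = D[i, j] / 2
    root.extend([nodes[i], nodes[j]])
    return root


def tree_splits(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial bipartitions of an unrooted tree, each canonicalised as
    the side not containing the lexicographically first taxon."""
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if anchor in side:
            side = frozenset(tips) - side
        if 2 <= len(side) <= len(tips) - 2:
            splits.add(side)
    return splits


@dataclass
class BootstrapResult:
    tree: TreeNode
    support: dict[frozenset[str], float]
    n_reps: int


def bootstrap_support(alignment: Sequence[tuple[str, str]],
                      n_reps: int = 500, seed: int = 0) -> BootstrapResult:
    """Nonparametric bootstrap: resample alignment columns with replacement,
    rebuild the NJ tree per replicate, and report the percentage of
    replicates containing each split of the full-data tree."""
    L = len(alignment[0][1])
    if L < 2:
        raise ValueError("alignment shorter than two columns")
    rng = np.random.default_rng(seed)
    full_dm = alignment_distance_matrix(alignment)
    full_tree = build_nj_tree(full_dm)
    targets = tree_splits(full_tree)
    hits = {s: 0 for s in targets}
    for _ in range(n_reps):
        cols = rng.integers(0, L, size=L)
        resampled = [(t, "".join(s[c] for c in cols)) for t, s in alignment]
        rep_tree = build_nj_tree(alignment_distance_matrix(resampled))
        rep_splits = tree_splits(rep_tree)
        for s in targets:
            if s in rep_splits:
                hits[s] += 1
    support = {s: 100.0 * h / n_reps for s, h in hits.items()}
    _annotate_support(full_tree, support)
    return BootstrapResult(tree=full_tree, support=support, n_reps=n_reps)


def _annotate_support(tree: TreeNode, support: dict[frozenset[str], float]):
    tips = sorted(t.name for t in tree.tips())
    anchor = tips[0]
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = frozenset(tips) - side if anchor in side else side
        if key in support:
            node.name = str(int(round(support[key])))


@dataclass
class SegmentSet:
    """Named, non-overlapping segments tiling an alignment."""

    segments: list[tuple[str, int, int]]
    alignment_length: Optional[int] = None

    def __post_init__(self):
        segs = sorted(self.segments, key=lambda s: s[1])
        pos = segs[0][1]
        for name, start, end in segs:
            if start != pos or end <= start:
                raise ValueError("segments must tile the alignment without "
                                 f"overlap; offending segment {name!r}")
            pos = end
        if self.alignment_length is not None and pos != self.alignment_length:
            raise ValueError("segments do not cover the alignment")
        self.segments = segs

    @classmethod
    def from_tsv(cls, path, alignment_length: Optional[int] = None):
        segs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, start, end = line.rstrip("\n").split("\t")
                segs.append((name, int(start), int(end)))
        return cls(segs, alignment_length)


@dataclass
class SegmentReport:
    segment: str
    tree: TreeNode
    support: dict[frozenset[str], float]
    nearest: dict[str, tuple[str, float]] = field(default_factory=dict)
    no_variation: bool = False
    indel_presence: dict[str, str] = field(default_factory=dict)


def _complete_deletion(alignment, start, end):
    sub = [(t, s[start:end]) for t, s in alignment]
    L = end - start
    keep = [c for c in range(L)
            if all(s[c] in _BASES for _, s in sub)]
    return [(t, "".join(s[c] for c in keep)) for t, s in sub], L - len(keep)


def _indel_characters(alignment, start, end) -> dict[str, str]:
    """Per-taxon presence (1) / absence (0) string over the segment's
    indel columns (columns where some but not all taxa have a base)."""
    sub = [(t, s[start:end]) for t, s in alignment]
    L = end - start
    cols = [c for c in range(L)
            if any(s[c] not in _BASES for _, s in sub)
            and any(s[c] in _BASES for _, s in sub)]
    return {t: "".join("1" if s[c] in _BASES else "0" for c in cols)
            for t, s in sub}


def segment_trees(alignment: Sequence[tuple[str, str]],
                  segments: SegmentSet,
                  query_taxa: Sequence[str] = (),
                  n_reps: int = 100,
                  seed: int = 0) -> list[SegmentReport]:
    """One NJ+bootstrap tree per segment, with a nearest-neighbor report
    for the query taxa (the recombination-mosaic readout)."""
    reports = []
    for k, (name, start, end) in enumerate(segments.segments):
        sub, _ = _complete_deletion(alignment, start, end)
        n_var = sum(1 for c in range(len(sub[0][1]))
                    if len({s[c] for _, s in sub}) > 1)
        if n_var == 0:
            dm = DistanceMatrix([t for t, _ in sub],
                                np.zeros((len(sub), len(sub))))
            tree = build_nj_tree(dm)
            rep = SegmentReport(segment=name, tree=tree, support={},
                                no_variation=True)
        else:
            boot = bootstrap_support(sub, n_reps=n_reps, seed=seed + k)
            rep = SegmentReport(segment=name, tree=boot.tree,
                                support=boot.support)
        rep.indel_presence = _indel_characters(alignment, start, end)
        dm = alignment_distance_matrix(sub)
        for qt in query_taxa:
            qi = dm.taxa.index(qt)
            dists = [(dm.matrix[qi, j], dm.taxa[j])
                     for j in range(len(dm.taxa)) if j != qi]
            d, nb = min(dists)
            rep.nearest[qt] = (nb, d)
        reports.append(rep)
    return reports
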