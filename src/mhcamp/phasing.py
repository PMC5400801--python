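"""Long-amplicon phasing: cluster subreads into allele haplotypes, polish a
consensus per cluster and scan pileups for sub-consensus minor variants.

The clustering procedure is a greedy discriminating-column splitter: build a
draft consensus, project every read onto it (banded global alignment via
edlib), find columns where a second base exceeds a frequency threshold at
sufficient depth, split the reads on the best such column, and recurse until
no column splits or the per-amplicon haplotype budget ``k_max`` is
exhausted.  Columns adjacent to homopolymer runs are excluded from the
split-column search because long-read indel noise concentrates there; the
polishing step is a per-column majority vote with a likelihood-based
predicted accuracy under a symmetric substitution error model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from collections import Counter
from typing import Optional, Sequence

import edlib
import numpy as np

from .simulate import homopolymer_mask

GAP = 4          # projected gap (deletion in the read)
NOCOV = 5        # outside the read's aligned span (truncation)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASES = np.frombuffer(b"ACGT-", dtype=np.uint8)

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class ConsensusCall:
    """One phased haplotype consensus."""

    sequence: str
    cluster_size: int
    polish_coverage: int
    predicted_accuracy: float
    amplicon: str = ""
    replicate: int = 0
    n_tie_columns: int = 0

    @property
    def header(self) -> str:
        return (f"{self.amplicon}|rep{self.replicate}|size{self.cluster_size}"
                f"|cov{self.polish_coverage}|acc{self.predicted_accuracy:.5f}")


@dataclass
class PhasingResult:
    calls: list[ConsensusCall] = field(default_factory=list)
    clusters: list[list[int]] = field(default_factory=list)
    low_coverage: bool = False
    n_reads: int = 0


@dataclass
class MinorVariantResult:
    """Per-position minor variant calls: (position, [(base, freq, depth)])."""

    positions: list[tuple[int, list[tuple[str, float, int]]]] = field(
        default_factory=list)

    def __len__(self) -> int:
        return len(self.positions)


def _project(read: str, ref: str) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Project a read onto reference columns.

    Returns a length-``len(ref)`` code array (0-3 base, 4 deletion gap,
    5 no coverage at truncated ends) and the list of insertions as
    (reference position, inserted string).
    """
    aln = edlib.align(read, ref, task="path", mode="NW")
    col = np.full(len(ref), GAP, dtype=np.uint8)
    ins: list[tuple[int, str]] = []
    q = 0
    t = 0
    for n, op in _CIGAR_RE.findall(aln["cigar"]):
        n = int(n)
        if op in "=XM":
            col[t:t + n] = _CODE[np.frombuffer(read[q:q + n].encode(),
                                               dtype=np.uint8)]
            q += n
            t += n
        elif op == "D":       # reference bases absent from the read
            t += n
        elif op == "I":       # read bases absent from the reference
            ins.append((t, read[q:q + n]))
            q += n
    # mark terminal gap runs as no-coverage (read truncation, not deletion)
    nz = np.flatnonzero(col != GAP)
    if nz.size:
        col[:nz[0]] = NOCOV
        col[nz[-1] + 1:] = NOCOV
    else:
        col[:] = NOCOV
    return col, ins


def _build_matrix(reads: Sequence[str], ref: str):
    M = np.empty((len(reads), len(ref)), dtype=np.uint8)
    ins_counter: Counter = Counter()
    for i, r in enumerate(reads):
        col, ins = _project(r, ref)
        M[i] = col
        for pos, s in ins:
            ins_counter[(pos, s)] += 1
    return M, ins_counter


def _column_counts(M: np.ndarray) -> np.ndarray:
    """(6, L) counts of codes per column."""
    counts = np.empty((6, M.shape[1]), dtype=np.int64)
    for b in range(6):
        counts[b] = (M == b).sum(axis=0)
    return counts


def _consensus_from_matrix(M: np.ndarray, ins_counter: Counter,
                           error_rate: float = 0.05):
    """Majority consensus with insertion handling and predicted accuracy."""
    n = M.shape[0]
    counts = _column_counts(M)
    base_counts = counts[:4]
    called = base_counts.argmax(axis=0)          # lexicographic tie-break
    top = base_counts.max(axis=0)
    # a column is real sequence unless deletion outnumbers covering bases;
    # columns where most reads end beforehand (terminal draft artifacts
    # from a seed read's trailing insertion) are dropped likewise
    covered = counts[:5].sum(axis=0)
    keep = counts[GAP] <= top
    keep &= top > counts[NOCOV]
    keep &= covered > 0

    sorted_counts = np.sort(base_counts, axis=0)
    ties = int(((sorted_counts[-1] == sorted_counts[-2]) & keep
                & (sorted_counts[-1] > 0)).sum())

    # posterior of the called base under a symmetric substitution model
    with np.errstate(divide="ignore", invalid="ignore"):
        depth = base_counts.sum(axis=0)
        ll = (base_counts * np.log(1 - error_rate)
              + (depth - base_counts) * np.log(error_rate / 3.0))
        ll -= ll.max(axis=0, keepdims=True)
        post = np.exp(ll)
        post /= post.sum(axis=0)
    col_post = post[called, np.arange(M.shape[1])]
    # a non-unanimous column can never claim certainty, even when the
    # posterior rounds to 1.0 in floating point
    unanimous = top == depth
    col_post = np.where(unanimous, col_post,
                        np.minimum(col_post, 1.0 - 1e-9))
    acc_cols = col_post[keep & (depth > 0)]
    accuracy = float(acc_cols.mean()) if acc_cols.size else 0.0

    # majority insertions
    ins_by_pos: dict[int, Counter] = {}
    for (pos, s), c in ins_counter.items():
        ins_by_pos.setdefault(pos, Counter())[s] = c
    pieces: list[str] = []
    L = M.shape[1]
    for t in range(L + 1):
        if t in ins_by_pos:
            s, c = ins_by_pos[t].most_common(1)[0]
            total = sum(ins_by_pos[t].values())
            if total > n / 2:
                pieces.append(s)
        if t < L and keep[t]:
            pieces.append("ACGT"[called[t]])
    return "".join(pieces), accuracy, ties


def _draft_consensus(reads: Sequence[str], n_iter: int = 2) -> str:
    """Iterated majority consensus seeded from the median-length read."""
    order = sorted(range(len(reads)), key=lambda i: (len(reads[i]), reads[i]))
    ref = reads[order[len(order) // 2]]
    for _ in range(n_iter):
        M, ins = _build_matrix(reads, ref)
        ref, _, _ = _consensus_from_matrix(M, ins)
    return ref


def _discriminating_columns(M: np.ndarray, ref: str, split_frac: float,
                            min_depth: int, min_minor: int,
                            hp_run: int) -> list[tuple[int, int]]:
    """Columns whose second most frequent base marks a haplotype split.

    Returns (minor count, column) candidates sorted best-first.  Gap codes
    are ignored (indel noise); columns inside or flanking homopolymer runs
    of length >= hp_run are excluded.
    """
    counts = _column_counts(M)[:4]
    depth = counts.sum(axis=0)
    n_reads = M.shape[0]
    depth_req = min(min_depth, max(2, int(0.8 * n_reads)))
    srt = np.sort(counts, axis=0)
    minor = srt[-2]
    with np.errstate(divide="ignore", invalid="ignore"):
        minor_frac = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    hp = homopolymer_mask(ref, hp_run)
    hp = hp | np.roll(hp, 1) | np.roll(hp, -1)
    ok = (depth >= depth_req) & (minor >= min_minor) & \
         (minor_frac >= split_frac) & ~hp
    cols = np.flatnonzero(ok)
    return sorted(((int(minor[c]), int(c)) for c in cols), reverse=True)


class LowCoverageError(RuntimeError):
    """Too few subreads to phase; the sample should be re-amplified."""


def cluster_subreads(
    reads: Sequence[tuple[str, str]] | Sequence[str],
    k_max: int = 4,
    min_cluster_frac: float = 0.1,
    seed: int = 0,
    min_reads: int = 25,
    split_frac: float = 0.2,
    min_depth: int = 50,
    min_minor: int = 5,
    hp_run: int = 4,
) -> PhasingResult:
    """Greedy discriminating-column clustering of one replicate's subreads.

    Reads may be (id, sequence) pairs or raw strings.  Returns clusters of
    read indices; clusters smaller than ``min_cluster_frac`` of all reads
    are discarded as noise.  Deterministic for fixed inputs and seed.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    n = len(seqs)
    if n < min_reads:
        return PhasingResult(low_coverage=True, n_reads=n)

    def prepare(idx: list[int]) -> dict:
        sub = [seqs[i] for i in idx]
        draft = _draft_consensus(sub)
        M, _ = _build_matrix(sub, draft)
        cand = _discriminating_columns(M, draft, split_frac, min_depth,
                                       min_minor, hp_run)
        return {"idx": idx, "M": M, "cand": cand}

    clusters: list[dict] = [prepare(list(range(n)))]
    while len(clusters) < k_max:
        best: Optional[tuple[int, int, int]] = None  # (minor count, cluster, col)
        for ci, cl in enumerate(clusters):
            if cl["cand"]:
                score, col = cl["cand"][0]
                if best is None or score > best[0]:
                    best = (score, ci, col)
        if best is None:
            break
        _, ci, col = best
        cl = clusters[ci]
        column = cl["M"][:, col]
        counts = np.bincount(column[column < 4], minlength=4)
        depth = counts.sum()
        qual = [b for b in np.argsort(-counts)
                if counts[b] >= min_minor and counts[b] / depth >= split_frac]
        budget = k_max - len(clusters) + 1
        qual = qual[:budget]
        if len(qual) < 2:
            break
        groups: dict[int, list[int]] = {int(b): [] for b in qual}
        largest = int(qual[0])
        for local_i, read_i in enumerate(cl["idx"]):
            b = int(column[local_i])
            groups.get(b, groups[largest]).append(read_i)
        clusters[ci:ci + 1] = [prepare(g) for g in groups.values() if g]

    total = n
    kept = [c["idx"] for c in clusters if len(c["idx"]) >= min_cluster_frac * total]
    if not kept:
        kept = [max((c["idx"] for c in clusters), key=len)]
    kept.sort(key=lambda c: (-len(c), c[0]))
    return PhasingResult(clusters=kept, n_reads=n)


def polish_consensus(
    reads: Sequence[tuple[str, str]] | Sequence[str],
    cap: int = 500,
    seed: int = 0,
    error_rate: float = 0.05,
    amplicon: str = "",
    replicate: int = 0,
) -> ConsensusCall:
    """Majority-polish one cluster with coverage capped at ``cap``.

    Predicted accuracy is the mean per-column posterior of the called base
    under a symmetric error model; it reaches 1.0 only when every polished
    column is unanimous.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    if not seqs:
        raise ValueError("empty cluster")
    cluster_size = len(seqs)
    if cluster_size > cap:
        rng = np.random.default_rng(seed)
        pick = sorted(rng.choice(cluster_size, size=cap, replace=False))
        seqs = [seqs[i] for i in pick]
    draft = _draft_consensus(seqs)
    M, ins = _build_matrix(seqs, draft)
    seq, acc, ties = _consensus_from_matrix(M, ins, error_rate)
    return ConsensusCall(sequence=seq, cluster_size=cluster_size,
                         polish_coverage=len(seqs), predicted_accuracy=acc,
                         amplicon=amplicon, replicate=replicate,
                         n_tie_columns=ties)


def phase_replicate(
    reads: Sequence[tuple[str, str]],
    k_max: int = 4,
    amplicon: str = "",
    replicate: int = 0,
    cap: int = 500,
    seed: int = 0,
    reassign: bool = True,
    **cluster_kw,
) -> PhasingResult:
    """Cluster + polish one (sample, amplicon, replicate) read set.

    With ``reassign`` (default) a final pass re-assigns every read to its
    closest polished consensus by edit distance and re-polishes, which
    cleans up reads mis-split by single-column signatures.
    """
    res = cluster_subreads(reads, k_max=k_max, seed=seed, **cluster_kw)
    if res.low_coverage:
        return res
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    calls = [polish_consensus([seqs[i] for i in c], cap=cap, seed=seed + 1 + j,
                              amplicon=amplicon, replicate=replicate)
             for j, c in enumerate(res.clusters)]
    if reassign and len(calls) > 1:
        assign: list[list[int]] = [[] for _ in calls]
        for i, s in enumerate(seqs):
            dists = [edlib.align(s, c.sequence, mode="NW")["editDistance"]
                     for c in calls]
            assign[int(np.argmin(dists))].append(i)
        min_frac = cluster_kw.get("min_cluster_frac", 0.1)
        kept = [c for c in assign if len(c) >= min_frac * len(seqs)]
        if kept:
            kept.sort(key=lambda c: (-len(c), c[0]))
            calls = [polish_consensus([seqs[i] for i in c], cap=cap,
                                      seed=seed + 100 + j, amplicon=amplicon,
                                      replicate=replicate)
                     for j, c in enumerate(kept)]
            res = PhasingResult(clusters=kept, n_reads=len(seqs))
    res.calls = calls
    return res


def minor_variant_scan(
    reads: Sequence[tuple[str, str]] | Sequence[str],
    reference: str,
    min_freq: float = 0.2,
    min_depth: int = 50,
    length_tolerance: int = 100,
) -> MinorVariantResult:
    """Reference-based pileup scan for minor variants.

    Reports positions where at least two variant classes (the four bases
    plus deletion) each exceed ``min_freq`` at depth >= ``min_depth``.
    Frequencies at a position are fractions of the covering reads, so the
    reported variants plus the remainder class sum to one.
    """
    seqs = [r[1] if isinstance(r, tuple) else r for r in reads]
    if max(len(s) for s in seqs) > len(reference) + length_tolerance:
        raise ValueError("reads exceed the reference length beyond tolerance")
    M, _ = _build_matrix(seqs, reference)
    counts = _column_counts(M)
    depth = counts[:5].sum(axis=0)
    result = MinorVariantResult()
    for t in range(len(reference)):
        d = int(depth[t])
        if d < min_depth:
            continue
        variants = [("ACGT-"[b], counts[b, t] / d, int(counts[b, t]))
                    for b in range(5)
                    if counts[b, t] / d >= min_freq and counts[b, t] > 0]
        if len(variants) >= 2:
            variants.sort(key=lambda v: -v[2])
            result.positions.append((t, variants))
    return result
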