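"""Interspecies diversity statistics on coding-sequence sets.

Implements the comparative measures used for class I loci: pairwise
nucleotide difference distributions, nucleotide diversity π (unweighted
mean pairwise p-distance with pairwise gap deletion), variable-site counts
over the full CDS or an antigen-binding-site (ABS) codon mask, Nei–Gojobori
synonymous/nonsynonymous rates on the ABS codons with Jukes–Cantor
correction, Fisher's exact test of equal synonymous and nonsynonymous
rates, and KIR-ligand epitope classification from mature residues 76–83
(Bw4: R83 on MHC-B; C1: V76+N80 on MHC-B or N80 on MHC-C; C2: K80 on
MHC-C).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

from .alleles import DEFAULT_SIGNAL_PEPTIDE, translate_cds

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"


def _seqs(cds_set: Sequence) -> list[str]:
    out = [s[1] if isinstance(s, tuple) else s for s in cds_set]
    if len({len(s) for s in out}) > 1:
        raise ValueError("sequences must be aligned to equal length "
                         "(near-identical CDS sets align trivially; pad "
                         "divergent sets upstream)")
    return [s.upper() for s in out]


def _pair_diff(a: str, b: str) -> tuple[int, int]:
    """(differences, compared sites) under pairwise gap deletion."""
    d = n = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            n += 1
            if x != y:
                d += 1
    return d, n


def pairwise_differences(cds_set: Sequence) -> tuple[list[int], float]:
    """All n(n-1)/2 unordered pairwise difference counts and their mean."""
    seqs = _seqs(cds_set)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    counts = [_pair_diff(a, b)[0]
              for a, b in itertools.combinations(seqs, 2)]
    return counts, round(sum(counts) / len(counts), 1)


def nucleotide_diversity(cds_set: Sequence) -> float:
    """π: unweighted mean pairwise p-distance (alleles equally weighted)."""
    seqs = _seqs(cds_set)
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    dists = []
    for a, b in itertools.combinations(seqs, 2):
        d, n = _pair_diff(a, b)
        if n == 0:
            raise ValueError("a pair shares no ungapped sites")
        dists.append(d / n)
    return sum(dists) / len(dists)


@dataclass(frozen=True)
class AbsMask:
    """Antigen-binding-site codon indices in mature-protein numbering."""

    codons: frozenset[int]
    signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE

    def __post_init__(self):
        if not self.codons:
            raise ValueError("empty ABS mask")
        if min(self.codons) < 1:
            raise ValueError("mask codons are 1-based")

    @classmethod
    def from_codons(cls, codons: Iterable[int],
                    signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE) -> "AbsMask":
        return cls(frozenset(int(c) for c in codons), signal_peptide)

    @classmethod
    def load(cls, path, signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE) -> "AbsMask":
        """One codon index per line; ``#`` comments allowed."""
        with open(path) as fh:
            codons = [int(line) for line in fh
                      if line.strip() and not line.lstrip().startswith("#")]
        return cls.from_codons(codons, signal_peptide)

    @classmethod
    def default(cls, signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE) -> "AbsMask":
        """The editable default mask shipped with the package (classical
        peptide-binding-groove residues); prefer an explicit list for
        published analyses since ABS definitions vary between studies."""
        from importlib import resources
        with resources.files("mhcamp.data").joinpath(
                "abs_codons_default.txt").open() as fh:
            codons = [int(line) for line in fh
                      if line.strip() and not line.lstrip().startswith("#")]
        return cls.from_codons(codons, signal_peptide)

    def cds_codon_indices(self) -> list[int]:
        """0-based CDS codon indices covered by the mask."""
        return sorted(c + self.signal_peptide - 1 for c in self.codons)

    def site_columns(self) -> list[int]:
        return [3 * c + k for c in self.cds_codon_indices() for k in range(3)]


def count_variable_sites(cds_set: Sequence,
                         mask: Optional[AbsMask] = None) -> int:
    """Columns with >= 2 observed bases; gap-containing columns excluded."""
    seqs = _seqs(cds_set)
    cols = (mask.site_columns() if mask is not None
            else range(len(seqs[0])))
    n_var = 0
    for c in cols:
        obs = {s[c] for s in seqs}
        if obs <= set(_BASES) and len(obs) >= 2:
            n_var += 1
    return n_var


# ---------------------------------------------------------------------------
# Nei–Gojobori


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site fractions of one codon.

    Per position, the synonymous fraction is computed over the non-stop
    single-base changes; each position contributes one site in total, so a
    codon always contributes exactly three sites.
    """
    aa, _ = translate_cds(codon)
    s = 0.0
    for p in range(3):
        syn = 0
        valid = 0
        for b in _BASES:
            if b == codon[p]:
                continue
            alt = codon[:p] + b + codon[p + 1:]
            if alt in _STOPS:
                continue
            valid += 1
            if translate_cds(alt)[0] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def _codon_pair_diffs(a: str, b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons by
    averaging over all mutational pathways that avoid stop codons."""
    diff_pos = [p for p in range(3) if a[p] != b[p]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        cur = a
        sd = nd = 0
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if nxt in _STOPS:
                return None
            if translate_cds(cur)[0] == translate_cds(nxt)[0]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [w for w in (walk(o) for o in
                         itertools.permutations(diff_pos)) if w is not None]
    if not paths:  # all paths blocked by stops: fall back to including them
        paths = []
        for o in itertools.permutations(diff_pos):
            cur = a
            sd = nd = 0
            for p in o:
                nxt = cur[:p] + b[p] + cur[p + 1:]
                if translate_cds(cur)[0] == translate_cds(nxt)[0]:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            paths.append((sd, nd))
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    """Jukes–Cantor-corrected rate; saturated proportions (p >= 3/4, only
    reachable for essentially unrelated sequences) give infinity."""
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]          # None encodes Ks = 0 (undefined ratio)
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float

    @property
    def ratio_is_infinite(self) -> bool:
        return self.ratio is None and self.ka > 0


def nei_gojobori_ka_ks(cds_set: Sequence, mask: AbsMask) -> KaKsResult:
    """Mean pairwise Nei–Gojobori Ka and Ks restricted to the mask codons.

    Pathway counting with stop-avoiding averaging per codon pair;
    Jukes–Cantor-corrected rates are means over all unordered pairs, with
    the uncorrected proportions also reported.  A stop codon inside the
    mask in any sequence is an error.
    """
    seqs = _seqs(cds_set)
    idx = mask.cds_codon_indices()
    for s in seqs:
        if len(s) % 3:
            raise ValueError("CDS length must be a multiple of 3")
        if idx[-1] * 3 + 3 > len(s):
            raise ValueError("mask extends beyond the CDS")
        for ci in idx:
            codon = s[3 * ci:3 * ci + 3]
            if codon in _STOPS:
                raise ValueError(f"stop codon inside the mask at codon {ci}")
            if any(b not in _BASES for b in codon):
                raise ValueError("mask codons must be ungapped across the set")

    per_seq_sites = []
    for s in seqs:
        ssum = nsum = 0.0
        for ci in idx:
            sy, ns = _codon_sites(s[3 * ci:3 * ci + 3])
            ssum += sy
            nsum += ns
        per_seq_sites.append((ssum, nsum))

    pn_list, ps_list, dn_list, ds_list = [], [], [], []
    nd_list, sd_list, n_list, s_list = [], [], [], []
    for (i, a), (j, b) in itertools.combinations(enumerate(seqs), 2):
        sd = nd = 0.0
        for ci in idx:
            s_d, n_d = _codon_pair_diffs(a[3 * ci:3 * ci + 3],
                                         b[3 * ci:3 * ci + 3])
            sd += s_d
            nd += n_d
        S = (per_seq_sites[i][0] + per_seq_sites[j][0]) / 2.0
        N = (per_seq_sites[i][1] + per_seq_sites[j][1]) / 2.0
        pn = nd / N if N else 0.0
        ps = sd / S if S else 0.0
        pn_list.append(pn)
        ps_list.append(ps)
        dn_list.append(_jukes_cantor(pn))
        ds_list.append(_jukes_cantor(ps))
        nd_list.append(nd)
        sd_list.append(sd)
        n_list.append(N)
        s_list.append(S)

    m = len(pn_list)
    ka = sum(dn_list) / m
    ks = sum(ds_list) / m
    ratio = (ka / ks if ks > 0 and math.isfinite(ka) and math.isfinite(ks)
             else None)
    return KaKsResult(ka=ka, ks=ks, ratio=ratio,
                      pn=sum(pn_list) / m, ps=sum(ps_list) / m,
                      n_sites=sum(n_list) / m, s_sites=sum(s_list) / m,
                      nd=sum(nd_list) / m, sd=sum(sd_list) / m)


# ---------------------------------------------------------------------------
# Fisher's exact test (exact integer hypergeometric enumeration)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def fisher_exact_table(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table.

    Sums the hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's; the
    comparison is exact (integer arithmetic), so ties are always included.
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    r1, r2, c1 = a + b, c + d, a + c
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    num_obs = math.comb(r1, a) * math.comb(r2, c1 - a)
    total = math.comb(r1 + r2, c1)
    acc = 0
    for k in range(lo, hi + 1):
        num = math.comb(r1, k) * math.comb(r2, c1 - k)
        if num <= num_obs:
            acc += num
    return acc / total


def fisher_exact(ka_count: int, ks_count: int, n_sites: float,
                 s_sites: float) -> float:
    """Test of equal synonymous/nonsynonymous rates: differences vs
    (half-up rounded) site totals within the mask."""
    n = _round_half_up(n_sites)
    s = _round_half_up(s_sites)
    if ka_count > n or ks_count > s:
        raise ValueError("more differences than sites")
    return fisher_exact_table([[ka_count, n - ka_count],
                               [ks_count, s - ks_count]])


# ---------------------------------------------------------------------------
# KIR epitopes


@dataclass(frozen=True)
class EpitopeCall:
    allotype: str
    epitope: str                   # Bw4 | C1 | C2 | none
    residues_76_83: str


def call_kir_epitope(protein: str, locus_kind: str, allotype: str = "",
                     signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE) -> EpitopeCall:
    """Classify a class I allotype's KIR-binding epitope from mature
    residues 76–83.

    MHC-B: R83 → Bw4; else V76 and N80 → C1; else none.
    MHC-C: N80 → C1; K80 → C2; else none.
    Null allotypes (stop before residue 83) are not classified.
    """
    if locus_kind not in ("B", "C"):
        raise ValueError("locus_kind must be 'B' or 'C'")
    mature = protein[signal_peptide:]
    if len(mature) < 83 or "*" in mature[:83]:
        raise ValueError("protein truncated before residue 83; "
                         "null allotypes are not classified")
    window = mature[75:83]
    r76, r80, r83 = mature[75], mature[79], mature[82]
    if locus_kind == "B":
        if r83 == "R":
            epi = "Bw4"
        elif r76 == "V" and r80 == "N":
            epi = "C1"
        else:
            epi = "none"
    else:
        epi = {"N": "C1", "K": "C2"}.get(r80, "none")
    return EpitopeCall(allotype=allotype, epitope=epi, residues_76_83=window)


# ---------------------------------------------------------------------------
# cohort summaries


def carrier_frequency(genotype_table, predicate: Callable[[str], bool]
                      ) -> tuple[int, float]:
    """Distinct individuals carrying >= 1 allele satisfying *predicate*.

    ``genotype_table`` maps sample -> iterable of allele identifiers (or is
    a GenotypeTable with a ``by_sample`` view).  Returns the carrier count
    and the percent of the cohort to one decimal.
    """
    table = getattr(genotype_table, "by_sample", genotype_table)
    if not table:
        raise ValueError("empty cohort")
    carriers = sum(
        1 for _, alleles in sorted(table.items())
        if any(predicate(a) for a in alleles))
    return carriers, round(100.0 * carriers / len(table), 1)


@dataclass
class DiversitySummary:
    locus: str
    n_alleles: int
    pairwise: list[int] = field(default_factory=list)
    mean_pairwise: float = 0.0
    pi: float = 0.0
    variable_sites_cds: int = 0
    variable_sites_abs: int = 0
    kaks: Optional[KaKsResult] = None
    fisher_p: Optional[float] = None


def locus_diversity(cds_set: Sequence, mask: AbsMask,
                    locus: str = "") -> DiversitySummary:
    """Full per-locus summary row: π, variable sites, ABS Ka/Ks, Fisher p."""
    counts, mean = pairwise_differences(cds_set)
    kaks = nei_gojobori_ka_ks(cds_set, mask)
    p = fisher_exact(_round_half_up(kaks.nd), _round_half_up(kaks.sd),
                     kaks.n_sites, kaks.s_sites)
    return DiversitySummary(
        locus=locus, n_alleles=len(cds_set), pairwise=counts,
        mean_pairwise=mean, pi=nucleotide_diversity(cds_set),
        variable_sites_cds=count_variable_sites(cds_set),
        variable_sites_abs=count_variable_sites(cds_set, mask),
        kaks=kaks, fisher_p=p)
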