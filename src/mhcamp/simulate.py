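"""Synthetic study generator: allele database, cohort and noisy subreads.

The generator emulates a hominid MHC class I region at desk scale:

* three amplicon groups — the A region (where a haplotype carries either the
  classical *A* gene, optionally together with a *Y*-like pseudogene, or the
  *Oko* gene on the alternative haplotype that lacks the *A* block), the B
  region (every haplotype carries a *B* gene; some additionally carry a
  divergent second *B* locus, named in the ``B*07`` group), and the C region
  (exactly one gene on every haplotype);
* an allele database per locus containing, by construction, an intron-only
  variant pair, a synonymous-only pair, a nonsynonymous pair and (A locus)
  a null allele whose nonsense codon sits at mature-protein position 257
  inside exon 4;
* diploid genotypes with pedigree structure (trios and father-offspring
  dyads) and a truth table down to the single read;
* duplicate amplification per sample and amplicon with stochastic coverage
  and a long-read error model whose indel rate is inflated inside
  homopolymer runs (insertions duplicate the local base, deletions remove
  it, which is how homopolymer length errors present in real long reads).

Every stochastic draw flows from one ``numpy`` generator seeded once, so a
run is fully replayable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import numpy as np

from .alleles import AlleleName, AlleleRecord, Feature, FeatureMap
from . import io as mio

# canonical class I gene architecture: 8 exons, CDS 1098 bp = 366 codons
EXON_LENGTHS = (73, 270, 276, 276, 117, 33, 48, 5)
INTRON_LENGTHS = (120, 110, 130, 100, 90, 80, 70)
UTR5_LEN = 60
UTR3_LEN = 120

#: mature-protein codon of the engineered nonsense mutation (class I
#: convention: 24-residue signal peptide, so CDS codon 281, inside exon 4)
NULL_STOP_MATURE_CODON = 257
SIGNAL_PEPTIDE = 24

REGION_OF_GENE = {"A": "A", "Oko": "A", "Y": "A", "B": "B", "B07": "B", "C": "C"}
LOCUS_LABEL = {"A": "A", "Oko": "Oko", "Y": "Y", "B": "B", "B07": "B", "C": "C"}
REGIONS = ("A", "B", "C")

#: per-amplicon subread count ranges reported for the real study; the
#: desk-scale law used in tests trades depth for speed (see docs/methods.md)
DEFAULT_COVERAGE_RANGES = {"A": (264, 1414), "B": (206, 1464), "C": (500, 1000)}
DESK_COVERAGE_RANGES = {"A": (60, 120), "B": (60, 120), "C": (60, 120)}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_STOPS = {"TAA", "TAG", "TGA"}


def seq_to_codes(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def codes_to_seq(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode()


@dataclass
class ReadErrorModel:
    """Per-base error process applied to amplicon templates."""

    sub_rate: float = 0.01
    ins_rate: float = 0.005
    del_rate: float = 0.005
    homopolymer_multiplier: float = 3.0
    homopolymer_min_run: int = 4
    truncation_prob: float = 0.02

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate,
                  self.truncation_prob):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")
        if self.homopolymer_multiplier < 1.0:
            raise ValueError("homopolymer multiplier must be >= 1")

    @classmethod
    def error_free(cls) -> "ReadErrorModel":
        return cls(0.0, 0.0, 0.0, 1.0, 4, 0.0)


@dataclass
class SimulatedRegionModel:
    """Gene-content rules and mutation parameters of the simulated region."""

    p_oko_haplotype: float = 0.26       # A-region haplotype carries Oko (no A)
    p_y_on_a_haplotype: float = 0.6     # A-haplotypes additionally carry Y
    p_second_b_locus: float = 0.25      # B-haplotypes additionally carry B07
    n_intron_subs: int = 3              # intron-only variant construction
    n_nonsyn_subs: int = 2              # nonsynonymous variant construction
    interlocus_divergence: float = 0.025  # A vs Oko/Y, B vs B07 ancestors
    homopolymer_seeds: int = 10         # runs planted in non-coding sequence
    dirichlet_alpha: float = 1.0        # allele frequency law per locus


@dataclass
class TruthTable:
    """Ground truth of a simulated study."""

    genotypes: dict[str, dict[str, list[str]]]  # sample -> region -> allele ids
    haplotypes: dict[str, tuple[dict, dict]]    # sample -> 2 haplotype dicts
    pedigree: list[tuple[str, Optional[str], Optional[str]]]
    read_sources: dict[str, str] = field(default_factory=dict)  # read id -> allele id


@dataclass
class SubreadSet:
    sample: str
    region: str
    replicate: int
    reads: list[tuple[str, str]]        # (read id, sequence)
    sources: dict[str, str] = field(default_factory=dict)  # read id -> allele


def _class_i_feature_map() -> FeatureMap:
    feats = [("5'UTR", 0, UTR5_LEN)]
    pos = UTR5_LEN
    for i, elen in enumerate(EXON_LENGTHS):
        feats.append(("exon", pos, pos + elen))
        pos += elen
        if i < len(INTRON_LENGTHS):
            feats.append(("intron", pos, pos + INTRON_LENGTHS[i]))
            pos += INTRON_LENGTHS[i]
    feats.append(("3'UTR", pos, pos + UTR3_LEN))
    return FeatureMap(feats)


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random non-stop codons + TAA."""
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = codes_to_seq(rng.integers(0, 4, size=3).astype(np.uint8))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return codes_to_seq(rng.integers(0, 4, size=n).astype(np.uint8))


def _noncoding_positions(fmap: FeatureMap) -> np.ndarray:
    pos = []
    for f in fmap:
        if f.kind != "exon":
            pos.extend(range(f.start, f.end))
    return np.asarray(pos)


def _seed_homopolymers(seq: str, fmap: FeatureMap, n_runs: int,
                       rng: np.random.Generator) -> str:
    arr = bytearray(seq.encode())
    noncoding = [f for f in fmap if f.kind != "exon"]
    for _ in range(n_runs):
        run_len = int(rng.integers(4, 8))
        feat = noncoding[int(rng.integers(0, len(noncoding)))]
        start = int(rng.integers(feat.start, feat.end))
        base = b"ACGT"[int(rng.integers(0, 4))]
        end = min(start + run_len, feat.end)  # never spill into an exon
        for p in range(start, end):
            arr[p] = base
    return arr.decode()


class _AncestorGene:
    def __init__(self, gene: str, genomic: str, fmap: FeatureMap):
        self.gene = gene
        self.genomic = genomic
        self.fmap = fmap


def _cds_pos_to_genomic(fmap: FeatureMap, cds_pos: int) -> int:
    off = 0
    for ex in fmap.exons:
        if cds_pos < off + len(ex):
            return ex.start + (cds_pos - off)
        off += len(ex)
    raise IndexError(cds_pos)


def _apply_subs(seq: str, subs: dict[int, str]) -> str:
    arr = bytearray(seq.encode())
    for pos, base in subs.items():
        arr[pos] = ord(base)
    return arr.decode()


def _codon_at(cds: str, idx0: int) -> str:
    return cds[3 * idx0: 3 * idx0 + 3]


def _synonymous_sub(cds: str, rng: np.random.Generator) -> tuple[int, str]:
    """Find a (cds position, new base) that preserves the protein."""
    from .alleles import translate_cds
    n = len(cds) // 3
    order = rng.permutation(n - 1)  # never touch the final stop codon
    for ci in order:
        codon = _codon_at(cds, int(ci))
        for p in range(3):
            for b in "ACGT":
                if b == codon[p]:
                    continue
                new = codon[:p] + b + codon[p + 1:]
                if new in _STOPS or codon in _STOPS:
                    continue
                if translate_cds(new)[0] == translate_cds(codon)[0]:
                    return 3 * int(ci) + p, b
    raise RuntimeError("no synonymous substitution available")


def _nonsynonymous_sub(cds: str, rng: np.random.Generator) -> tuple[int, str]:
    from .alleles import translate_cds
    n = len(cds) // 3
    for _ in range(10_000):
        ci = int(rng.integers(1, n - 1))
        codon = _codon_at(cds, ci)
        if codon in _STOPS:
            continue
        p = int(rng.integers(0, 3))
        b = "ACGT"[int(rng.integers(0, 4))]
        if b == codon[p]:
            continue
        new = codon[:p] + b + codon[p + 1:]
        if new in _STOPS:
            continue
        if translate_cds(new)[0] != translate_cds(codon)[0]:
            return 3 * ci + p, b
    raise RuntimeError("no nonsynonymous substitution found")


def _diverge(anc: _AncestorGene, rate: float, rng: np.random.Generator,
             gene: str) -> _AncestorGene:
    """A related gene ancestor: codon-aware coding subs + intron subs."""
    from .alleles import extract_cds
    genomic = anc.genomic
    cds = extract_cds(genomic, anc.fmap)
    n_coding = max(1, int(rate * len(cds) * 0.6))
    n_noncoding = max(1, int(rate * (len(genomic) - len(cds))))
    subs: dict[int, str] = {}
    for _ in range(n_coding):
        if rng.random() < 0.5:
            cpos, b = _synonymous_sub(cds, rng)
        else:
            cpos, b = _nonsynonymous_sub(cds, rng)
        cds = cds[:cpos] + b + cds[cpos + 1:]
        subs[_cds_pos_to_genomic(anc.fmap, cpos)] = b
    nc = _noncoding_positions(anc.fmap)
    for pos in rng.choice(nc, size=n_noncoding, replace=False):
        cur = genomic[int(pos)]
        b = "ACGT"[int(rng.integers(0, 4))]
        if b != cur:
            subs[int(pos)] = b
    return _AncestorGene(gene, _apply_subs(genomic, subs), anc.fmap)


def build_allele_database(
    model: SimulatedRegionModel | None = None,
    n_alleles_per_locus: int = 5,
    seed: int = 0,
) -> tuple[list[AlleleRecord], list[dict]]:
    """Simulate per-locus allele databases covering every nomenclature class.

    Returns the allele records and a metadata list with the construction
    class of each allele (``ancestor`` / ``intron`` / ``synonymous`` /
    ``nonsynonymous`` / ``null`` / ``mixed``).
    """
    if n_alleles_per_locus < 1:
        raise ValueError("need at least one allele per locus")
    model = model or SimulatedRegionModel()
    rng = np.random.default_rng(seed)
    fmap = _class_i_feature_map()

    def make_ancestor(gene: str) -> _AncestorGene:
        cds = _random_orf(rng, sum(EXON_LENGTHS) // 3)
        # reserve a TGG at the engineered nonsense codon so a single
        # substitution can create TGA there (A locus null allele)
        stop_codon0 = NULL_STOP_MATURE_CODON + SIGNAL_PEPTIDE - 1
        cds = cds[:3 * stop_codon0] + "TGG" + cds[3 * stop_codon0 + 3:]
        pieces = [_random_seq(rng, UTR5_LEN)]
        off = 0
        for i, elen in enumerate(EXON_LENGTHS):
            pieces.append(cds[off:off + elen])
            off += elen
            if i < len(INTRON_LENGTHS):
                pieces.append(_random_seq(rng, INTRON_LENGTHS[i]))
        pieces.append(_random_seq(rng, UTR3_LEN))
        genomic = _seed_homopolymers("".join(pieces), fmap,
                                     model.homopolymer_seeds, rng)
        return _AncestorGene(gene, genomic, fmap)

    anc_a = make_ancestor("A")
    ancestors = {
        "A": anc_a,
        "Oko": _diverge(anc_a, model.interlocus_divergence, rng, "Oko"),
        "Y": _diverge(anc_a, model.interlocus_divergence, rng, "Y"),
        "B": make_ancestor("B"),
        "C": make_ancestor("C"),
    }
    ancestors["B07"] = _diverge(ancestors["B"], model.interlocus_divergence,
                                rng, "B07")

    from .alleles import extract_cds

    records: list[AlleleRecord] = []
    meta: list[dict] = []
    group_start = {"A": 1, "Oko": 1, "Y": 1, "B": 1, "B07": 7, "C": 1}

    for gene, anc in ancestors.items():
        locus = LOCUS_LABEL[gene]
        prefix = "Gogo"
        g0 = group_start[gene]
        seen: set[str] = {a.genomic_seq if False else "" for a in records}
        seen = {r.genomic_seq for r in records}
        variants: list[tuple[AlleleName, str, str]] = []  # (name, genomic, class)

        anc_name = AlleleName(prefix, locus, (g0, 1, 1, 1))
        variants.append((anc_name, anc.genomic, "ancestor"))

        cds = extract_cds(anc.genomic, fmap)

        # intron-only pair partner
        nc = _noncoding_positions(fmap)
        subs = {}
        while len(subs) < model.n_intron_subs:
            pos = int(rng.choice(nc))
            b = "ACGT"[int(rng.integers(0, 4))]
            if anc.genomic[pos] != b:
                subs[pos] = b
        variants.append((AlleleName(prefix, locus, (g0, 1, 1, 2)),
                         _apply_subs(anc.genomic, subs), "intron"))

        # synonymous-only pair partner
        cpos, b = _synonymous_sub(cds, rng)
        variants.append((AlleleName(prefix, locus, (g0, 1, 2)),
                         _apply_subs(anc.genomic,
                                     {_cds_pos_to_genomic(fmap, cpos): b}),
                         "synonymous"))

        # nonsynonymous pair partner
        subs = {}
        c = cds
        for _ in range(model.n_nonsyn_subs):
            cpos, b = _nonsynonymous_sub(c, rng)
            c = c[:cpos] + b + c[cpos + 1:]
            subs[_cds_pos_to_genomic(fmap, cpos)] = b
        variants.append((AlleleName(prefix, locus, (g0, 2)),
                         _apply_subs(anc.genomic, subs), "nonsynonymous"))

        if gene == "A":
            # null allele: TGG -> TGA at the engineered codon
            stop_codon0 = NULL_STOP_MATURE_CODON + SIGNAL_PEPTIDE - 1
            gpos = _cds_pos_to_genomic(fmap, 3 * stop_codon0 + 2)
            variants.append((AlleleName(prefix, locus, (g0 + 4, 1), "N"),
                             _apply_subs(anc.genomic, {gpos: "A"}), "null"))

        # extra alleles: mixed nonsynonymous + intron changes
        extra_group = g0 + 2
        while len(variants) < n_alleles_per_locus + (1 if gene == "A" else 0):
            subs = {}
            c = cds
            for _ in range(int(rng.integers(1, 3))):
                cpos, b = _nonsynonymous_sub(c, rng)
                c = c[:cpos] + b + c[cpos + 1:]
                subs[_cds_pos_to_genomic(fmap, cpos)] = b
            for pos in rng.choice(nc, size=2, replace=False):
                b = "ACGT"[int(rng.integers(0, 4))]
                if anc.genomic[int(pos)] != b:
                    subs[int(pos)] = b
            variants.append((AlleleName(prefix, locus, (extra_group, 1)),
                             _apply_subs(anc.genomic, subs), "mixed"))
            extra_group += 1

        for name, genomic, cls in variants:
            if genomic in seen:
                raise RuntimeError("duplicate simulated allele sequence")
            seen.add(genomic)
            rec = AlleleRecord(name=name, genomic_seq=genomic, features=fmap)
            records.append(rec)
            meta.append({"id": rec.id, "gene": gene, "locus": locus,
                         "region": REGION_OF_GENE[gene], "class": cls})
    return records, meta


def _draw_haplotype(model: SimulatedRegionModel, alleles_by_gene: dict,
                    freqs_by_gene: dict, rng: np.random.Generator) -> dict:
    def pick(gene: str) -> str:
        ids = alleles_by_gene[gene]
        return ids[int(rng.choice(len(ids), p=freqs_by_gene[gene]))]

    hap: dict[str, dict[str, str]] = {"A": {}, "B": {}, "C": {}}
    if rng.random() < model.p_oko_haplotype:
        hap["A"]["Oko"] = pick("Oko")
    else:
        hap["A"]["A"] = pick("A")
        if rng.random() < model.p_y_on_a_haplotype:
            hap["A"]["Y"] = pick("Y")
    hap["B"]["B"] = pick("B")
    if rng.random() < model.p_second_b_locus:
        hap["B"]["B07"] = pick("B07")
    hap["C"]["C"] = pick("C")
    return hap


def sample_population(
    db: list[AlleleRecord],
    meta: list[dict],
    n_samples: int = 35,
    n_trios: int = 1,
    n_dyads: int = 1,
    model: SimulatedRegionModel | None = None,
    seed: int = 0,
) -> TruthTable:
    """Draw a cohort of diploid genotypes with pedigree structure.

    Trio children receive one haplotype from each parent; dyad children one
    from the known father and one fresh draw.  Allele frequencies per locus
    follow a symmetric Dirichlet drawn once per run.
    """
    if n_trios * 3 > n_samples:
        raise ValueError("cohort too small for the requested trios")
    if n_samples - n_trios - n_dyads < (2 if n_trios else 1 if n_dyads else 0):
        raise ValueError("not enough founders for the requested pedigrees")
    model = model or SimulatedRegionModel()
    rng = np.random.default_rng(seed)

    alleles_by_gene: dict[str, list[str]] = {}
    for rec, m in zip(db, meta):
        alleles_by_gene.setdefault(m["gene"], []).append(rec.id)
    freqs_by_gene = {
        g: rng.dirichlet([model.dirichlet_alpha] * len(ids))
        for g, ids in alleles_by_gene.items()
    }

    n_children = n_trios + n_dyads
    n_founders = n_samples - n_children
    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    founders = samples[:n_founders]
    haplotypes: dict[str, tuple[dict, dict]] = {}
    pedigree: list[tuple[str, Optional[str], Optional[str]]] = []

    for s in founders:
        haplotypes[s] = (
            _draw_haplotype(model, alleles_by_gene, freqs_by_gene, rng),
            _draw_haplotype(model, alleles_by_gene, freqs_by_gene, rng),
        )
        pedigree.append((s, None, None))

    child_idx = n_founders
    for _ in range(n_trios):
        mother, father = (founders[int(i)] for i in
                          rng.choice(len(founders), size=2, replace=False))
        child = samples[child_idx]
        child_idx += 1
        hm = haplotypes[mother][int(rng.integers(0, 2))]
        hf = haplotypes[father][int(rng.integers(0, 2))]
        haplotypes[child] = (hm, hf)
        pedigree.append((child, mother, father))
    for _ in range(n_dyads):
        father = founders[int(rng.choice(len(founders)))]
        child = samples[child_idx]
        child_idx += 1
        hf = haplotypes[father][int(rng.integers(0, 2))]
        hm = _draw_haplotype(model, alleles_by_gene, freqs_by_gene, rng)
        haplotypes[child] = (hm, hf)
        pedigree.append((child, None, father))

    genotypes: dict[str, dict[str, list[str]]] = {}
    for s in samples:
        h1, h2 = haplotypes[s]
        per_region: dict[str, list[str]] = {}
        for region in REGIONS:
            ids = list(h1[region].values()) + list(h2[region].values())
            per_region[region] = sorted(ids)
        genotypes[s] = per_region
    return TruthTable(genotypes=genotypes, haplotypes=haplotypes,
                      pedigree=pedigree)


# ---------------------------------------------------------------------------
# read simulation


def homopolymer_mask(seq: str, min_run: int) -> np.ndarray:
    """Boolean mask of positions inside runs of length >= min_run."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    mask = np.zeros(n, dtype=bool)
    i = 0
    while i < n:
        j = i
        while j < n and arr[j] == arr[i]:
            j += 1
        if j - i >= min_run:
            mask[i:j] = True
        i = j
    return mask


def _simulate_read(codes: np.ndarray, p_sub: np.ndarray, p_ins: np.ndarray,
                   p_del: np.ndarray, trunc_prob: float,
                   rng: np.random.Generator) -> str:
    arr = codes
    ps, pi, pd = p_sub, p_ins, p_del
    if trunc_prob and rng.random() < trunc_prob:
        keep = int(len(arr) * rng.uniform(0.5, 0.95))
        if rng.random() < 0.5:
            arr, ps, pi, pd = arr[:keep], ps[:keep], pi[:keep], pd[:keep]
        else:
            arr, ps, pi, pd = arr[-keep:], ps[-keep:], pi[-keep:], pd[-keep:]
    u = rng.random(arr.shape[0])
    arr = arr.copy()
    sub = u < ps
    if sub.any():
        arr[sub] = (arr[sub] + rng.integers(1, 4, size=int(sub.sum()))) % 4
    # counts: 0 = deleted, 2 = duplicated (insertion of the local base)
    v = rng.random(arr.shape[0])
    counts = np.ones(arr.shape[0], dtype=np.int64)
    counts[v < pd] = 0
    w = rng.random(arr.shape[0])
    counts[(w < pi) & (counts > 0)] = 2
    return codes_to_seq(np.repeat(arr, counts))


def simulate_subreads(
    truth: TruthTable,
    db: list[AlleleRecord],
    error_model: ReadErrorModel | None = None,
    coverage_ranges: dict[str, tuple[int, int]] | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    amplification_alpha: float = 20.0,
    out_dir: str | Path | None = None,
) -> list[SubreadSet]:
    """Emit duplicate noisy subread sets per (sample, amplicon group).

    Per replicate, the total read count is uniform in the per-region
    coverage range and reads are multinomially distributed over the gene
    copies present (a Dirichlet jitter emulates amplification imbalance).
    The truth table is updated in place with per-read source alleles.
    """
    error_model = error_model or ReadErrorModel()
    coverage_ranges = coverage_ranges or DEFAULT_COVERAGE_RANGES
    for lo, hi in coverage_ranges.values():
        if lo < 1:
            raise ValueError("coverage must be positive")
    rng = np.random.default_rng(seed)
    by_id = {rec.id: rec for rec in db}

    # per-template precomputed arrays
    tmpl_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}

    def template_arrays(aid: str):
        if aid not in tmpl_cache:
            seq = by_id[aid].genomic_seq
            codes = seq_to_codes(seq)
            hp = homopolymer_mask(seq, error_model.homopolymer_min_run)
            mult = np.where(hp, error_model.homopolymer_multiplier, 1.0)
            p_sub = np.full(len(seq), error_model.sub_rate)
            p_ins = np.minimum(error_model.ins_rate * mult, 0.5)
            p_del = np.minimum(error_model.del_rate * mult, 0.5)
            tmpl_cache[aid] = (codes, p_sub, p_ins, p_del)
        return tmpl_cache[aid]

    out: list[SubreadSet] = []
    for sample in sorted(truth.genotypes):
        h1, h2 = truth.haplotypes[sample]
        for region in REGIONS:
            copies = list(h1[region].values()) + list(h2[region].values())
            lo, hi = coverage_ranges[region]
            for rep in range(1, n_replicates + 1):
                n_reads = int(rng.integers(lo, hi + 1))
                weights = rng.dirichlet([amplification_alpha] * len(copies))
                counts = rng.multinomial(n_reads, weights)
                reads: list[tuple[str, str]] = []
                sources: dict[str, str] = {}
                serial = 0
                for aid, c in zip(copies, counts):
                    codes, ps, pi, pd = template_arrays(aid)
                    for _ in range(int(c)):
                        serial += 1
                        rid = f"{sample}|{region}|rep{rep}|{serial:05d}"
                        seq = _simulate_read(codes, ps, pi, pd,
                                             error_model.truncation_prob, rng)
                        reads.append((rid, seq))
                        sources[rid] = aid
                truth.read_sources.update(sources)
                sset = SubreadSet(sample, region, rep, reads, sources)
                out.append(sset)
                if out_dir is not None:
                    path = Path(out_dir)
                    path.mkdir(parents=True, exist_ok=True)
                    mio.write_fastq(reads,
                                    path / f"{sample}_{region}_rep{rep}.fastq")
    return out


def simulate_study(
    seed: int = 0,
    n_samples: int = 35,
    n_alleles_per_locus: int = 5,
    model: SimulatedRegionModel | None = None,
    error_model: ReadErrorModel | None = None,
    coverage_ranges: dict[str, tuple[int, int]] | None = None,
    n_trios: int = 1,
    n_dyads: int = 1,
):
    """One-shot study: allele database + cohort + duplicate subreads."""
    model = model or SimulatedRegionModel()
    rng = np.random.default_rng(seed)
    s_db, s_pop, s_reads = (int(x) for x in rng.integers(0, 2**31 - 1, 3))
    db, meta = build_allele_database(model, n_alleles_per_locus, seed=s_db)
    truth = sample_population(db, meta, n_samples=n_samples, n_trios=n_trios,
                              n_dyads=n_dyads, model=model, seed=s_pop)
    subreads = simulate_subreads(truth, db, error_model=error_model,
                                 coverage_ranges=coverage_ranges, seed=s_reads)
    return db, meta, truth, subreads
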