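"""Genotype validation: replicate concordance, discordance resolution,
allelic-dropout checks, Mendelian trio consistency and genotype assembly.

Every sample is amplified and sequenced twice; a consensus is accepted only
when both replicates support it or an explicit resolution path applies:

* length differences adjacent to homopolymer runs (>= 4 bases) are
  classified as technology noise and resolved — preferring, when a known
  allele database is supplied, the replicate whose sequence matches a
  database allele exactly;
* a single base-pair discordance triggers a minor-variant re-analysis of
  both replicates' raw reads; two alleles are accepted only when both
  variants pass frequency/depth thresholds in *both* replicates and the
  variant coding sequences are corroborated by another cohort sample or by
  pedigree transmission;
* replicate frequency consistency of two-variant positions distinguishes
  the phasing artefact from allelic dropout.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

import edlib

from .alleles import FeatureMap
from .phasing import ConsensusCall, MinorVariantResult, minor_variant_scan
from .simulate import homopolymer_mask

DISCORDANCE_CLASSES = ("identical", "homopolymer", "single_bp", "other")
RESOLUTIONS = ("accepted", "resolved_by_minor_variant",
               "resolved_by_corroboration", "unresolved")

#: maximum gene copies one haplotype can carry per amplicon region
HAPLOTYPE_CAPACITY = {"A": 2, "B": 2, "C": 1}


@dataclass
class Difference:
    kind: str              # sub | ins | del
    pos1: int              # 0-based position on the first sequence
    pos2: int
    detail: str = ""
    homopolymer: bool = False


@dataclass
class DiscordanceReport:
    pair: tuple[int, int]               # indices into the two call lists
    cls: str
    region: Optional[str] = None        # feature kind at the differing sites
    positions: list[int] = field(default_factory=list)  # 1-based, seq1
    differences: list[Difference] = field(default_factory=list)
    resolution: str = "accepted"
    sequence: Optional[str] = None      # the accepted sequence, if resolved
    extra_sequences: list[str] = field(default_factory=list)


def _diff_list(seq1: str, seq2: str, hp_run: int = 4) -> list[Difference]:
    aln = edlib.align(seq1, seq2, task="path", mode="NW")
    hp1 = homopolymer_mask(seq1, hp_run)
    hp2 = homopolymer_mask(seq2, hp_run)
    diffs: list[Difference] = []
    q = t = 0  # q on seq1, t on seq2
    for n, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
        n = int(n)
        if op == "=":
            q += n
            t += n
        elif op in "XM":
            for k in range(n):
                if seq1[q + k] != seq2[t + k]:
                    diffs.append(Difference("sub", q + k, t + k,
                                            f"{seq2[t+k]}>{seq1[q+k]}"))
            q += n
            t += n
        elif op == "I":  # bases present in seq1 only
            near = any(hp1[max(0, q - 1):min(len(hp1), q + n + 1)])
            diffs.append(Difference("ins", q, t, seq1[q:q + n],
                                    homopolymer=near))
            q += n
        elif op == "D":  # bases present in seq2 only
            near = any(hp2[max(0, t - 1):min(len(hp2), t + n + 1)]) or \
                any(hp1[max(0, q - 1):min(len(hp1), q + 1)])
            diffs.append(Difference("del", q, t, seq2[t:t + n],
                                    homopolymer=near))
            t += n
    return diffs


def classify_pair(seq1: str, seq2: str, features: Optional[FeatureMap] = None,
                  hp_run: int = 4) -> DiscordanceReport:
    """Classify the differences between one consensus pair."""
    diffs = _diff_list(seq1, seq2, hp_run)
    report = DiscordanceReport(pair=(-1, -1), cls="other", differences=diffs,
                               positions=[d.pos1 + 1 for d in diffs])
    if not diffs:
        report.cls = "identical"
        report.sequence = seq1
    elif all(d.kind in ("ins", "del") and d.homopolymer for d in diffs):
        report.cls = "homopolymer"
    elif len(diffs) == 1:
        report.cls = "single_bp"
    if features is not None and diffs:
        kinds = {features.kind_at(d.pos1) for d in diffs}
        kinds.discard(None)
        report.region = kinds.pop() if len(kinds) == 1 else "mixed"
    return report


def compare_replicates(
    calls_rep1: Sequence[ConsensusCall],
    calls_rep2: Sequence[ConsensusCall],
    features: Optional[FeatureMap | dict] = None,
    hp_run: int = 4,
) -> tuple[list[DiscordanceReport], list[tuple[int, int]]]:
    """Match consensus sequences across replicates and classify each pair.

    Matching is greedy on edit distance.  Returns the per-pair reports and
    the unmatched calls as ``(replicate, index)`` dropout-suspect flags.
    ``features`` may be one map for all pairs or a dict keyed by the pair's
    index in replicate 1.
    """
    n1, n2 = len(calls_rep1), len(calls_rep2)
    dists = []
    for i in range(n1):
        for j in range(n2):
            d = edlib.align(calls_rep1[i].sequence, calls_rep2[j].sequence,
                            mode="NW")["editDistance"]
            dists.append((d, i, j))
    dists.sort()
    used1: set[int] = set()
    used2: set[int] = set()
    reports: list[DiscordanceReport] = []
    for d, i, j in dists:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        fmap = features.get(i) if isinstance(features, dict) else features
        rep = classify_pair(calls_rep1[i].sequence, calls_rep2[j].sequence,
                            fmap, hp_run)
        rep.pair = (i, j)
        reports.append(rep)
    dropouts = [(1, i) for i in range(n1) if i not in used1] + \
               [(2, j) for j in range(n2) if j not in used2]
    return reports, dropouts


def resolve_single_bp(
    report: DiscordanceReport,
    reads_rep1: Sequence[tuple[str, str]],
    reads_rep2: Sequence[tuple[str, str]],
    reference: str,
    cohort_cds: dict[str, set[str]],
    sample: str,
    features: Optional[FeatureMap] = None,
    pedigree_links: Iterable[str] = (),
    min_freq: float = 0.2,
    min_depth: int = 50,
) -> DiscordanceReport:
    """Attempt to resolve a single-base replicate discordance.

    Runs the minor-variant scan of both replicates against *reference*;
    two alleles are accepted iff >= 2 base variants pass the thresholds in
    both replicates AND each variant-containing coding sequence is seen in
    another cohort sample (or the sample's pedigree links).  Unresolved is
    a valid outcome and leaves the report flagged.
    """
    if report.cls != "single_bp":
        raise ValueError("resolution applies to single_bp reports only")
    scans = [minor_variant_scan(r, reference, min_freq, min_depth)
             for r in (reads_rep1, reads_rep2)]
    shared = None
    for pos, variants in scans[0].positions:
        bases1 = {b for b, _, _ in variants if b != "-"}
        for pos2, variants2 in scans[1].positions:
            if pos2 == pos:
                bases2 = {b for b, _, _ in variants2 if b != "-"}
                common = bases1 & bases2
                if len(common) >= 2:
                    shared = (pos, sorted(common))
        if shared:
            break
    if shared is None:
        report.resolution = "unresolved"
        return report

    pos, bases = shared
    candidates = [reference[:pos] + b + reference[pos + 1:] for b in bases[:2]]
    links = set(pedigree_links)

    def corroborated(seq: str) -> bool:
        if features is not None:
            from .alleles import extract_cds
            key = extract_cds(seq, features)
        else:
            key = seq
        for other, cset in cohort_cds.items():
            if other == sample:
                continue
            if key in cset:
                if other in links:
                    return True  # pedigree transmission
                return True      # cohort corroboration
        return False

    if all(corroborated(c) for c in candidates):
        report.resolution = "resolved_by_minor_variant"
        report.sequence = candidates[0]
        report.extra_sequences = candidates[1:]
    else:
        report.resolution = "unresolved"
    return report


def check_allelic_dropout(
    freqs_rep1: tuple[float, float],
    freqs_rep2: tuple[float, float],
    depths: Optional[tuple[int, int]] = None,
    min_freq: float = 0.2,
    freq_tolerance: float = 0.15,
    min_depth: int = 50,
) -> str:
    """'consistent' | 'dropout_suspect' | 'indeterminate'.

    Two-variant frequencies from both replicates are consistent with two
    genuine alleles (no dropout) when the minor frequency passes the
    threshold in both replicates and the replicate minor frequencies agree
    within the tolerance.
    """
    if depths is not None and min(depths) < min_depth:
        return "indeterminate"
    m1, m2 = min(freqs_rep1), min(freqs_rep2)
    if m1 >= min_freq and m2 >= min_freq and abs(m1 - m2) <= freq_tolerance:
        return "consistent"
    return "dropout_suspect"


# ---------------------------------------------------------------------------
# Mendelian checks


def _partitions(calls: Sequence[str]):
    items = list(calls)
    n = len(items)
    for mask in range(2 ** n):
        side_m = [items[k] for k in range(n) if mask >> k & 1]
        side_p = [items[k] for k in range(n) if not mask >> k & 1]
        yield side_m, side_p


def check_mendelian(
    child: dict[str, Sequence[str]],
    mother: Optional[dict[str, Sequence[str]]],
    father: Optional[dict[str, Sequence[str]]],
) -> dict[str, dict]:
    """Per-region Mendelian consistency of a trio (or dyad).

    Genotypes map region -> validated allele identifiers.  A region is
    consistent iff the child's calls split into a maternal-compatible and a
    paternal-compatible haplotype set, respecting the per-region haplotype
    gene capacity (gene absence, e.g. the *Oko* haplotype, is an
    inheritable state: an empty side is always compatible).  With one
    parent missing (dyad) only the available side is constrained; with
    both missing the region is indeterminate.  Alleles present in both
    parents are annotated as transmissible by either one.
    """
    if mother is None and father is None:
        return {r: {"status": "indeterminate", "origin": {}} for r in child}
    out: dict[str, dict] = {}
    for region, calls in child.items():
        cap = HAPLOTYPE_CAPACITY.get(region, 2)
        mset = set(mother.get(region, [])) if mother is not None else None
        pset = set(father.get(region, [])) if father is not None else None
        ok = False
        for side_m, side_p in _partitions(list(dict.fromkeys(calls))):
            if len(side_m) > cap or len(side_p) > cap:
                continue
            if mset is not None and not set(side_m) <= mset:
                continue
            if pset is not None and not set(side_p) <= pset:
                continue
            ok = True
            break
        origin = {}
        for a in calls:
            in_m = mset is not None and a in mset
            in_p = pset is not None and a in pset
            origin[a] = ("either" if in_m and in_p else
                         "maternal" if in_m else
                         "paternal" if in_p else "untransmitted")
        out[region] = {"status": "consistent" if ok else "violation",
                       "origin": origin}
    return out


# ---------------------------------------------------------------------------
# genotype assembly


@dataclass
class GenotypeCall:
    sample: str
    region: str
    allele: str                        # allele name or novel-sequence id
    locus: Optional[str] = None
    evidence: str = "both_replicates"  # or a resolution class
    flags: list[str] = field(default_factory=list)


class GenotypeTable:
    """Validated per-sample, per-region allele calls with provenance."""

    def __init__(self, calls: Iterable[GenotypeCall]):
        self.calls = list(calls)

    def __len__(self) -> int:
        return len(self.calls)

    def of_sample(self, sample: str, region: Optional[str] = None
                  ) -> list[GenotypeCall]:
        return [c for c in self.calls if c.sample == sample
                and (region is None or c.region == region)]

    @property
    def samples(self) -> list[str]:
        return sorted({c.sample for c in self.calls})

    @property
    def by_sample(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for c in self.calls:
            out.setdefault(c.sample, []).append(c.allele)
        return out

    def region_genotype(self, sample: str, region: str) -> set[str]:
        return {c.allele for c in self.of_sample(sample, region)}

    def gene_count(self, sample: str, region: str) -> int:
        n = len(self.region_genotype(sample, region))
        return max(1, -(-n // 2))  # >2 distinct alleles implies >=2 genes

    def to_rows(self) -> list[dict]:
        return [{"sample": c.sample, "region": c.region, "allele": c.allele,
                 "gene_count": self.gene_count(c.sample, c.region),
                 "flags": ";".join(c.flags), "evidence": c.evidence}
                for c in self.calls]


def assemble_genotypes(
    validated: dict[tuple[str, str], list[tuple[str, str]]],
    k_max: dict[str, int] | None = None,
) -> GenotypeTable:
    """Assemble the final table from validated (sample, region) call lists.

    ``validated`` maps (sample, region) to (allele identifier, evidence)
    pairs.  More than 2 distinct alleles in a region implies a second gene;
    a single balanced call is flagged homozygous; more calls than the
    region's phasing budget allows is a phasing inconsistency.
    """
    k_max = k_max or {"A": 4, "B": 3, "C": 2}
    calls: list[GenotypeCall] = []
    for (sample, region), entries in sorted(validated.items()):
        distinct = list(dict.fromkeys(a for a, _ in entries))
        if len(distinct) > 2 * k_max.get(region, 4):
            raise ValueError(
                f"{sample}/{region}: {len(distinct)} alleles exceed the "
                "phasing budget — phasing inconsistency")
        flags = ["homozygous"] if len(distinct) == 1 else []
        first_evidence = {}
        for allele, evidence in entries:
            first_evidence.setdefault(allele, evidence)
        for allele in distinct:
            calls.append(GenotypeCall(sample=sample, region=region,
                                      allele=allele,
                                      evidence=first_evidence[allele],
                                      flags=list(flags)))
    return GenotypeTable(calls)
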