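"""Allele matching, novelty classification, null detection and naming.

Validated consensus sequences are matched against a known-allele database
by global alignment; differences are partitioned by feature kind and codon
effect, and the hierarchical name fields follow from the difference class:
a new non-coding variant extends the 4th field, a synonymous coding variant
the 3rd, a new protein the 2nd (or opens a new allele group when the
protein diverges beyond a ceiling), and null alleles — premature stop or
frameshift before the final exon's stop — carry the ``N`` suffix.

Real committee nomenclature is first-come-first-served; batch naming here
sorts queries lexicographically by sequence first so that names are a pure
function of the input set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import edlib

from .alleles import (DEFAULT_SIGNAL_PEPTIDE, AlleleName, AlleleRecord,
                      FeatureMap, Feature, NomenclatureError, translate_cds)

CLASSIFICATIONS = ("exact", "intron_variant", "synonymous_variant",
                   "nonsynonymous_variant", "divergent")


@dataclass
class MatchResult:
    query_id: str
    best: Optional[AlleleRecord]
    n_coding_nonsyn: int = 0
    n_coding_syn: int = 0
    n_noncoding: int = 0
    n_indel_coding: int = 0
    n_indel_noncoding: int = 0
    classification: str = "divergent"
    edit_distance: int = 0
    query_record: Optional[AlleleRecord] = None

    @property
    def is_exact(self) -> bool:
        return self.classification == "exact"


def transfer_features(reference: AlleleRecord, query_seq: str,
                      query_id: str = "query") -> AlleleRecord:
    """Project a reference allele's feature map onto a near-identical query.

    Feature boundaries are carried through the global alignment so the
    query's exons can be extracted even when indels shift coordinates.
    """
    aln = edlib.align(query_seq, reference.genomic_seq, task="path", mode="NW")
    # map: reference position -> query position (for boundary transfer)
    import re
    ref2q: dict[int, int] = {}
    q = t = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
        n = int(n)
        if op in "=XM":
            for k in range(n):
                ref2q[t + k] = q + k
            q += n
            t += n
        elif op == "D":
            for k in range(n):
                ref2q[t + k] = q
            t += n
        elif op == "I":
            q += n
    ref2q[t] = q  # end sentinel
    feats = []
    for f in reference.features:
        s, e = ref2q[f.start], ref2q[f.end]
        if e > s:
            feats.append(Feature(f.kind, s, e))
    return AlleleRecord(name=query_id, genomic_seq=query_seq,
                        features=FeatureMap(feats))


def _compare(query: AlleleRecord, ref: AlleleRecord) -> MatchResult:
    res = MatchResult(query_id=query.id, best=ref, query_record=query)
    aln = edlib.align(query.genomic_seq, ref.genomic_seq, task="path",
                      mode="NW")
    res.edit_distance = aln["editDistance"]
    if res.edit_distance == 0:
        res.classification = "exact"
        return res

    # indels partitioned by the reference feature kind
    import re
    q = t = 0
    n_sub_noncoding = 0
    for n, op in re.findall(r"(\d+)([=XIDM])", aln["cigar"]):
        n = int(n)
        if op in "=XM":
            if op == "X" or op == "M":
                for k in range(n):
                    if query.genomic_seq[q + k] != ref.genomic_seq[t + k]:
                        kind = ref.features.kind_at(t + k)
                        if kind != "exon":
                            n_sub_noncoding += 1
            q += n
            t += n
        elif op == "D":
            kind = ref.features.kind_at(t)
            if kind == "exon":
                res.n_indel_coding += 1
            else:
                res.n_indel_noncoding += 1
            t += n
        elif op == "I":
            kind = ref.features.kind_at(min(t, len(ref.genomic_seq) - 1))
            if kind == "exon":
                res.n_indel_coding += 1
            else:
                res.n_indel_noncoding += 1
            q += n
    res.n_noncoding = n_sub_noncoding

    # coding effect from the two CDSs directly
    if len(query.cds) == len(ref.cds) and len(ref.cds) % 3 == 0:
        for ci in range(len(ref.cds) // 3):
            a = query.cds[3 * ci:3 * ci + 3]
            b = ref.cds[3 * ci:3 * ci + 3]
            if a != b:
                pa, _ = translate_cds(a)
                pb, _ = translate_cds(b)
                ndiff = sum(x != y for x, y in zip(a, b))
                if pa == pb:
                    res.n_coding_syn += ndiff
                else:
                    res.n_coding_nonsyn += ndiff
    elif query.cds != ref.cds:
        res.n_indel_coding = max(res.n_indel_coding, 1)

    if res.n_coding_nonsyn or res.n_indel_coding:
        res.classification = "nonsynonymous_variant"
    elif res.n_coding_syn:
        res.classification = "synonymous_variant"
    else:
        res.classification = "intron_variant"
    return res


def match_known_alleles(query: AlleleRecord, db: Iterable[AlleleRecord],
                        divergence_ceiling: float = 0.10,
                        locus: Optional[str] = None) -> MatchResult:
    """Match a query against all database alleles of the same locus.

    The best match minimises edit distance; ties break on allele name.
    Queries farther than ``divergence_ceiling`` (fraction of the query
    length) from every database allele are classified ``divergent``.
    """
    locus = locus or query.locus
    cands = [r for r in db if locus is None or r.locus == locus]
    if not cands:
        raise ValueError(f"no database alleles for locus {locus!r}")
    scored = sorted(
        ((edlib.align(query.genomic_seq, r.genomic_seq,
                      mode="NW")["editDistance"], r.id, r) for r in cands))
    dist, _, best = scored[0]
    if dist > divergence_ceiling * len(query.genomic_seq):
        return MatchResult(query_id=query.id, best=best, edit_distance=dist,
                           classification="divergent", query_record=query)
    return _compare(query, best)


def detect_null_allele(record: AlleleRecord,
                       signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE):
    """Classify an allele as functional or null.

    Null alleles carry a premature stop (reported at its mature-protein
    codon number) or a frameshift (CDS length not a multiple of 3).
    """
    if not record.coding_complete:
        return "null", {"mechanism": "frameshift",
                        "cds_length": len(record.cds)}
    if record.premature_stop is not None:
        return "null", {"mechanism": "nonsense",
                        "codon": record.premature_stop - signal_peptide,
                        "cds_codon": record.premature_stop,
                        "exon": record.features.exon_index_at(
                            _cds_to_genomic(record.features,
                                            3 * (record.premature_stop - 1)))}
    return "functional", None


def _cds_to_genomic(fmap: FeatureMap, cds_pos: int) -> int:
    off = 0
    for ex in fmap.exons:
        if cds_pos < off + len(ex):
            return ex.start + (cds_pos - off)
        off += len(ex)
    raise IndexError(cds_pos)


class Registry:
    """Holds the allele names already assigned per (prefix, locus)."""

    def __init__(self, names: Iterable[AlleleName] = ()):
        self.names: set[AlleleName] = set()
        self.protein_groups: dict[tuple[str, str, int], list[str]] = {}
        for n in names:
            self.add(n)

    def add(self, name: AlleleName, protein: Optional[str] = None) -> None:
        if name in self.names:
            raise NomenclatureError(f"registry collision: {name.render()}")
        self.names.add(name)
        if protein is not None:
            key = (name.prefix, name.locus, name.fields[0])
            self.protein_groups.setdefault(key, []).append(protein)

    def of_locus(self, prefix: str, locus: str) -> list[AlleleName]:
        return [n for n in self.names
                if n.prefix == prefix and n.locus == locus]

    def next_free(self, prefix: str, locus: str, stem: tuple[int, ...],
                  depth: int) -> int:
        """Smallest unused value for field ``depth`` (0-based) under stem."""
        used = {n.fields[depth] for n in self.of_locus(prefix, locus)
                if len(n.fields) > depth and n.fields[:depth] == stem}
        k = 1
        while k in used:
            k += 1
        return k


def _pad(fields: tuple[int, ...], n: int) -> tuple[int, ...]:
    return fields + (1,) * (n - len(fields))


def assign_allele_name(match: MatchResult, is_null: bool, registry: Registry,
                       group_ceiling: int = 5) -> AlleleName:
    """Assign a hierarchical name from a match classification.

    exact keeps the known name; an intron variant takes the next free 4th
    field under the best match's 3-field name; a synonymous variant the next
    free 3rd field; a nonsynonymous variant the next free 2nd field of the
    group, unless the protein differs from every group member by more than
    ``group_ceiling`` residues, which opens a new group.  Null alleles get
    the ``N`` suffix.
    """
    best = match.best
    if best is None or not isinstance(best.name, AlleleName):
        raise NomenclatureError("best match carries no parseable name")
    bname = best.name
    prefix, locus = bname.prefix, bname.locus
    suffix = "N" if is_null else ""

    if match.classification == "exact":
        return bname
    if match.classification == "intron_variant":
        stem = _pad(bname.fields[:3], 3)
        f4 = registry.next_free(prefix, locus, stem, 3)
        name = AlleleName(prefix, locus, stem + (f4,), bname.suffix or suffix)
    elif match.classification == "synonymous_variant":
        stem = _pad(bname.fields[:2], 2)
        f3 = registry.next_free(prefix, locus, stem, 2)
        name = AlleleName(prefix, locus, stem + (f3,), suffix)
    else:  # nonsynonymous or divergent: protein-level placement
        protein = match.query_record.protein if match.query_record else ""
        group = bname.fields[0]
        members = registry.protein_groups.get((prefix, locus, group), [])
        in_group = (match.classification == "nonsynonymous_variant") and any(
            _protein_distance(protein, p) <= group_ceiling for p in members
        ) if members else match.classification == "nonsynonymous_variant"
        if in_group:
            stem = (group,)
            f2 = registry.next_free(prefix, locus, stem, 1)
            name = AlleleName(prefix, locus, (group, f2), suffix)
        else:
            f1 = registry.next_free(prefix, locus, (), 0)
            name = AlleleName(prefix, locus, (f1, 1), suffix)
    registry.add(name, match.query_record.protein if match.query_record else None)
    return name


def _protein_distance(a: str, b: str) -> int:
    if len(a) != len(b):
        return max(len(a), len(b)) - min(len(a), len(b)) + sum(
            x != y for x, y in zip(a, b))
    return sum(x != y for x, y in zip(a, b))


@dataclass
class CodingGroup:
    key: str
    members: list = field(default_factory=list)


def collapse_to_coding_groups(alleles: Iterable) -> list[list]:
    """Partition alleles into groups sharing an identical coding sequence.

    Accepts :class:`AlleleRecord` objects (grouped by CDS identity) or
    objects/dicts with ``name`` (+ optional ``accession``): those are
    grouped by the name's coding-group truncation, and groups sharing a
    GenBank accession (identical sequences deposited once for two species)
    are merged.  Idempotent; the groups partition the input.
    """
    items = list(alleles)
    keys: list[str] = []
    for it in items:
        if isinstance(it, AlleleRecord):
            keys.append("cds:" + it.cds)
        else:
            name = it["name"] if isinstance(it, dict) else it.name
            if isinstance(name, str):
                name = AlleleName.parse(name)
            keys.append("name:" + name.coding_group.render())

    # union-find over group keys, merging keys that share an accession
    parent: dict[str, str] = {}

    def find(k: str) -> str:
        parent.setdefault(k, k)
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_accession: dict[str, str] = {}
    for it, key in zip(items, keys):
        find(key)
        acc = (it.accession if isinstance(it, AlleleRecord)
               else (it.get("accession") if isinstance(it, dict)
                     else getattr(it, "accession", None)))
        if acc:
            if acc in by_accession:
                union(by_accession[acc], key)
            else:
                by_accession[acc] = key

    groups: dict[str, list] = {}
    for it, key in zip(items, keys):
        groups.setdefault(find(key), []).append(it)
    return list(groups.values())
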