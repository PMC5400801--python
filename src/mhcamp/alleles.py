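"""Core domain types for full-length MHC class I alleles.

An allele here is a *genomic* amplicon-scale sequence (5'UTR through 3'UTR)
with an exon/intron feature map from which the coding sequence and protein
are derived.  Coordinates are 0-based half-open internally; all user-facing
reports use 1-based positions, and protein residues are numbered on the
mature protein (after removal of a signal peptide, 24 residues by default),
which is the convention used for class I epitope and nonsense-codon
positions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio.Data.CodonTable import standard_dna_table

#: residues cleaved off the N-terminus to obtain the mature class I protein
DEFAULT_SIGNAL_PEPTIDE = 24

FEATURE_KINDS = ("5'UTR", "exon", "intron", "3'UTR")

_STOP_CODONS = frozenset(standard_dna_table.stop_codons)
_CODON_TABLE = dict(standard_dna_table.forward_table)

_NAME_RE = re.compile(
    r"^(?P<prefix>[A-Za-z]{2,4})-(?P<locus>A|Oko|B|C|Y)\*"
    r"(?P<fields>\d{2,}(?::\d{2,}){0,3})\s?(?P<suffix>N)?$"
)


class NomenclatureError(ValueError):
    """Raised for malformed or colliding allele names."""


@dataclass(frozen=True, order=True)
class AlleleName:
    """Hierarchical MHC allele name, e.g. ``Gogo-A*05:02:01:01N``.

    Field semantics follow the HLA convention: the first field is the allele
    group, the second distinguishes protein sequences, the third synonymous
    coding variants, and the fourth non-coding (intron/UTR) variants.  The
    ``N`` suffix marks a null allele (premature stop or frameshift).
    """

    prefix: str
    locus: str
    fields: tuple[int, ...]
    suffix: str = ""

    def __post_init__(self) -> None:
        if self.locus not in ("A", "Oko", "B", "C", "Y"):
            raise NomenclatureError(f"unknown locus label {self.locus!r}")
        if not 1 <= len(self.fields) <= 4:
            raise NomenclatureError("allele names carry 1-4 numeric fields")
        if self.suffix not in ("", "N"):
            raise NomenclatureError(f"unsupported suffix {self.suffix!r}")

    @classmethod
    def parse(cls, text: str) -> "AlleleName":
        m = _NAME_RE.match(text.strip().strip("*"))
        if m is None:
            raise NomenclatureError(f"cannot parse allele name {text!r}")
        fields = tuple(int(f) for f in m.group("fields").split(":"))
        return cls(m.group("prefix"), m.group("locus"), fields, m.group("suffix") or "")

    def render(self) -> str:
        joined = ":".join(f"{f:02d}" for f in self.fields)
        return f"{self.prefix}-{self.locus}*{joined}{self.suffix}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()

    def truncate(self, n_fields: int) -> "AlleleName":
        """Name shortened to the first *n_fields* fields (suffix dropped)."""
        return AlleleName(self.prefix, self.locus, self.fields[:n_fields])

    @property
    def coding_group(self) -> "AlleleName":
        """Name with the non-coding (4th) field dropped: alleles sharing this
        truncated name share an identical coding sequence."""
        return self.truncate(min(len(self.fields), 3))

    @property
    def is_null(self) -> bool:
        return self.suffix == "N"


@dataclass(frozen=True)
class Feature:
    kind: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start


class FeatureMap:
    """Ordered, non-overlapping exon/intron/UTR intervals tiling a contiguous
    stretch of the forward strand of an amplicon."""

    def __init__(self, features: Iterable[tuple[str, int, int] | Feature]):
        feats = [f if isinstance(f, Feature) else Feature(*f) for f in features]
        if not feats:
            raise ValueError("empty feature map")
        for a, b in zip(feats, feats[1:]):
            if b.start != a.end:
                raise ValueError(
                    f"features must tile contiguously; gap/overlap between "
                    f"{a} and {b}"
                )
        if not any(f.kind == "exon" for f in feats):
            raise ValueError("a feature map needs at least one exon")
        self.features: list[Feature] = feats

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureMap) and self.features == other.features

    @property
    def span(self) -> tuple[int, int]:
        return self.features[0].start, self.features[-1].end

    @property
    def exons(self) -> list[Feature]:
        return [f for f in self.features if f.kind == "exon"]

    def kind_at(self, position: int) -> Optional[str]:
        """Feature kind covering a 0-based genomic position, or None."""
        for f in self.features:
            if f.start <= position < f.end:
                return f.kind
        return None

    def exon_index_at(self, position: int) -> Optional[int]:
        """1-based exon number covering *position* (None if not exonic)."""
        for i, f in enumerate(self.exons, start=1):
            if f.start <= position < f.end:
                return i
        return None

    def cds_offset(self, position: int) -> Optional[int]:
        """0-based offset of a genomic position within the concatenated CDS."""
        off = 0
        for f in self.exons:
            if f.start <= position < f.end:
                return off + (position - f.start)
            off += len(f)
        return None


def extract_cds(genomic_seq: str, features: FeatureMap) -> str:
    """Concatenate exon intervals of *genomic_seq* in feature order."""
    if features.span[1] > len(genomic_seq):
        raise ValueError(
            f"feature map extends to {features.span[1]} but sequence has "
            f"only {len(genomic_seq)} bases"
        )
    return "".join(genomic_seq[f.start:f.end] for f in features.exons)


def translate_cds(cds: str) -> tuple[str, Optional[int]]:
    """Translate a CDS with the standard genetic code.

    Returns the protein up to and including the first stop (rendered ``*``)
    and, when a stop occurs before the final codon, its 1-based codon index.
    Codons containing ambiguous bases translate to ``X`` rather than being
    dropped.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    cds = cds.upper()
    n_codons = len(cds) // 3
    residues: list[str] = []
    for i in range(n_codons):
        codon = cds[3 * i: 3 * i + 3]
        if codon in _STOP_CODONS:
            residues.append("*")
            premature = i + 1 if i + 1 < n_codons else None
            return "".join(residues), premature
        residues.append(_CODON_TABLE.get(codon, "X"))
    return "".join(residues), None


def mature_position(cds_codon_index: int,
                    signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE) -> int:
    """Convert a 1-based CDS codon index to mature-protein numbering."""
    return cds_codon_index - signal_peptide


@dataclass
class AlleleRecord:
    """A named full-length genomic allele with derived CDS and protein."""

    name: AlleleName | str
    genomic_seq: str
    features: FeatureMap
    accession: Optional[str] = None
    cds: str = field(init=False)
    protein: str = field(init=False)
    premature_stop: Optional[int] = field(init=False)

    def __post_init__(self) -> None:
        self.genomic_seq = self.genomic_seq.upper()
        self.cds = extract_cds(self.genomic_seq, self.features)
        if len(self.cds) % 3 == 0:
            self.protein, self.premature_stop = translate_cds(self.cds)
            self.coding_complete = True
        else:
            # frameshifted/incomplete CDS: translate the in-frame prefix
            trimmed = self.cds[: 3 * (len(self.cds) // 3)]
            self.protein, self.premature_stop = translate_cds(trimmed)
            self.coding_complete = False

    @property
    def id(self) -> str:
        return self.name.render() if isinstance(self.name, AlleleName) else str(self.name)

    @property
    def locus(self) -> Optional[str]:
        return self.name.locus if isinstance(self.name, AlleleName) else None

    def mature_protein(self, signal_peptide: int = DEFAULT_SIGNAL_PEPTIDE) -> str:
        return self.protein[signal_peptide:]
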