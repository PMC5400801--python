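"""Readers and writers for the plain-text formats the pipeline touches.

FASTA/FASTQ go through Biopython; newick through scikit-bio.  Feature maps
are a GFF-like four-column TSV (seq_id, kind, start, end; 0-based half-open)
and genotype tables are TSV, both trivially diffable.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .alleles import FeatureMap


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Duplicate ids and empty records are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    recs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(recs, str(path), "fasta")


def read_fastq(path) -> list[tuple[str, str]]:
    """Read a FASTQ file into ``[(id, sequence), ...]`` (qualities dropped:
    the phasing stage is consensus-driven and does not use them)."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fastq")]


def write_fastq(records: Iterable[tuple[str, str]], path, quality: int = 40) -> None:
    """Write reads with a flat per-base quality."""
    recs = []
    for i, s in records:
        r = SeqRecord(Seq(s), id=i, description="")
        r.letter_annotations["phred_quality"] = [quality] * len(s)
        recs.append(r)
    SeqIO.write(recs, str(path), "fastq")


def load_feature_map(path, seq_id: str | None = None) -> FeatureMap | dict[str, FeatureMap]:
    """Load feature maps from a TSV (seq_id, kind, start, end).

    Returns the map for *seq_id* when given, else a dict of all maps.
    Interval validity (sorted, contiguous, non-overlapping) is enforced by
    :class:`FeatureMap`.
    """
    rows: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sid, kind, start, end = line.split("\t")
            rows.setdefault(sid, []).append((kind, int(start), int(end)))
    maps = {sid: FeatureMap(feats) for sid, feats in rows.items()}
    if seq_id is not None:
        return maps[seq_id]
    return maps


def write_feature_map(maps: dict[str, FeatureMap], path) -> None:
    with open(path, "w") as fh:
        for sid, fmap in maps.items():
            for f in fmap:
                fh.write(f"{sid}\t{f.kind}\t{f.start}\t{f.end}\n")


def write_newick(tree: TreeNode) -> str:
    """Render a tree as a newick string with branch lengths."""
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def read_newick(text: str) -> TreeNode:
    return TreeNode.read(_io.StringIO(text), format="newick")


GENOTYPE_COLUMNS = ["sample", "region", "allele", "gene_count", "flags", "evidence"]


def write_genotype_table(rows: list[dict], path) -> None:
    """Write one row per validated allele call."""
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=GENOTYPE_COLUMNS, delimiter="\t")
        w.writeheader()
        for row in rows:
            w.writerow({k: row.get(k, "") for k in GENOTYPE_COLUMNS})


def read_genotype_table(path) -> list[dict]:
    with open(path, newline="") as fh:
        return [dict(r) for r in csv.DictReader(fh, delimiter="\t")]
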