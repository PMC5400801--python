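"""Accounting over the published gorilla class I allele table.

The package ships a machine-readable transcription of the study's allele
table (allele name, gorilla (sub)species, number of carrier individuals,
GenBank accession, and whether the coding sequence was novel).  The
functions here reproduce the headline accounting: distinct full-length
alleles, coding-sequence groups per locus, novel groups, and the *Oko*
carrier fraction of the 35-animal cohort.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .alleles import AlleleName
from .nomenclature import collapse_to_coding_groups

COHORT_SIZE = 35

#: loci pooled in the per-locus accounting: the A-region genes are reported
#: together because they occupy alternative haplotypes of one region
LOCUS_CLASSES = {"A": "A+Oko", "Oko": "A+Oko", "B": "B", "C": "C"}


def load_allele_table() -> pd.DataFrame:
    """The published allele table with parsed names."""
    with resources.files("mhcamp.data").joinpath(
            "gorilla_class1_alleles.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["parsed"] = df["allele"].map(AlleleName.parse)
    df["locus"] = df["parsed"].map(lambda n: n.locus)
    df["locus_class"] = df["locus"].map(LOCUS_CLASSES)
    df["novel_coding"] = df["novel_coding"].astype(bool)
    return df


def distinct_allele_count(df: pd.DataFrame | None = None) -> int:
    """Distinct full-length sequences = distinct accessions (a sequence
    shared between the two gorilla species was deposited once)."""
    df = load_allele_table() if df is None else df
    return df["accession"].nunique()


def coding_group_summary(df: pd.DataFrame | None = None) -> pd.DataFrame:
    """Per locus class: number of coding-sequence groups and novel groups."""
    df = load_allele_table() if df is None else df
    rows = []
    for locus_class, sub in df.groupby("locus_class"):
        items = [{"name": n, "accession": a, "novel": novel}
                 for n, a, novel in zip(sub["parsed"], sub["accession"],
                                        sub["novel_coding"])]
        groups = collapse_to_coding_groups(items)
        n_novel = sum(any(m["novel"] for m in g) for g in groups)
        rows.append({"locus_class": locus_class, "n_alleles": len(sub),
                     "n_coding_groups": len(groups),
                     "n_novel_groups": n_novel})
    return pd.DataFrame(rows).set_index("locus_class")


def novel_group_total(df: pd.DataFrame | None = None) -> int:
    return int(coding_group_summary(df)["n_novel_groups"].sum())


def carrier_count(locus: str, df: pd.DataFrame | None = None) -> int:
    """Individuals carrying any allele of *locus*, summed over the table's
    per-allele carrier counts."""
    df = load_allele_table() if df is None else df
    return int(df.loc[df["locus"] == locus, "n_individuals"].sum())


def oko_carrier_fraction(df: pd.DataFrame | None = None,
                         cohort: int = COHORT_SIZE) -> tuple[int, float]:
    """(carriers, percent to one decimal) of *Oko* in the cohort."""
    n = carrier_count("Oko", df)
    return n, round(100.0 * n / cohort, 1)
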