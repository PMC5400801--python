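"""Replicate concordance classification, discordance resolution, dropout
checks, Mendelian consistency and genotype assembly."""

import itertools

import numpy as np
import pytest

from mhcamp.alleles import FeatureMap
from mhcamp.phasing import ConsensusCall
from mhcamp.validation import (HAPLOTYPE_CAPACITY, DiscordanceReport,
                               GenotypeTable, assemble_genotypes,
                               check_allelic_dropout, check_mendelian,
                               classify_pair, compare_replicates,
                               resolve_single_bp)


def _template(n=300, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _call(seq, **kw):
    return ConsensusCall(sequence=seq, cluster_size=50, polish_coverage=50,
                         predicted_accuracy=1.0, **kw)


FEATURES = FeatureMap([("5'UTR", 0, 30), ("exon", 30, 120),
                       ("intron", 120, 180), ("exon", 180, 240),
                       ("3'UTR", 240, 300)])


class TestClassifyPair:
    def test_identical(self):
        t = _template(seed=1)
        rep = classify_pair(t, t, FEATURES)
        assert rep.cls == "identical" and not rep.positions

    def test_homopolymer_deletion_in_3utr(self):
        t = _template(seed=2)
        t = t[:250] + "AAAAAA" + t[256:]          # 6-A run in the 3'UTR
        other = t[:252] + t[253:]                  # 1-base deletion inside it
        rep = classify_pair(t, other, FEATURES)
        assert rep.cls == "homopolymer"
        assert rep.region == "3'UTR"

    def test_single_substitution_elsewhere(self):
        t = _template(seed=3)
        alt = "A" if t[60] != "A" else "C"
        other = t[:60] + alt + t[61:]
        rep = classify_pair(t, other, FEATURES)
        assert rep.cls == "single_bp"
        assert rep.region == "exon"

    def test_single_indel_outside_homopolymer_is_single_bp(self):
        t = "ACGTCG" * 50                           # no runs >= 4
        other = t[:100] + t[101:]
        rep = classify_pair(t, other)
        assert rep.cls == "single_bp"

    def test_many_differences_are_other(self):
        t = _template(seed=4)
        other = t[:50] + "A" * 6 + t[56:]
        rep = classify_pair(t, other, FEATURES)
        assert rep.cls == "other"

    def test_exhaustive_small_cases(self):
        """Engineered identical / homopolymer / single_bp / other cases all
        classify correctly."""
        base = "ACGTC" * 20 + "AAAAAA" + "GTCAG" * 20
        run_start = 100
        cases = [
            (base, "identical"),
            (base[:run_start + 2] + base[run_start + 3:], "homopolymer"),
            (base[:run_start + 1] + "A" + base[run_start + 1:], "homopolymer"),
            (base[:10] + ("C" if base[10] != "C" else "G") + base[11:],
             "single_bp"),
            (base[:10] + base[11:], "single_bp"),       # non-run deletion
            (base[:10] + "TT" + base[12:] if base[10:12] != "TT" else
             base[:10] + "GG" + base[12:], "other"),
        ]
        for other, expected in cases:
            assert classify_pair(base, other).cls == expected, expected


class TestCompareReplicates:
    def test_matching_and_dropout_flag(self):
        t1, t2 = _template(seed=5), _template(seed=6)
        rep1 = [_call(t1), _call(t2)]
        rep2 = [_call(t1)]
        reports, dropouts = compare_replicates(rep1, rep2)
        assert len(reports) == 1 and reports[0].cls == "identical"
        assert dropouts == [(1, 1)]

    def test_deletion_vs_two_bases_case(self):
        """One replicate collapsed two near-identical alleles into one
        consensus with a deletion; the other separated them."""
        t = _template(seed=7)
        with_del = t[:80] + t[81:]
        alt = "A" if t[80] != "A" else "C"
        variant = t[:80] + alt + t[81:]
        reports, dropouts = compare_replicates(
            [_call(with_del)], [_call(t), _call(variant)])
        assert reports[0].cls == "single_bp"
        assert len(dropouts) == 1


class TestResolveSingleBp:
    def _setup(self, seed=8):
        ref = _template(seed=seed)
        pos = 150
        b1 = "A" if ref[pos] not in "A" else "G"
        b2 = "C" if b1 != "C" else "T"
        v1 = ref[:pos] + b1 + ref[pos + 1:]
        v2 = ref[:pos] + b2 + ref[pos + 1:]
        return ref, pos, v1, v2

    def test_two_alleles_accepted_with_corroboration(self):
        ref, pos, v1, v2 = self._setup()
        reads1 = [v1] * 44 + [v2] * 56
        reads2 = [v1] * 42 + [v2] * 58
        report = DiscordanceReport(pair=(0, 0), cls="single_bp")
        cohort = {"other1": {v1}, "other2": {v2}}
        out = resolve_single_bp(report, reads1, reads2, ref, cohort, "carlos")
        assert out.resolution == "resolved_by_minor_variant"
        assert {out.sequence, *out.extra_sequences} == {v1, v2}

    def test_below_threshold_unresolved(self):
        ref, pos, v1, v2 = self._setup(seed=9)
        reads1 = [v1] * 3 + [v2] * 97
        reads2 = [v1] * 2 + [v2] * 98
        report = DiscordanceReport(pair=(0, 0), cls="single_bp")
        out = resolve_single_bp(report, reads1, reads2, ref,
                                {"o": {v1, v2}}, "s")
        assert out.resolution == "unresolved"

    def test_no_corroboration_unresolved(self):
        ref, pos, v1, v2 = self._setup(seed=10)
        reads1 = [v1] * 44 + [v2] * 56
        reads2 = [v1] * 42 + [v2] * 58
        report = DiscordanceReport(pair=(0, 0), cls="single_bp")
        out = resolve_single_bp(report, reads1, reads2, ref, {}, "s")
        assert out.resolution == "unresolved"


class TestAllelicDropout:
    @pytest.mark.parametrize("f1,f2,expected", [
        ((0.439, 0.561), (0.419, 0.581), "consistent"),
        ((0.319, 0.681), (0.310, 0.690), "consistent"),
        ((0.45, 0.55), (0.05, 0.95), "dropout_suspect"),
    ])
    def test_replicate_frequency_agreement(self, f1, f2, expected):
        assert check_allelic_dropout(f1, f2) == expected

    def test_low_depth_indeterminate(self):
        assert check_allelic_dropout((0.4, 0.6), (0.4, 0.6),
                                     depths=(30, 400)) == "indeterminate"


class TestMendelian:
    def test_trio_consistent_shared_alleles(self):
        child = {"C": ["c1", "c2"]}
        mother = {"C": ["c1", "c3"]}
        father = {"C": ["c2", "c4"]}
        out = check_mendelian(child, mother, father)
        assert out["C"]["status"] == "consistent"
        assert out["C"]["origin"] == {"c1": "maternal", "c2": "paternal"}

    def test_allele_absent_from_both_parents_violation(self):
        out = check_mendelian({"C": ["c9", "c1"]}, {"C": ["c1", "c2"]},
                              {"C": ["c3", "c4"]})
        assert out["C"]["status"] == "violation"

    def test_allele_in_both_parents_is_either(self):
        out = check_mendelian({"C": ["c1", "c2"]}, {"C": ["c1", "c2"]},
                              {"C": ["c1", "c3"]})
        assert out["C"]["status"] == "consistent"
        assert out["C"]["origin"]["c1"] == "either"

    def test_dyad_checks_only_available_parent(self):
        out = check_mendelian({"C": ["c1", "c9"]}, None, {"C": ["c1", "c2"]})
        assert out["C"]["status"] == "consistent"   # c9 attributed to mother

    def test_missing_both_parents_indeterminate(self):
        out = check_mendelian({"C": ["c1"]}, None, None)
        assert out["C"]["status"] == "indeterminate"

    def test_haplotype_capacity_respected(self):
        # C region carries one gene per haplotype: three distinct alleles
        # cannot all come from one parent pair with capacity 1 per side
        out = check_mendelian({"C": ["c1", "c2", "c3"]},
                              {"C": ["c1", "c2", "c3"]},
                              {"C": ["c1", "c2", "c3"]})
        assert out["C"]["status"] == "violation"

    def test_exhaustive_three_allele_enumeration(self):
        """All trio configurations over a 3-allele single-gene locus: the
        checker flags exactly the transmissions impossible under biparental
        inheritance of the distinct validated calls (one allele per
        haplotype at a one-gene region)."""
        genotypes = list(itertools.combinations_with_replacement("xyz", 2))

        def brute_force(child, mother, father):
            distinct = sorted(set(child))
            if len(distinct) == 1:
                a = distinct[0]
                return a in mother or a in father
            a, b = distinct
            return (a in mother and b in father) or \
                   (b in mother and a in father)

        for child, mother, father in itertools.product(genotypes, repeat=3):
            expected = brute_force(child, mother, father)
            got = check_mendelian({"C": list(child)}, {"C": list(mother)},
                                  {"C": list(father)})["C"]["status"]
            assert (got == "consistent") == expected, (child, mother, father)


class TestAssembleGenotypes:
    def test_three_b_alleles_imply_two_genes(self):
        table = assemble_genotypes({
            ("S1", "B"): [("b1", "both_replicates"),
                          ("b2", "both_replicates"),
                          ("b3", "both_replicates")]})
        assert table.gene_count("S1", "B") == 2

    def test_four_a_region_alleles(self):
        table = assemble_genotypes({
            ("S1", "A"): [(a, "both_replicates")
                          for a in ("a1", "a2", "y1", "y2")]})
        assert table.gene_count("S1", "A") == 2

    def test_single_allele_flagged_homozygous(self):
        table = assemble_genotypes({("S1", "B"): [("b1", "both_replicates")]})
        assert "homozygous" in table.of_sample("S1", "B")[0].flags

    def test_phasing_inconsistency_rejected(self):
        calls = [(f"c{i}", "both_replicates") for i in range(5)]
        with pytest.raises(ValueError, match="phasing"):
            assemble_genotypes({("S1", "C"): calls})


class TestSimulatedPedigreeConsistency:
    def test_simulated_trios_never_violate_mendelian_rules(self, allele_db):
        """Cross-module property: trio children built by haplotype draws
        from their parents are Mendelian-consistent at every region."""
        from mhcamp.simulate import sample_population
        db, meta = allele_db
        for seed in range(5):
            truth = sample_population(db, meta, n_samples=9, n_trios=2,
                                      n_dyads=1, seed=seed)
            for child, mother, father in truth.pedigree:
                if mother is None and father is None:
                    continue
                out = check_mendelian(
                    {r: list(set(ids))
                     for r, ids in truth.genotypes[child].items()},
                    ({r: list(set(ids))
                      for r, ids in truth.genotypes[mother].items()}
                     if mother else None),
                    ({r: list(set(ids))
                      for r, ids in truth.genotypes[father].items()}
                     if father else None))
                assert all(v["status"] == "consistent"
                           for v in out.values()), (seed, child)
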