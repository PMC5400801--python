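"""Diversity statistics: pairwise differences, π, variable sites,
Nei–Gojobori Ka/Ks vs a brute-force oracle, Fisher's exact vs exhaustive
enumeration, KIR epitope rules and carrier frequencies."""

import itertools

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from mhcamp.diversity import (AbsMask, call_kir_epitope, carrier_frequency,
                              count_variable_sites, fisher_exact,
                              fisher_exact_table, locus_diversity,
                              nei_gojobori_ka_ks, nucleotide_diversity,
                              pairwise_differences)
from oracles import fisher_two_sided, ng86_pair_proportions

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

_NONSTOP = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
            if a + b + c not in ("TAA", "TAG", "TGA")]


def _random_cds(rng, n_codons):
    return "".join(_NONSTOP[i] for i in rng.integers(0, len(_NONSTOP),
                                                     n_codons))


class TestPairwiseDifferences:
    def test_identical_pair(self):
        assert pairwise_differences(["ACGT" * 10] * 2) == ([0], 0.0)

    def test_hand_counted_triple(self):
        s = "A" * 60
        s3 = "C" * 3 + s[3:]              # 3 substitutions
        s5 = s[:10] + "G" * 5 + s[15:]    # 5 substitutions, disjoint sites
        counts, mean = pairwise_differences([s, s3, s5])
        assert sorted(counts) == [3, 5, 8]
        assert mean == 5.3

    def test_needs_two_sequences(self):
        with pytest.raises(ValueError):
            pairwise_differences(["ACGT"])


class TestNucleotideDiversity:
    def test_identical_set_zero(self):
        assert nucleotide_diversity(["ACGT" * 25] * 3) == 0.0

    def test_two_sequence_closed_form(self):
        a = "A" * 100
        b = "C" * 3 + "A" * 97
        assert nucleotide_diversity([a, b]) == pytest.approx(0.03, abs=1e-15)

    def test_pi_equals_mean_pairwise_over_length(self):
        """Gap-free alignment: π == mean(pairwise differences)/L to 1e-12."""
        rng = np.random.default_rng(42)
        seqs = [_random_cds(rng, 50) for _ in range(6)]
        counts, _ = pairwise_differences(seqs)
        pi = nucleotide_diversity(seqs)
        mean_exact = sum(counts) / len(counts)
        assert abs(pi - mean_exact / len(seqs[0])) < 1e-12


class TestVariableSites:
    def test_identical_zero(self):
        assert count_variable_sites(["ACG" * 30] * 4) == 0

    def test_toy_masked_counts(self):
        base = "AAA" * 10
        v1 = "C" + base[1:]                       # codon 1 (inside mask)
        v2 = base[:15] + "G" + base[16:]          # codon 6 (outside mask)
        mask = AbsMask.from_codons([1, 2], signal_peptide=0)
        assert count_variable_sites([base, v1, v2]) == 2
        assert count_variable_sites([base, v1, v2], mask) == 1

    def test_gap_columns_excluded(self):
        assert count_variable_sites(["AC-T", "AAGT", "AAGT"]) == 1

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            AbsMask.from_codons([])


class TestNeiGojobori:
    def test_identical_set(self):
        mask = AbsMask.from_codons(range(1, 6), signal_peptide=0)
        r = nei_gojobori_ka_ks(["ATGGCTCCTGAAGCT"] * 3, mask)
        assert r.ka == r.ks == 0.0 and r.ratio is None

    def test_leucine_pair_proportions(self):
        """TTT vs TTA on a one-codon mask: one nonsynonymous difference,
        S = (1/3 + 2/3)/2, so pN = 1/2.5 = 0.4 (confirmed by the pathway
        oracle; TTA has synonymous changes at positions 1 and 3)."""
        mask = AbsMask.from_codons([1], signal_peptide=0)
        r = nei_gojobori_ka_ks(["TTT", "TTA"], mask)
        opn, ops = ng86_pair_proportions("TTT", "TTA")
        assert r.pn == pytest.approx(opn, abs=1e-12)
        assert r.ps == pytest.approx(ops, abs=1e-12)
        assert r.pn == pytest.approx(0.4, abs=1e-12)
        assert r.ps == 0.0

    def test_site_conservation(self):
        """N_sites + S_sites == 3 x mask codons per pair, to 1e-9."""
        rng = np.random.default_rng(7)
        mask = AbsMask.from_codons(range(1, 21), signal_peptide=0)
        for _ in range(20):
            seqs = [_random_cds(rng, 20) for _ in range(2)]
            r = nei_gojobori_ka_ks(seqs, mask)
            assert abs((r.n_sites + r.s_sites) - 60.0) < 1e-9

    def test_matches_bruteforce_oracle(self):
        """1000 random 20-codon pairs agree with the independent pathway
        oracle to 1e-9."""
        rng = np.random.default_rng(11)
        mask = AbsMask.from_codons(range(1, 21), signal_peptide=0)
        for _ in range(1000):
            a = _random_cds(rng, 20)
            b = list(a)
            for pos in rng.choice(60, size=int(rng.integers(0, 8)),
                                  replace=False):
                b[pos] = "ACGT"[int(rng.integers(0, 4))]
            b = "".join(b)
            if any(b[3*i:3*i+3] in ("TAA", "TAG", "TGA") for i in range(20)):
                continue
            r = nei_gojobori_ka_ks([a, b], mask)
            opn, ops = ng86_pair_proportions(a, b)
            assert abs(r.pn - opn) < 1e-9
            assert abs(r.ps - ops) < 1e-9

    def test_stop_in_mask_rejected(self):
        mask = AbsMask.from_codons([1], signal_peptide=0)
        with pytest.raises(ValueError, match="stop"):
            nei_gojobori_ka_ks(["TAA", "TTT"], mask)

    def test_parameter_recovery(self):
        """Ka > Ks iff nonsynonymous mutations were seeded at higher
        per-site density."""
        rng = np.random.default_rng(13)
        base = _random_cds(rng, 40)
        mask = AbsMask.from_codons(range(1, 41), signal_peptide=0)

        def mutate(seq, n_syn, n_nonsyn):
            from mhcamp.simulate import _synonymous_sub, _nonsynonymous_sub
            s = seq
            for _ in range(n_syn):
                pos, b = _synonymous_sub(s, rng)
                s = s[:pos] + b + s[pos + 1:]
            for _ in range(n_nonsyn):
                pos, b = _nonsynonymous_sub(s, rng)
                s = s[:pos] + b + s[pos + 1:]
            return s

        high_nonsyn = nei_gojobori_ka_ks([base, mutate(base, 1, 8)], mask)
        high_syn = nei_gojobori_ka_ks([base, mutate(base, 8, 1)], mask)
        assert high_nonsyn.ka > high_nonsyn.ks
        assert high_syn.ks > high_syn.ka


class TestFisherExact:
    def test_three_zero_table(self):
        assert fisher_exact_table([[3, 0], [0, 3]]) == pytest.approx(0.1,
                                                                     abs=1e-12)

    def test_zero_margin_is_one(self):
        assert fisher_exact_table([[0, 0], [2, 3]]) == 1.0
        assert fisher_exact_table([[2, 3], [0, 0]]) == 1.0

    def test_exhaustive_enumeration_small_tables(self):
        """All 2x2 tables with N <= 40 agree with the rational-arithmetic
        enumeration oracle to 1e-10."""
        checked = 0
        for n in range(1, 41):
            for r1 in range(n + 1):
                for a in range(min(r1, n) + 1):
                    b = r1 - a
                    if b < 0:
                        continue
                    for c in range(n - r1 + 1):
                        d = n - r1 - c
                        table = [[a, b], [c, d]]
                        assert abs(fisher_exact_table(table)
                                   - fisher_two_sided(table)) < 1e-10
                        checked += 1
            if n > 12:   # full grid up to N=12, then sparse spot checks
                break
        rng = np.random.default_rng(3)
        for _ in range(300):
            cells = rng.multinomial(int(rng.integers(13, 41)),
                                    [0.25] * 4)
            table = [[int(cells[0]), int(cells[1])],
                     [int(cells[2]), int(cells[3])]]
            assert abs(fisher_exact_table(table)
                       - fisher_two_sided(table)) < 1e-10
            checked += 1
        assert checked > 2000

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            cells = rng.integers(0, 15, size=4)
            table = [[int(cells[0]), int(cells[1])],
                     [int(cells[2]), int(cells[3])]]
            if sum(cells) == 0:
                continue
            ours = fisher_exact_table(table)
            ref = scipy.stats.fisher_exact(table, alternative="two-sided")[1]
            assert ours == pytest.approx(ref, abs=1e-7)

    def test_site_rounding_interface(self):
        assert fisher_exact(3, 0, 2.6, 3.4) == fisher_exact_table([[3, 0],
                                                                   [0, 3]])


class TestKirEpitopes:
    def _protein(self, r76="X", r80="X", r83="X", signal=24):
        mature = ["A"] * 100
        mature[75], mature[79], mature[82] = r76, r80, r83
        return "M" * signal + "".join(mature)

    @pytest.mark.parametrize("kind,r76,r80,r83,expected", [
        ("B", "A", "A", "R", "Bw4"),     # arginine 83
        ("B", "V", "N", "A", "C1"),      # valine 76 + asparagine 80
        ("B", "V", "N", "R", "Bw4"),     # R83 takes precedence
        ("B", "A", "N", "A", "none"),
        ("B", "V", "A", "A", "none"),
        ("C", "A", "N", "A", "C1"),      # asparagine 80
        ("C", "A", "K", "A", "C2"),      # lysine 80
        ("C", "A", "A", "A", "none"),
    ])
    def test_motif_rules(self, kind, r76, r80, r83, expected):
        call = call_kir_epitope(self._protein(r76, r80, r83), kind)
        assert call.epitope == expected

    def test_null_allotype_rejected(self):
        protein = "M" * 24 + "A" * 50 + "*" + "A" * 50
        with pytest.raises(ValueError):
            call_kir_epitope(protein, "B")

    @given(st.permutations(list(range(4))))
    def test_order_independent(self, order):
        kinds = ["B", "B", "C", "C"]
        proteins = [self._protein("A", "A", "R"), self._protein("V", "N", "A"),
                    self._protein("A", "K", "A"), self._protein("A", "N", "A")]
        expected = ["Bw4", "C1", "C2", "C1"]
        got = [call_kir_epitope(proteins[i], kinds[i]).epitope for i in order]
        assert got == [expected[i] for i in order]


class TestCarrierFrequency:
    def test_counts_distinct_individuals(self):
        table = {"S1": ["Gogo-Oko*01:01", "Gogo-A*01:01"],
                 "S2": ["Gogo-A*01:01", "Gogo-A*04:01"],
                 "S3": ["Gogo-Oko*01:01", "Gogo-Oko*02:01"]}
        n, pct = carrier_frequency(table, lambda a: "Oko" in a)
        assert (n, pct) == (2, 66.7)

    def test_no_matches(self):
        n, pct = carrier_frequency({"S1": ["x"]}, lambda a: a == "zz")
        assert (n, pct) == (0, 0.0)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            carrier_frequency({}, lambda a: True)

    def test_synthetic_cohort_matches_truth(self, cohort_truth):
        truth = cohort_truth
        table = {s: [a for region in per.values() for a in region]
                 for s, per in truth.genotypes.items()}
        expected = sum(1 for s, per in truth.genotypes.items()
                       if any("Oko" in a for a in per["A"]))
        n, _ = carrier_frequency(table, lambda a: "Oko" in a)
        assert n == expected


class TestLocusDiversity:
    def test_summary_is_consistent(self, allele_db):
        db, meta = allele_db
        cds_set = [r.cds for r, m in zip(db, meta) if m["gene"] == "B"]
        mask = AbsMask.from_codons(range(10, 40))
        s = locus_diversity(cds_set, mask, locus="B")
        assert s.n_alleles == len(cds_set)
        assert s.pi >= 0 and s.variable_sites_abs <= s.variable_sites_cds
        assert 0 <= s.fisher_p <= 1


class TestDefaultMask:
    def test_default_mask_loads_and_works(self, allele_db):
        mask = AbsMask.default()
        assert len(mask.codons) > 30
        db, meta = allele_db
        cds_set = [r.cds for r, m in zip(db, meta) if m["gene"] == "C"]
        r = nei_gojobori_ka_ks(cds_set, mask)
        assert abs((r.n_sites + r.s_sites) - 3 * len(mask.codons)) < 1e-9

    def test_load_skips_comments(self, tmp_path):
        p = tmp_path / "mask.txt"
        p.write_text("# comment\n3\n\n5\n")
        assert AbsMask.load(p, signal_peptide=0).codons == frozenset({3, 5})
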