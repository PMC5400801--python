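# mhcamp

Full-length MHC class I genotyping from long amplicon reads, with the
comparative analyses that typically follow: duplicate-amplicon haplotype
phasing and consensus validation, allele nomenclature with null-allele
detection, nucleotide-diversity and antigen-binding-site Ka/Ks
statistics, KIR-ligand epitope classification, and domain-by-domain
neighbor-joining phylogenetics.

The package targets the gorilla-like class I architecture: an A region
whose haplotypes carry either the classical *A* gene (± a *Y*-like
pseudogene) or the *Oko* gene, a B region with a second *B* locus on some
haplotypes, and a single-gene C region. It is built for researchers who
genotype nonhuman-primate (or other multigene-family) MHC from long
amplicons sequenced in duplicate and need every allele call to be
validated and auditable, and it ships a synthetic-study generator so the
whole pipeline is testable end-to-end against known truth without any
downloads.

## The core methods

* **Phasing** — subreads of one (sample, amplicon, replicate) are split
  into up to `k_max` allele haplotypes by greedy discriminating-column
  clustering (minor base frequency ≥ 0.2, depth-aware, homopolymer
  columns excluded), then each cluster is majority-polished with coverage
  capped at 500 and a predicted accuracy from per-column posteriors.
* **Validation** — replicate consensus pairs are classified
  identical / homopolymer / single-bp / other; single-bp discordances are
  re-analysed by a minor-variant pileup scan and accepted as two alleles
  only with replicate-consistent frequencies and cohort or pedigree
  corroboration; Mendelian trio checks respect haplotype gene content
  (gene absence is inheritable).
* **Nomenclature** — hierarchical names `prefix-locus*f1:f2:f3:f4[N]`
  where f2 separates proteins, f3 synonymous and f4 non-coding variants;
  premature stops/frameshifts get the `N` suffix.
* **Diversity** — π as the unweighted mean pairwise p-distance; variable
  sites; Nei–Gojobori Ka/Ks by stop-avoiding pathway counting on an
  explicit ABS codon mask with Jukes–Cantor correction; two-sided
  Fisher's exact test by exact hypergeometric enumeration;
  Bw4/C1/C2 epitopes from mature residues 76–83.
* **Phylogenetics** — TN93 distances, canonical NJ (consistent on
  additive matrices), column bootstrap, and per-segment trees with a
  nearest-neighbor mosaic report for suspected recombinants.

## Worked example

Simulate a small cohort, genotype it end-to-end, and compare against the
generator's truth table:

```python
from mhcamp.simulate import simulate_study, DESK_COVERAGE_RANGES
from mhcamp.pipeline import genotype_study, genotype_recovery

db, meta, truth, subreads = simulate_study(
    seed=11, n_samples=10, coverage_ranges=DESK_COVERAGE_RANGES)
result = genotype_study(subreads, db, meta, seed=1)

print(f"exact-genotype recovery: {genotype_recovery(result, truth):.3f}")
print(f"mean predicted consensus accuracy: "
      f"{100 * result.mean_predicted_accuracy:.5f}%")
for call in result.genotypes.of_sample("S001"):
    print(call.region, call.allele, call.evidence, call.flags)
```

prints

```
exact-genotype recovery: 1.000
mean predicted consensus accuracy: 99.99999%
A Gogo-Oko*03:01 both_replicates,db_exact []
A Gogo-A*01:02 both_replicates,db_exact []
A Gogo-Y*01:01:02 both_replicates,db_exact []
B Gogo-B*01:01:01:02 both_replicates,db_exact []
B Gogo-B*07:02 both_replicates,db_exact []
B Gogo-B*01:01:01:01 both_replicates,db_exact []
C Gogo-C*01:01:01:01 both_replicates,db_exact []
C Gogo-C*01:01:02 both_replicates,db_exact []
```

Every (sample, region) genotype of the ten samples matches the simulated
truth. Sample `S001` is informative on both structural fronts: its A
region carries an *Oko* allele on one haplotype and *A* + *Y* on the
other, and its three distinct B-region alleles (two `B*01` plus a
`B*07`) are the signature of a second *B* gene on one haplotype — the
`evidence` column records the decision path behind each call. The published-table accounting is equally direct:

```python
from mhcamp.published import coding_group_summary, oko_carrier_fraction
print(coding_group_summary())
print(oko_carrier_fraction())   # -> (16, 45.7)
```

## Command line

A thin CLI wraps the library: `mhcamp simulate`, `mhcamp genotype`,
`mhcamp validate`, `mhcamp diversity`, `mhcamp phylo`. Run
`mhcamp --help` for options.
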