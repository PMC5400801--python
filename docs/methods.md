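# Methods

`mhcamp` re-implements, at desk scale, a complete genotyping and
comparative-analysis workflow for full-length MHC class I genes sequenced
as long PCR amplicons in duplicate. This note documents the models, the
parameters that matter, the synthetic-data generator the tests run
against, and the numerical choices.

## The genotyping problem

Great-ape MHC class I regions are multigene families with
presence/absence variation between haplotypes. The package models three
amplicon groups of a gorilla-like class I region:

* **A region** — a haplotype carries either the classical *A* gene
  (optionally together with a *Y*-like pseudogene) or, on the alternative
  haplotype that lacks the *A* genomic block, the *Oko* gene. A diploid
  can therefore present up to four distinct A-region sequences in one
  amplicon (two *A* + two *Y*), or none at the *A* locus proper
  (*Oko*/*Oko* homozygotes).
* **B region** — every haplotype carries a *B* gene; some additionally
  carry a divergent second *B* locus (named in the ``B*07`` allele
  group), so individuals with three B-region alleles indicate two genes.
* **C region** — exactly one gene on every haplotype.

Each sample is amplified and sequenced twice; genotypes are *validated*,
not merely called: a sequence is reported only when both replicates
support it or an explicit, audited resolution path applies.

## Phasing and consensus polishing

Subreads of one (sample, amplicon, replicate) are clustered into allele
haplotypes by a greedy discriminating-column procedure:

1. build a draft consensus (iterated per-column majority seeded from the
   median-length read), projecting every read onto draft coordinates by
   global alignment (edlib);
2. find *discriminating columns*: a second base at frequency ≥ 0.2 with
   at least 5 supporting reads, at column depth ≥ min(50, 0.8 × reads in
   the cluster); columns inside or flanking homopolymer runs of length
   ≥ 4 are excluded, because long-read indel noise concentrates there;
3. split the cluster on the best such column, re-draft each side and
   recurse until no column splits or the per-amplicon haplotype budget
   `k_max` (A: 4, B: 3, C: 2) is reached;
4. discard clusters below 10 % of the replicate's reads as noise, then
   re-assign every read to its closest consensus and re-polish once.

Polishing is per-column majority with insertion handling, subsampled to a
coverage cap of 500 reads. The **predicted accuracy** is the mean
per-column posterior of the called base under a symmetric substitution
model (error rate 0.05); it equals 1.0 only when every polished column is
unanimous, and a non-unanimous column is clamped strictly below 1 so the
guarantee survives floating-point rounding. Ties break lexicographically
(A < C < G < T) and are counted as an accuracy penalty. Columns whose
majority is a deletion, or that almost no read covers (a draft artifact
of a seed read's trailing insertion), are dropped.

The minor-variant scan is a reference pileup: positions where at least
two variant classes (four bases + deletion) each reach frequency ≥ 0.2 at
depth ≥ 50 are reported with per-variant frequencies and depths;
frequencies at a position plus the remainder class sum to one.

With fewer than 25 reads a replicate is flagged low-coverage and queued
for repeat rather than phased.

## Replicate validation and genotype assembly

Consensus sequences are matched across replicates by edit distance and
each pair is classified: `identical`; `homopolymer` (all differences are
indels adjacent to runs ≥ 4 — resolved by preferring the replicate whose
sequence matches a known allele exactly, since run-length errors are
replicate-specific technology noise); `single_bp` (re-analysed by the
minor-variant scan of both replicates' raw reads, accepted as two alleles
only when both variants pass thresholds in both replicates *and* each
variant coding sequence is corroborated by another cohort sample or a
pedigree link); `other`. A consensus present in one replicate only, or
one side of a discordant pair, is still accepted when its full-length
sequence matches the allele database exactly — the database-backed
analogue of cohort corroboration; otherwise it is a dropout suspect.

Allelic dropout is excluded when the minor-variant frequency passes
threshold in both replicates and the replicate minor frequencies agree
within 0.15 (a package default; the underlying phenomenon, not the
cutoff, is what the validation literature documents).

Mendelian checks operate on the distinct validated calls per region
(dosage is not observable from calls alone): a trio is consistent when
the child's calls split into a maternal-compatible and a
paternal-compatible haplotype set respecting per-region haplotype gene
capacity (A: 2 genes/haplotype, B: 2, C: 1); gene absence (the *Oko*
haplotype) is thereby an inheritable state, dyads constrain only the
known parent, and an allele present in both parents is annotated
"either".

More than two distinct validated alleles in a region implies a second
gene; more than 2 × `k_max` is rejected as a phasing inconsistency.

## Nomenclature

Hierarchical names follow the HLA convention
(`prefix-locus*f1:f2[:f3[:f4]][N]`): field 2 separates proteins, field 3
synonymous coding variants, field 4 non-coding variants. A query is
matched to the same-locus database allele of minimal edit distance
(divergence ceiling 10 %), differences are partitioned by feature kind
and codon effect, and the name extends the matching field. A new allele
group (field 1) opens when the protein differs from every group member by
more than 5 residues — group boundaries are committee decisions in real
nomenclature, so this ceiling is an explicit, configurable package
convention, and batch naming sorts queries lexicographically by sequence
to make names a pure function of the input (real nomenclature is
first-come-first-served).

Null alleles (`N` suffix) carry a premature stop or a frameshift; stop
positions are reported in mature-protein numbering, i.e. after removal of
a signal peptide of 24 residues (the class I convention; configurable,
since per-locus signal peptide lengths vary in principle).

## Diversity statistics

* π — unweighted mean pairwise p-distance with pairwise gap deletion
  (alleles equally weighted; no population frequencies). On gap-free
  alignments π × L equals the mean pairwise difference exactly, which is
  asserted to 1e-12.
* Variable sites — columns with ≥ 2 observed bases; columns containing
  any gap are excluded (the common DnaSP convention).
* Ka/Ks on antigen-binding sites — Nei–Gojobori pathway counting
  restricted to an explicit codon mask (mature numbering). Per codon and
  position, the synonymous site fraction is computed over the non-stop
  single-base changes, so every codon contributes exactly three sites;
  multi-base codon differences average over the stop-avoiding mutational
  pathways (falling back to all pathways when every one is blocked).
  Rates are Jukes–Cantor corrected means over all unordered pairs;
  saturated proportions (p ≥ 3/4) report infinity rather than raising,
  and the uncorrected proportions are always reported alongside. The ABS
  site list is an explicit input; the package ships an editable default
  (`AbsMask.default()`, the classical peptide-binding-groove residues)
  but no hidden mask is load-bearing — every test uses an explicit list.
* Fisher's exact test — two-sided, summing hypergeometric probabilities
  ≤ the observed table's, with exact integer arithmetic so ties are
  handled deterministically. The 2×2 table is differences vs half-up
  rounded site totals within the mask, a package convention (tools differ
  and rarely document their construction).
* KIR epitopes — determined solely by mature residues 76–83: on MHC-B,
  R83 → Bw4, else V76∧N80 → C1; on MHC-C, N80 → C1, K80 → C2. Truncated
  (null) allotypes are not classified.

## Phylogenetics

Pairwise TN93 distances (base frequencies estimated from each pair,
pairwise gap deletion; saturation is a flagged error state, never NaN),
canonical neighbor-joining with a lowest-index tie-break (consistent on
additive matrices to 1e-9, asserted), and a nonparametric bootstrap (500
column resamples by default) reporting the percentage of replicates
containing each split of the full-data tree. Inside bootstrap replicates
a saturated pair falls back to the p-distance so a replicate never
aborts. Segment (domain-by-domain) trees use complete deletion within
each segment so segments are comparable; indel columns are excluded from
distances and reported as per-taxon binary presence characters; the
per-segment nearest neighbor of designated query taxa is the
recombination-mosaic readout. Breakpoint *discovery* is out of scope:
segments come from feature maps or user configuration.

## The synthetic-data generator

The generator is first-class, tested code; it defines the conditions
every downstream claim is measured under.

* **Gene architecture** — 8 exons with the canonical class I lengths
  (73, 270, 276, 276, 117, 33, 48, 5 nt; CDS 1098 nt = 366 codons),
  introns of 70–130 nt and short UTRs, giving ~2 kb amplicons. This is
  shorter than real class I amplicons (~3–4 kb, driven by longer introns)
  but preserves every structural property the pipeline exercises.
* **Allele database** — per locus: the ancestor, an intron-only variant
  (3 non-coding substitutions), a synonymous variant, a nonsynonymous
  variant (2 coding substitutions) and extra mixed variants; the A locus
  adds a null allele whose single nonsense substitution (TGG→TGA) sits at
  mature codon 257, inside exon 4. Related genes within a region (*Oko*,
  *Y*, the second *B* locus) diverge from the region ancestor by ~2.5 %
  with codon-aware coding changes. Homopolymer runs (4–7 nt) are seeded
  into non-coding sequence only, clamped at feature boundaries.
* **Population** — haplotypes draw gene content per the region rules
  (*Oko*-haplotype probability 0.26, chosen so the expected *Oko* carrier
  fraction is near the published 45.7 %; *Y* on 60 % of *A* haplotypes;
  second *B* locus on 25 % of haplotypes) and allele identity from a
  symmetric Dirichlet frequency law drawn once per run. Trio children
  receive one haplotype from each parent; dyads one from the known
  father.
* **Reads** — per replicate, coverage is uniform in a per-region range
  and reads are multinomial over the gene copies present with a
  Dirichlet(20) amplification jitter. The error model applies
  substitutions (1 %), single-base duplications (0.5 %) and deletions
  (0.5 %) per base, the indel rates multiplied by 3 inside homopolymer
  runs ≥ 4 — matching how run-length errors present in real long reads —
  plus 2 % read truncation. No per-base quality model is simulated
  (qualities are flat) and the pipeline never reads them. The published
  study gives no raw subread error rates, so these defaults are package
  choices, not calibrated claims.

**What passing tests show — and don't.** The generator produces
substitution-structured allele differences, haplotype-structured gene
content, realistic depth imbalance and homopolymer-biased indel noise; it
does not simulate PCR chimeras/recombinants, pass-number-dependent
quality, barcode cross-talk or reference-biased primer effects. Recovery
rates measured here therefore bound the algorithmic behaviour of the
pipeline, not the wet-lab failure modes of a real run.

**Problem sizes.** The per-amplicon coverage default mirrors the
published subread ranges (A: 264–1414, B: 206–1464, C: 500–1000), at
which depth thresholds such as the 500-read polishing cap are meaningful.
The simulation-based tests and the acceptance script run the same
pipeline at a desk-scale law of 60–120 reads per amplicon and replicate —
a deliberately *harder* setting for phasing (less evidence per
discriminating column), chosen to keep whole-study runs fast; results at
the published depths can be reproduced by passing the default coverage
law.

A study with two B07-bearing haplotypes carries four distinct B-region
alleles while per-replicate phasing is budgeted at `k_max = 3`; the
validation layer can still assemble all four via the corroboration path,
but this configuration is the main residual source of imperfect genotype
recovery under defaults.

## Known limitations

* Phasing splits on substitution columns only; two alleles differing
  exclusively by an indel are not separated (the generator's variant
  classes are substitution-structured, matching the dominant variation in
  the target system).
* Corroboration in the end-to-end pipeline uses the known-allele
  database; the paired minor-variant + cohort-sequence resolution is
  exposed and tested as its own operation.
* Naming reproduces the field semantics of the hierarchical fields, not
  committee history; group boundaries follow the protein-distance
  ceiling.
* The mean-of-pairs Ka/Ks and the Fisher table construction are stated
  conventions; other tools make different (often undocumented) choices.
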