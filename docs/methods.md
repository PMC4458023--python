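# Methods

This note documents the models and procedures behind `pinepop`, the choices
made where the design was genuinely open, and what the synthetic data do and
do not demonstrate.

## Pipeline overview

All analyses share one coordinate frame: a reference transcriptome (contig
FASTA) against which every sample's SNPs were called. The pipeline stages, in
run order:

1. optional contig retention filters (ORF presence, exclusion-id list) and
   assembly summary statistics;
2. per-sample VCF parsing into sets of biallelic SNP keys
   (contig, 1-based position, ref, alt);
3. per-species SNP unions, pairwise common/unique tables, and the spacing
   filter over the merged SNP set;
4. per-sample consensus construction and concatenation over the contigs
   common to, and polymorphic in, all samples;
5. diversity statistics per species; 6. PCoA, group-level TN93/UPGMA, and
   permutation-tested pairwise Fst.

Internally all coordinates are 0-based half-open; the 1-based VCF convention
is converted exactly at the I/O boundary.

## Assembly statistics and filters

* **N50** is defined as the largest contig length L such that contigs of
  length ≥ L jointly contain at least half of the total bases. When the
  cumulative sum hits exactly half, the larger qualifying length is chosen.
  This definition provably coincides with the conventional sorted-cumulative
  scan (property-tested against a brute-force candidate search).
* **Length cutoff**: "contigs over 100" is interpreted inclusively
  (length ≥ 100 bp), the common assembler-report convention; a strict mode
  is available (`length_inclusive=False`).
* **GC percent** is computed over A/C/G/T bases only; all other characters
  are reported separately as a non-ATGC count.
* **ORF filter**: a contig is retained if any of its six reading frames
  contains ATG followed by at least `min_orf_aa` codons (start included)
  terminated by a stop codon inside the contig. Default `min_orf_aa = 100`
  (a conventional minimum-protein length); requiring the start codon is
  configurable (`require_start=False` accepts stop-free runs), since
  assembler fragments may truncate 5' ends. The pipeline applies no ORF
  filter by default: the synthetic reference is already a "final" contig
  set, and random sequence would be decimated by an ORF requirement for
  reasons unrelated to anything this package measures.

## SNP panel semantics

* **Variant identity** is the full key (contig, position, ref, alt):
  same-position different-alt calls are different SNPs. This is the stricter
  and exactly reproducible convention for cross-species comparisons.
* **Spacing filter** (default `min_gap = 50` bp): a SNP survives only if no
  other SNP in the merged, all-species set lies within `min_gap` bp on the
  same contig. Both members of a close pair are removed (neighbour
  exclusion, not greedy thinning) — the filter models a genotyping-assay
  requirement for clean flanking sequence on *both* sides of every kept SNP,
  so a kept SNP may not serve as the excuse to keep its neighbour. The
  boundary |Δpos| = min_gap counts as too close. Contig ends are ignored: a
  SNP 10 bp from an end can survive; flank availability for a specific assay
  is an assay-design concern outside this package. The output is
  inclusion-maximal under this rule and independent of input order.
* **Mapping percentages** are uniformly 100 × part / total reads, rounded to
  two decimals; the merged row uses summed counts. (Published tables do not
  always state their denominators; total reads is the one choice that
  reproduces the values that are arithmetically checkable.)

## Merged alignment

Consensus sequences substitute each sample's variants into the reference:
hom-alt sites take the alt base; het sites take the two-base IUPAC code by
default (policies "alt" and "ref" exist for pipelines that need haploidized
sequences). Contig selection requires at least one variant in *every* sample
("all samples", not "all species" — with per-species selection a
monomorphic-in-one-sample contig would silently deflate that sample's
divergence). Sequences are reference-projected, hence positionally aligned
by construction; no alignment algorithm runs.

## Diversity statistics

π is the mean over sequence pairs of (differences / compared sites), i.e.
per-pair pairwise-deletion denominators; with complete data this equals
differences/L. Tajima's D uses the standard a₁…e₂ constants; D is reported
as undefined (NaN) when S = 0 or n < 4 (the variance-based normalization is
not reliable below four sequences, which also matches how small groups are
conventionally reported).

**Ambiguity policy.** Two treatments of IUPAC heterozygote codes:

* `missing` — pairwise deletion; S and singletons counted over unambiguous
  bases only. Simple and conservative, but with diploid consensus input it
  is biased: a singleton heterozygote is invisible, and π conditional on
  both sequences being homozygous underestimates heterozygosity at
  unbalanced frequencies.
* `expand` — a heterozygote contributes both alleles. The difference between
  two samples at a site is the mean of the 2×2 allele comparisons (two
  identical heterozygotes differ by 0.5, which is exactly the probability
  that one random allele from each differs); S and singletons are counted on
  the expanded allele multiset; Tajima constants use 2N chromosomes. By an
  exchangeability argument this estimator is unbiased for haplotype π, so
  θ-recovery tests are only meaningful under this policy.

Library functions default to `missing` (the conservative choice for data of
unknown provenance); the pipeline's diversity report defaults to `expand`
because its input is known to be IUPAC-coded diploid consensus.

The per-species report adds a Total/Average row: pooled N, L, S and
singletons over all samples, with π and D averaged across species (D over
species where defined). Singletons at multiallelic columns count each
allele seen once, except that a column where *every* observed allele is
unique contributes one less (a two-sequence difference is one mutation).

## Relationships and differentiation

* **TN93** distances use the closed form with base frequencies estimated
  from the two sequences pooled over their comparable (both-unambiguous)
  sites. Saturated pairs (any log argument ≤ 0) are flagged undefined rather
  than raising; zero-coefficient terms are taken as their zero limit when
  the corresponding observed proportion is also zero. With equal base
  frequencies and substitutions in equal-rate proportions the formula
  reduces to Jukes–Cantor (regression-tested to 1e-9).
* **UPGMA** runs on group-level distances: the mean TN93 over all
  inter-group sequence pairs. Merge height is half the inter-cluster
  distance, so trees are exactly ultrametric; ties break on the smallest
  (row, col) index pair, making output deterministic and order-invariant up
  to rotation.
* **PCoA** is the Gower transform B = −½·J·D²·J on squared distances,
  eigendecomposed; coordinates are eigenvectors scaled by √λ for positive λ.
  Negative eigenvalues (possible for non-Euclidean inputs) are reported but
  yield no coordinates. Axis signs are fixed so each axis's largest-magnitude
  loading is positive. The input is the sample pairwise *difference-count*
  matrix, so axis units are base differences.
* **Fst** is the two-population Weir–Cockerham estimator as a ratio of sums
  across the pair's biallelic segregating sites, each diploid contributing
  two alleles (heterozygotes via IUPAC expansion). Negative estimates are
  reported as computed. Significance: whole samples (both alleles together)
  are shuffled between the two species only; p = (#{permuted ≥ observed}+1) /
  (n_permutations+1), so p can never be 0. Hudson's estimator was considered
  as an alternative ratio but Weir–Cockerham's explicit finite-sample
  correction matters at these sample sizes (3–5 diploids); with very few
  samples per group, permutation granularity bounds the attainable p (3 vs 3
  samples: 20 assignments, minimum two-sided mass 0.1) — a real limitation
  of small-panel studies that the package reproduces rather than hides.
* **Outlier exclusion**: a configurable sample list is excluded from UPGMA
  and Fst but *not* from PCoA — PCoA is the diagnostic that identifies the
  outlier, so it must keep every sample.

## Synthetic species complex

The generator produces study-condition data, not pine evolution. Model:

* **Reference**: `n_contigs` i.i.d. uniform-composition contigs; lengths
  gamma-distributed (shape 4) around `contig_length_mean`, floored at
  `contig_length_min`. Defaults 200 × ~1000 bp — large enough that every
  statistic has hundreds-to-thousands of informative sites, small enough
  that the full pipeline runs in seconds.
* **Within-species polymorphism**: segregating-site count
  S ~ Binomial(L, θ·a₁(2N)), placed uniformly without positional collisions;
  derived-allele counts from P(i) ∝ 1/i^skew on 1…2N−1; derived alleles
  assigned to chromosomes by sampling without replacement. Under skew = 1
  the expected per-site π contribution is exactly 1/a₁, so E[π] = θ and
  Watterson's S/(L·a₁) recovers θ — both are tested. Defaults θ = 0.005
  per site (the magnitude reported for conifer transcriptomes) and
  skew = 1.5, which yields a mildly negative Tajima's D as observed in
  range-expanding trees.
* **Shared polymorphism**: `shared_poly_fraction` (default 0.3) of the mean
  per-species site target segregates in *all* species with a common alt
  allele and independent per-species frequencies. Sharing among subsets of
  species is not modelled; shared sites add equally to every pair's common
  count and therefore never disturb the divergence-driven ordering.
* **Divergence**: the pairwise fixed-difference-rate matrix is fitted with a
  UPGMA tree and per-branch site counts are drawn as Binomial(L, branch
  length); each site is fixed derived in the branch's clade. An ultrametric
  matrix is reproduced exactly in expectation; otherwise its ultrametric
  projection is. The default matrix (0.006 outgroup-vs-trio, 0.0015–0.002
  within trio) mirrors a complex whose members are mutually much closer than
  any is to the outgroup. The reference plays the root haplotype, so every
  species carries fixed differences from it — as when the reference is a
  single sequenced individual.
* **Admixed outlier**: one designated sample's genotypes are re-drawn with
  each haplotype's species-of-origin sampled per contig between two parent
  species (default weight 0.5). This reproduces, qualitatively, a
  between-cluster PCoA outlier and inflated shared SNPs with the second
  parent — and the tests demonstrate that the cohesion ordering only holds
  when the outlier is excluded, which is precisely why such exclusion is
  standard practice.
* **Determinism**: a single seeded generator drives all draws in fixed
  order; identical config + seed gives byte-identical FASTA/VCF/TSV output.

What the generator does **not** emulate: linkage and recombination (sites
are independent), coalescent genealogies (frequencies are i.i.d. across
sites), sequencing or genotype-calling error, indels or multiallelic sites,
expression-dependent coverage, or missing data. Passing tests therefore show
that the estimators and the pipeline recover the parameters of this
idealized process at realistic magnitudes — not that they are robust to the
error structure of real RNA-seq variant calls.

## Numerical and reporting choices

* Tajima constants evaluated in double precision directly from their
  definitions (property-tested against an independent implementation to
  1e-12 over n = 4…30, S = 1…50).
* PCoA eigenvalues below 1e-10·|λ_max| are treated as zero.
* The run log is timestamp-free so that the determinism contract covers
  every output byte, log included.
* Pipeline problem sizes (200 contigs, 17 samples, 200–1000 permutations,
  20-replicate recovery checks) were chosen so the full test suite and the
  acceptance script each complete in well under a minute of compute while
  keeping every statistical check's sampling error far from its assertion
  threshold.

## Known limitations

* Fst is pairwise Weir–Cockerham only; no AMOVA variance decomposition,
  no hierarchical structure.
* TN93 group distances fail loudly (rather than imputing) when any sequence
  pair is saturated.
* The spacing filter's neighbour-exclusion reading is one of two defensible
  interpretations of "50 bp flanking on either side"; greedy thinning would
  keep more SNPs. The gap and the rule are configurable and documented.
* Sharing of polymorphism among species subsets (rather than all species) is
  not modelled, so the generator cannot produce incomplete lineage sorting
  patterns.
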