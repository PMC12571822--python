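# Methods

## Overview

`gchap` analyses gene-CDS-haplotype (gcHap) diversity in panels of inbred
rice accessions. A gcHap is a distinct combination of SNP alleles inside a
gene's coding sequence; because cultivated rice is predominantly selfing,
each accession carries essentially one CDS haplotype per gene, and the
panel-wide frequency spectrum of these haplotypes summarises the standing
allelic diversity at the locus. The pipeline calls haplotypes from a VCF +
GFF3 pair, quantifies within- and between-population diversity, compares
landraces (LAN) with modern varieties (MV) to measure breeding-driven
shifts, associates major haplotypes with agronomic traits, and builds
mutation-step haplotype networks.

## Haplotype calling

For each gene, the CDS SNP set is the intersection of the VCF's SNP
positions with the gene's CDS intervals (1-based inclusive on both sides;
strand is recorded but does not reorder sites). Accessions are grouped by
exact allele-vector identity; groups are ranked by descending panel-wide
count (ties broken by first occurrence in accession order) and named
`Hap1`, `Hap2`, ... Naming is global, so `Hap1` denotes the same CDS
sequence in every population table.

Heterozygous or missing genotypes conflict with the one-haplotype-per-
accession model. Two policies are provided:

* `exclude` (default): an accession with any het/missing call at a CDS SNP
  of the gene is dropped from that gene. This is the strictest reproducible
  rule and keeps every reported frequency a ratio of observed haplotypes.
* `ref-fill`: het/missing calls are replaced by the reference allele.
  Useful for sensitivity analysis; not the default because it invents
  sequence content.

Frequency denominators are always the non-excluded accessions of the
subset under consideration, so counts sum to the analysed sample.

A *major* gcHap has panel-wide frequency >= 1% (threshold configurable;
the boundary is inclusive). The *favorable* haplotype at a locus is the
highest-frequency major haplotype and the *unfavorable* one the
lowest-frequency major haplotype; on frequency ties the favorable side
takes the lower Hap rank and the unfavorable side the higher, so the pair
is always distinct. Loci with fewer than two major haplotypes are flagged
not-analyzable rather than silently skipped.

## Diversity statistics

With haplotype frequencies `p_i` (sum 1) in a population of `n`
non-excluded accessions:

* **Shannon equitability** `E_H = (-sum p_i ln p_i) / ln S`, where `S` is
  the count of haplotypes with `p_i > 0`. Natural logs are used (the base
  cancels in the ratio); `E_H := 0` when `S = 1`, resolving the 0/0 case so
  monomorphic genes report a defined value. `E_H` depends only on the
  frequency vector, never on `n`.
* **Nei's normalised identity**
  `I_Nei = sum x_i y_i / sqrt(sum x_i^2 * sum y_i^2)` over the union of the
  two populations' haplotype sets (zero-filled). 1 means identical
  composition; values below ~0.35 indicate strong differentiation.
* **Haplotype Fst** is Nei's G_ST on haplotype frequencies with
  sample-size weights: `H_S = sum_k w_k (1 - sum_i p_ki^2)` with
  `w_k = n_k / n`, `H_T = 1 - sum_i pbar_i^2`, `Fst = (H_T - H_S) / H_T`,
  and 0 when `H_T = 0`. The estimator name is stamped into the output
  table (`estimator` column) because "F-statistic" alone is ambiguous;
  Weir-Cockerham and AMOVA variants would differ in small samples.

## Landrace-vs-modern-variety shift

Per gene and population group (Xian or Geng), `E_H` and the haplotype
count `gcHapN` are computed separately on the LAN and MV subsets, with the
deltas MV - LAN. Mean rows are plain arithmetic means of the per-gene
values; the delta mean is kept at full precision alongside 3-4 decimal
display values, since mixed precision is how such tables are conventionally
printed.

Significance of the `E_H` difference comes from a two-sided
label-permutation test: under the null of no LAN/MV structuring the class
labels are exchangeable, so labels are reshuffled (subset sizes fixed)
and `p = (1 + #{|dE_H*| >= |dE_H|}) / (1 + reps)`. Defaults: 10,000
replicates, seed 1. The input is canonicalised to a sorted pooled
haplotype-index vector, so the p-value depends only on (seed, reps, data),
not on accession order. Significance bands: `**` for p < 0.0001, `*` for
p < 0.05, `ns` otherwise. The artificial-selection label is `up` exactly
when the test is significant — it marks *evidence of selection having
re-shaped the spectrum*, not the direction of the diversity change (a
significantly negative delta is still labelled `up`).

Per-haplotype frequency drift between the classes is tested with a 2x2
chi-square (hap vs not-hap x LAN vs MV) without continuity correction;
results with an expected cell below 1 are flagged `low_count`, and
degenerate margins return an undefined p rather than a fabricated one.

## Trait association

Per gene x trait, groups are the major haplotypes with at least `min_n`
phenotyped accessions (default 10; recorded in output metadata). A
classical one-way ANOVA (computed from sums of squares so that degenerate
all-equal inputs give F = 0 rather than NaN) yields F and p; associations
with p < 1e-7 are flagged `strong` — a deliberately conservative fixed
threshold used instead of FDR control, with raw p always emitted. Only one
factor (haplotype) exists in this design, so a one-way analysis is the
correct model. Pairwise differences use Tukey's HSD (studentized-range
distribution, via statsmodels) and are summarised as a compact letter
display computed with the insert-and-absorb algorithm: two groups share a
letter iff their Tukey-adjusted p >= 0.05. Letter identity depends on the
ordering of groups (by descending mean), but the sharing structure is
order-invariant and is what the tests assert.

The favorable-vs-unfavorable comparison uses Welch's unequal-variance
t-test because the two groups are extremely unbalanced by construction
(highest- vs lowest-frequency major haplotype). Comparisons where either
group has fewer than two phenotyped accessions are counted as attempted
but reported as skipped with a reason.

## Haplotype networks

Mutation distances between haplotypes are Hamming distances over the CDS
allele vectors. The network is built Kruskal-style over all pairs sorted
by (steps ascending, Hap-rank pair ascending): an edge joining two
components becomes a spanning edge (`in_msn=True`); an edge internal to a
component is retained as an alternative link (`in_msn=False`,
a reticulation) iff its step count equals the step at which its endpoints
first became connected; longer redundant edges are dropped. The spanning
edges therefore form a minimum spanning tree of the haplotypes —
verified in the tests against exhaustive enumeration of all labeled
spanning trees (Prüfer sequences) on small instances. A connection limit,
off by default, excludes all edges above a step threshold and may split
the network into subnetworks; no probabilistic (TCS-style) limit is
computed, because a fixed deterministic rule is reproducible and testable,
and the construction already realises "connect the most closely related
haplotypes with the fewest mutations first". Median (unsampled
intermediate) haplotypes are not inserted.

## Synthetic data generator

The generator emulates the features of a multi-population inbred rice
panel that the pipeline's statistics are sensitive to:

* **Panel composition** defaults to the landrace/modern strata of the 3K
  Rice Genomes panel: 732 LAN-Xian, 358 MV-Xian, 328 LAN-Geng, 139
  MV-Geng.
* **Haplotypes on a mutation tree**: per gene, the root haplotype is
  all-reference and each new haplotype copies a random existing one and
  mutates one previously unmutated site. Hence vectors are unique,
  pairwise Hamming distance equals tree-path length, and the network
  module has an exact ground truth. This requires
  `n_haps_per_gene <= sites_per_gene + 1` (checked).
* **Frequency spectra**: one Dirichlet(alpha = 0.5) draw per population —
  skewed spectra with a realistic dominant Hap1. MV frequencies re-weight
  the LAN spectrum toward its dominant haplotype by `drift_strength`
  (default 0.5), reproducing the observed pattern of modern breeding:
  fewer observed haplotypes in MVs, with the spectrum concentrated on
  favored alleles.
* **Genotypes** are written as homozygous VCF calls with per-call het and
  missing noise (defaults 0.1% and 0.2%, the order of residual error in a
  curated inbred SNP matrix). Each gene also gets two intronic decoy SNPs
  that correct CDS-interval intersection must ignore.
* **Traits**: each of the 15 agronomic traits is tied to one gene; the
  trait value is the accession's per-haplotype additive effect (drawn
  N(0, 1) by default, or planted explicitly) plus N(0, trait_sd = 1)
  noise.
* **Reproducibility**: one RNG stream per (stage, gene) derived from the
  master seed, so per-gene output is stable when `n_genes` changes, and
  repeated runs are byte-identical.

What the generator does *not* emulate: linkage to non-CDS variation,
recombination within genes, coalescent genealogies, genotyping error that
correlates across sites, and phenotype-environment interaction. Passing
tests therefore demonstrate correctness of the statistics and the
identifiability of the pipeline under its own model, not robustness to
those real-data complications.

## Numerical and scale choices

* Diversity identities (uniform spectrum E_H = 1, disjoint fixed
  populations G_ST = 1, two-group ANOVA F = t^2) are asserted to 1e-10 to
  1e-12.
* Permutation calibration uses 500 null datasets of 200 + 200 accessions
  with 1,000 replicates each; type-I error is required to sit in
  0.05 +/- 0.02. Power checks plant a 1-sigma haplotype effect at n = 200
  per group (expected t ~ 10, so p < 1e-7 detection is near-certain) over
  100 seeds.
* Exhaustive network oracles run on <= 6-haplotype instances, where all
  n^(n-2) labeled spanning trees can be enumerated quickly.
* Result tables are written with `%.17g` floats so that write-read round
  trips are bit-exact (`float_precision="round_trip"` on the read side).

## Known limitations

* The het/missing exclusion rule discards whole accessions per gene; at
  high missingness this shrinks denominators quickly (use `ref-fill` to
  probe sensitivity).
* The permutation p-value floor is `1/(1 + reps)`; with the default
  10,000 replicates the `**` band (p < 1e-4) is reachable, but fewer
  replicates silently cap attainable significance.
* G_ST on haplotype frequencies saturates below 1 when within-population
  diversity is high; values are comparable across genes, not across
  estimators.
* The compact letter display is exact for the pairwise decisions it is
  given; it does not re-adjust for the number of genes or traits scanned.
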