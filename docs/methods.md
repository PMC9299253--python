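# Methods

## Data model

All analyses start from a *count table*: per genomic site (1-based,
coordinate-sorted) and per sample, six read counts in the order
`A:T:C:G:N:del` (a pool-seq "sync" dialect with a header line naming the
samples). Depth filters count all six classes; allele frequencies are
always computed over the four nucleotides only. Samples are described by a
*manifest* (label, kind `pool`/`individual`, habitat
`marine`/`acidic`/`basic`, location, optional distance rank and pool size)
and chromosomes by a table of lengths and autosomal status.

## Statistics

For allele-frequency vectors `p`, `q` (length ≥ 2, summing to 1):

- **AFD** `= ½ Σ|pᵢ − qᵢ|`, the half-L1 distance. For biallelic sites this
  is the absolute difference of either allele's frequency. It is a metric
  on the frequency simplex (non-negative, symmetric, triangle inequality),
  bounded by [0, 1].
- **Nei FST (G_ST)** `= (H_T − H_S)/H_T` with `H_S = 1 − ½(Σpᵢ² + Σqᵢ²)`,
  `H_T = 1 − Σp̄ᵢ²`, `p̄ = (p+q)/2` (unweighted). Defined as 0 when
  `H_T = 0` (both samples monomorphic for the same allele). Note
  `(0.6,0.4)` vs `(0.4,0.6)` gives `H_S = 0.48`, `H_T = 0.5`, FST = 0.04;
  estimators of the Hudson family give 0.08 for the same input — this
  package intentionally uses G_ST.

Window scans average a per-SNP statistic in windows starting at
`1, 1+step, …` per chromosome, spanning `[start, start+window−1]`;
windows with fewer than `min_snps` SNPs are discarded.

## Ascertainment

*indSeq*: a site qualifies when (a) the MAF of read counts summed over a
marine reference set of individuals is ≥ 0.04, (b) cumulative depth over
that set is ≤ 1000× (purging collapsed repeats), (c) every sample has
depth ≥ 1×, and (d) it is ≥ 100 bp from any other qualifying site. The
spacing filter removes *both* members of a close pair by default (clusters
are treated as alignment artifacts wholesale); a `keep_one` switch retains
the leftmost member instead.

*poolSeq*: a site qualifies when the combined depth of the two contrast
pools lies in the closed range [100, 500]×, the combined-count MAF is
≥ 0.25, and each pool individually covers it at ≥ 50×. Qualifying sites
are genotyped (frequency = count / nucleotide depth) in every sample.

## Panels and the gradient contrast

The *adaptive* panel takes autosomal SNPs with acidic–basic AFD ≥ 0.85 and
thins them greedily in descending-AFD order (ties by coordinate) under a
100-kb spacing constraint. The *baseline* panel takes SNPs whose AFD lies
in a ±0.1% relative band around the genome-wide median (a percentile-band
reading is also implemented), thins them in seeded random order, and
subsamples to 500 if oversubscribed. At each panel SNP the *acidic allele*
is the nucleotide most frequent in the acidic pool (adaptive panel) or the
one maximizing `f_acidic − f_basic` (baseline panel); exact ties are broken
by a seeded draw and flagged.

The gradient contrast computes the Spearman correlation between marine-pool
distance rank and the per-pool median acidic-allele frequency, and a
one-sided permutation p-value (probability of a correlation at least as
negative, over random permutations of the medians across ranks, with
add-one correction). The *minor-allele subset* restricts to SNPs whose
acidic allele is < 0.5 in every marine pool.

## Genealogy preparation

Individuals are haploidized per SNP to the read-majority nucleotide
(seeded tie-break) — a deliberate simplification that sidesteps diploid
calling at 16×. The marine–freshwater contrast draws two nucleotides per
individual per SNP from its read pileup (approximating two chromosomes),
pools within groups, masks SNPs with pooled MAF < 0.25, and reports per-SNP
AFD. The *neutral filter* keeps SNPs that are **not** differentiated
(AFD > 0.4) in *both* the marine–freshwater and acidic–basic contrasts
(an unmeasured contrast never counts as exceeding) **and** lie within the
peripheral 5 Mb of their chromosome, where recombination is high and
linked-selection footprints weak. Synthetic pool genotypes draw one allele
per pool per SNP from the pool frequencies. Neighbour joining on
p-distances is included as a structure-recovery utility; likelihood tree
inference is external (FASTA export).

## Haplotype windows

Within a window (default 5 kb, `[center − w/2, center + w/2 − 1]` for even
`w`) each individual is genotyped at each site: missing below 10× total
depth; heterozygous for the top two read alleles when the within-individual
read MAF exceeds 0.1 *strictly*; else homozygous for the majority allele.
Filters apply in a fixed order: individuals with > 25% missing calls are
dropped first, then sites with > 40% missingness or called-allele MAF < 5%
(two alleles per homozygote, one of each per heterozygote). The order is
switchable (`sites_filter_first`) for sensitivity analysis. Export follows
a fastPHASE-style `.inp` layout plus a TSV twin that round-trips.

## Synthetic generator

The generator is the package's study design; its defaults are fixed, not
tuned per run:

- 21 chromosomes of 21 Mb; `chrXIX` is the non-autosomal sex chromosome.
- Pools: `acidic`, `basic` (100 fish each) and six marine pools
  (`NU, IR, NL, DE, IS, CA`) with distance ranks 0–5; 85× target pool
  depth (Poisson). Optional individuals at 16×.
- Site positions are drawn uniformly per chromosome with ≥ 150 bp spacing;
  ancestral frequencies are Uniform(0.05, 0.95).
- Background differentiation follows a Balding–Nichols model: each
  sample's true frequency is Beta(`p(1−F)/F` shaped) around the ancestral
  `p`, with separate `F` for the marine group (target mean pairwise Nei
  FST 0.019) and the freshwater pools (target 0.068).
- Planted adaptive sites (autosomes only): acidic frequency
  ~ Uniform(0.925, 1), basic ~ Uniform(0, 0.075) (true AFD ≥ 0.85); marine
  frequency is 0.30 at every pool (`neutral_flat`) or decays geometrically
  with distance rank, `0.30 × 0.5^rank` (`gene_flow_decline`).
- Reads: depth ~ Poisson(target); allele counts ~ Multinomial over a
  6-class error model (each true allele emits itself with prob 1−e and
  each other nucleotide with e/3, e = 0.002; N/deletion classes are never
  emitted by the generator but are parsed and counted toward depth).
  Individuals draw a Hardy–Weinberg genotype first, then reads.

### FST calibration

`F` cannot be set from the naive per-site identity
`E[FST] = F/(2−F)` (equivalently `F = 2t/(1+t)`): across the ancestral
frequency mixture the numerator `H_T − H_S` and denominator `H_T` of the
per-SNP statistic are positively correlated, so the mean per-SNP two-sample
FST exceeds the ratio of expectations — by ~13% at the freshwater target.
`F` is therefore found by bisection against a Monte-Carlo estimate of the
mean per-SNP pairwise Nei FST (150,000 sites, fixed internal calibration
seed, 40 iterations), cached per target. Recovery at 10⁵ truth-level
sites: 0.0190 for target 0.019 and 0.0679 for target 0.068.

Count-level FST estimates exceed truth-level values by ≈ 1/depth (binomial
sampling variance enters H_S and H_T differently); recovery tests therefore
compare counts-level statistics to truth-table values of the *same*
statistic and separately verify the truth-level calibration.

## Determinism

Every stochastic step (simulation, tie-breaks, baseline subsampling,
haploidization, synthetic genotypes, permutation tests) flows from an
explicit seed through `numpy.random.Generator`; identical seeds give
byte-identical outputs. The acceptance script derives all child seeds
(< 2³¹) from a single `--seed` via `SeedSequence`.

## Scope and limitations

- The generator models free recombination (independent sites): no linkage
  disequilibrium, no haplotype structure beyond the dedicated
  window-simulator (`simulate_haplotype_window`), no demographic history
  beyond the one-level Balding–Nichols hierarchy.
- Mapping artifacts are represented only through their filter signatures
  (depth extremes, clustered sites), not mechanistically.
- The gradient test treats pools as exchangeable under the null; it does
  not model spatial autocorrelation among marine pools.
- Problem sizes in tests and examples (10⁴–10⁵ sites) are the package's
  own choice to keep desk-scale runtimes; the pipeline is linear in sites
  and streams nothing, so memory is the binding constraint at genome scale.
- `marine_freshwater_contrast`'s two-draw haploidization has an
  irreducible finite-sample floor: even identical groups show a mean
  |frequency difference| of ≈ 0.09 for 10-vs-10 individuals; thresholded
  uses (the 0.4 neutrality cut) are insensitive to this floor.
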