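# Methods

This note documents the statistical model, the parameter defaults and the
reasoning behind them, what the synthetic generator does and does not
emulate, and the numerical choices in the implementation. Every empirical
statement here is asserted by the test suite or computed by
`scripts/acceptance.py`.

## Data model

Input is a per-individual CNV call table: `(sample_id, chrom, start, end,
copy_state, source)` with optional QC metadata (`lod`, `confidence`,
`n_probes`) and a sample sheet mapping samples to populations. Copy states
are integers 0–4; state 2 (copy-neutral) is rejected as a call. Only
autosomes are analyzed — allosomal copy number confounds sex with genotype.
Intervals are held internally as 0-based half-open; TSV I/O defaults to
1-based inclusive coordinates and BED I/O is 0-based half-open, with
conversion only at the boundary.

## Quality control

Call-level filtering removes calls with length < 1 kb **or** fewer than 3
probes **or** LOD < 5; equality survives. These thresholds reflect the
resolution limit of SNP-array CNV calling: shorter or probe-poor calls are
dominated by boundary noise. Absent metadata passes (the filter cannot act
on information it does not have). Sample-level filtering removes samples
whose deletion count or duplication count exceeds the cohort mean + 5
standard deviations, with mean and SD computed before any exclusion; 5 SD is
deliberately permissive so only assay failures are dropped. Note that with
`n` samples a single outlier's z-score is bounded by `(n−1)/√n`, so this
rule can only fire in cohorts of ≳27 samples — the test suite exercises it
at n = 61.

Same-sample overlapping calls with inconsistent states are resolved in
favor of the higher LOD; at equal LOD the CNP-genotyped call wins over the
rare-CNV call (predefined loci are genotyped with more information than de
novo segmentation). CNP calls with genotype confidence > 0.1 are converted
to missing markers: the sample's genotype at the enclosing region becomes
NaN rather than defaulting to 2.

## CNVR and CNVseg construction

A CNVR is a connected component of the "overlaps by ≥ 1 bp" relation over
calls; abutting intervals do not merge. The implementation is a sorted
sweep per chromosome (O(n log n)); the test suite checks it against an
O(n²) union-find oracle on random instances. CNVsegs cut each CNVR at every
member call's internal breakpoints, producing a tiling.

Genotype assignment at a locus: a sample with no overlapping call is state
2; with multiple overlapping calls the longest call wins, ties broken by
lower copy state, then leftmost start — a deterministic rule favoring the
call with the most supporting territory. A CNVR is classified `deletion`,
`duplication`, or `multiallelic` by the states its members carry; it is a
`singleton` when all member calls come from one individual and `complex`
when some individual carries both a deletion and a duplication in it.
`event_frequency` is carriers / non-missing samples.

## Three-allele EM

Haploid alleles carry 0 (`l`), 1 (`n`) or 2 (`g`) copies. Under HWE the
genotype probabilities are P0 = p_l², P1 = 2p_l·p_n, P2 = p_n² + 2p_l·p_g,
P3 = 2p_n·p_g, P4 = p_g². The E-step splits the observed 2-copy count
between the `n/n` and `l/g` configurations in proportion to p_n² :
2p_l·p_g; the M-step re-estimates frequencies by allele counting. The
log-likelihood is monotone (asserted on random inputs) and the estimate
matches a 2-simplex grid-search MLE (step 1e-3) within 2e-3.

**Initialization is (0.3, 0.4, 0.3), not uniform.** The uniform point
(1/3, 1/3, 1/3) is an exact fixed point of the EM map for data consisting
only of 2-copy genotypes (the split ratio p_n² : 2p_l·p_g equals 1:2 · …
symmetrically reproduces itself), so a uniform start can stall at a
non-boundary stationary point; the asymmetric start breaks the symmetry
while remaining interior. Tolerance 1e-8 on the frequency change, cap
10,000 iterations.

## F<sub>ST</sub>

Weir–Cockerham variance-components θ, summing the per-allele components
a, b, c over the three alleles: θ = Σa / Σ(a+b+c). Because genotype
configurations are not directly observable (the 2-copy mixture), the
observed heterozygosity in the b and c components is replaced by its HWE
expectation h = 2p(1−p) per allele. This makes θ a function of estimated
allele frequencies and sample sizes only; the cost is that deviations from
HWE inflate or deflate θ undetectably. θ is undefined (reported NaN) when
the denominator is 0, i.e. all populations monomorphic for the same allele.
The per-locus scan skips loci with call rate below 0.5 in a population.

## Distances, trees, bootstrap

The distance between two populations is the mean number of differing loci
over all between-population sample pairs, skipping loci missing in either
sample of a pair — a raw count (not normalized per locus), so values scale
with the number of loci analyzed. The within-population diagonal uses
distinct pairs. The distance decomposes additively over loci, which the
implementation exploits: per-locus per-pair mean differences are
precomputed from genotype count vectors, making a locus bootstrap a matrix
product instead of a cohort rebuild.

Trees: UPGMA (average linkage, ultrametric) and neighbor joining (negative
branch lengths clamped to 0, flagged on the tree object). Bootstrap support
resamples loci with replacement (default 1,000 replicates) and reports
majority-rule consensus: clades (rooted, for UPGMA) or bipartitions
(unrooted, for NJ) present in > 50% of replicate trees, with support
percentages written as internal node labels. Majority clades are pairwise
compatible, so nesting them by size reconstructs the consensus tree
directly.

## Sharing

Comparing CNVR sharing between groups of unequal size is biased — larger
groups accumulate more regions — so all groups are subsampled to the
smallest group's size, CNVRs are rebuilt from the subsample's calls, each
region is assigned to its Venn cell (the set of groups with ≥ 1 carrier),
and cell counts are averaged over replicates (default 100). Pairwise
sharing(I, J) is the fraction of CNVRs carried by J that are also carried
by I, computed on the full data; it is asymmetric by construction and
satisfies sharing(I,J)·|J| = sharing(J,I)·|I|.

## Differentiation scan

Genotypes map to allele counts deterministically (0→2 loss, 1→loss+normal,
2→2 normal, 3→normal+gain, 4→2 gain; the rare l/g configuration inside
state 2 is counted as normal/normal, consistent with its non-identifiability).
For a test population against each reference, two-sided Fisher exact tests
compare loss vs non-loss and gain vs non-gain allele counts. Significance
uses per-locus Bonferroni (α / n_loci) within each reference × allele
family. Loci are ranked by the number of significant comparisons, ties by
the "overall" p-value: the minimum over the two alleles of the test against
all references pooled. Zero-margin tables return p = 1. On
identical-frequency populations the family-wise error of the scan stays at
the nominal level (computed by the acceptance script over 200 replicate
scans). Population-exclusive CNVRs are those carried only by the test
population among test + references, by default requiring ≥ 2 distinct test
carriers so a single private call does not qualify.

## Structure and taggability

Only loci whose observed genotypes stay on one side of state 2 (within
{0,1,2} or {2,3,4}) have a determinable per-individual allele dosage; these
are recoded as dosage of the non-normal allele and fed to PCA with
Patterson normalization (mean-imputed, centered, scaled by √(p(1−p)) with
p = mean/2), computed by SVD with a deterministic sign convention
(largest-magnitude loading positive). Zero-variance columns are dropped.

CNP–SNP r² comes from two-locus haplotype frequencies estimated by EM from
unphased dosages; the only ambiguous class is the double heterozygote,
split between cis and trans phase in proportion to current haplotype
products. Linkage-equilibrium initialization, tolerance 1e-10, ≥ 5 complete
observations and both loci polymorphic required (else NaN). A common CNP
(carrier frequency > 0.10) is *tagged* when some SNP within 20 kb of either
CNVR boundary reaches r² ≥ 0.8 — the conventional proxy threshold for
array-based association coverage.

## Synthetic generator

The generator emulates array-style CNV calling output with known truth:

- Population allele frequencies drift from a shared ancestral frequency
  down a nested hierarchy by Dirichlet steps (child ~ Dir(p(1−c)/c)), which
  keeps the mean at the parent and scales variance with the drift
  coefficient c — so distance trees have a known generating topology.
- Ancestral loci are loss-biased (70% deletion / 20% duplication / 10%
  multiallelic) with non-normal allele frequency ~ Beta(0.8, 4), matching
  the low-frequency, deletion-dominated character of array CNV maps; locus
  lengths are log-normal around 15 kb.
- Per sample per locus, two alleles are drawn from the population's
  frequencies; non-2 states are emitted as calls with Gaussian boundary
  jitter (SD 500 bp, truncated at 40% of locus length so neighboring loci
  never merge — enforced by a separability check).
- Private singleton calls land in reserved coordinates far from configured
  loci; "complex" loci give one carrier a deletion and a duplication
  sub-call in non-overlapping parts of the locus; a missing-rate fraction
  of carrier calls get confidence > 0.1 (downstream missing genotypes); a
  qc-noise fraction of calls get sub-threshold length/probes/LOD, with the
  corrupted call keys recorded in the truth bundle.
- The default cohort mirrors a 155-sample, 7-population study design
  (80/41/9/8/8/6/3) over 1,440 loci.
- Linked SNPs are generated per chromosome conditional on the CNV allele,
  from haplotype frequencies achieving a requested D′ and MAF, with the
  closed-form r² recorded.

Not emulated: probe-level intensities or calling-algorithm error models
(calls are emitted directly from true genotypes), LD between CNV loci,
genome-realistic locus placement (uniform spacing on equal-sized
chromosomes), batch effects, or allosomes. Boundary jitter is independent
across carriers, so CNVR ends are order statistics of Gaussians rather
than recurrent breakpoints.

## Limitations

- HWE is assumed throughout: in the EM (identifiability of the 2-copy
  mixture requires it) and in the F<sub>ST</sub> heterozygosity terms.
- The raw-count distance scale depends on the locus set; trees are
  invariant to the scale but distances are not comparable across maps.
- Fisher tests treat alleles within an individual as independent draws,
  ignoring diploid correlation; the Bonferroni correction is per
  reference × allele family, not across families.
- The "overall" differentiation p-value pools references, which weights
  references by sample size.
- EM-based r² assumes random mating for phase inference; NaN is returned
  rather than a point estimate when data are insufficient, so taggability
  denominators count only estimable CNPs.
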