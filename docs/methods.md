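# Methods

This note records the statistical models implemented in `clonotrace`,
the defaults and why they were chosen, the numerical decisions that are
not visible from the API, and what the synthetic-data generator does and
does not emulate.

## Generative model of the synthetic data

**Single cells.** A sample is a mixture of a wild-type population and a
forest of somatic clones, each clone a set of `(locus, zygosity)`
mutations with a cell fraction; fractions sum to at most one and the
remainder is wild type. A child clone either extends its parent's
mutation set or converts exactly one heterozygous mutation to homozygous
(copy-neutral LOH progression). Cells are drawn multinomially over
clones. With probability `doublet_rate` a barcode captures two
independently drawn cells: their allele sets merge and the expected
depth doubles; doublets are recorded in the truth table but never
pre-filtered, so clone inference must tolerate them. At each locus every
allele copy drops out independently with probability `ado_rate`; if all
copies drop, the locus yields zero reads and a missing genotype. Depth
is negative binomial (mean `depth_mean`, dispersion `depth_dispersion`;
overdispersion is characteristic of amplicon panels) and the alt count
is binomial around the surviving-allele fraction perturbed by a per-base
substitution probability `seq_error`. Germline heterozygous SNP loci
(`n_snps`, default 20) are carried by every cell and drive ADO
estimation.

**Defaults** mirror a targeted single-cell DNA panel on bone marrow:
5,000–10,000 cells per sample (tests use 10,000), `ado_rate = 0.05` per
allele (sample-level hom/het ratio ≈ 0.105), `doublet_rate = 0.02`,
depth 80× with dispersion 10, `seq_error = 1e-3`. The per-cell depth
distribution of commercial panels is not publicly characterized; the
negative-binomial choice and its parameters are assumptions exposed in
`SimConfig`.

**Bulk duplex counts.** Per timepoint, each mutation's true VAF is
`Σ carrier-clone fraction × multiplicity / 2`; alt counts are binomial
at consensus depth `bulk_depth` (default 20,000, sufficient for a 0.1%
VAF floor), with strand-split counts, background error-only sites at
`seq_error`, and a fibroblast-like germline comparator drawn at the
error rate.

**Exome-style counts.** Truth is a set of segments with integer allele
pairs `(a, b)`. Target counts have mean proportional to
`purity·(a+b)/2 + (1−purity)`, multiplied by a per-target capture
efficiency (lognormal, σ = 0.25) shared with an emitted panel of
normals. Het-SNP alt fractions have mean
`(purity·c_alt + (1−purity)) / (purity·(a+b) + 2(1−purity))` where
`c_alt` is the copy number of the haplotype carrying the alt allele
(recorded as truth). The copy-number validation grid uses dispersion 40
rather than the single-cell default 10: hybrid-capture exome coverage is
far less overdispersed than amplicon coverage.

**Synthetic hierarchies** (`random_hierarchy`) draw 3–6 clones totalling
at most 50% of cells, each at least 0.5%; 85% of clones arise
independently (single mutation, wild-type parent) and the rest are
one-mutation subclones no larger than their parent's residual
population. This mirrors the observed structure of clonal hematopoiesis
in this disease context, where nearly all clones are independent and
subclones are recent and small. Gene labels are drawn with
*EIF6* > *TP53* ≫ *PRPF8*, *CSNK1A1* weights matching the cohort's
mutation spectrum.

**What the generator does not emulate:** alignment and mapping
artifacts, UMI/barcode errors, GC- or fragment-length-dependent coverage
waves, copy-number subclonality, cell-cycle and ambient-DNA effects, and
any correlation of dropout across loci within a cell. Tests passing on
this generator therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to every real-data
failure mode.

## Genotyping and dropout

Genotypes follow fixed thresholds: missing if DP < 10; a variant is
present iff alt ≥ 3 and alt/DP ≥ 0.30; present calls are homozygous at
alt/DP ≥ 0.90 (the hom boundary is a package choice — presence criteria
alone do not separate het from hom — and is config-exposed). ADO is the
ratio of hom-appearing to het-appearing cells at informative SNPs
(pseudobulk alt fraction in [0.35, 0.65] and het calls in ≥ 20% of
genotyped cells), averaged unweighted across sites, with a percentile
bootstrap over cells; cells missing at more than half their loci are
dropped first as empty-droplet-like artifacts.

Under independent per-allele dropout at rate d, a het cell appears hom
with probability 2d(1−d) and het with (1−d)², giving the closed-form
ratio 2d/(1−d). The thresholds add a small positive correction
(~1–2% relative at the defaults): binomial fluctuations at moderate
depth push a few true-het cells below the 30% cutoff, and a wt call at a
het SNP counts as homozygous reference. The exact expectation —
integrating the thresholds over the depth distribution — is derived
independently in the test suite and the estimator is calibrated against
it; the dropout-only form remains the leading-order value.

## Clone inference

Cells with complete genotypes at all somatic loci under test are grouped
by exact genotype vector; groups below 10 cells or 0.1% frequency are
discarded (the smallest real clones of interest sit at ~0.1%). For a
candidate group differing from a larger group only by het→wt or het→hom
at one locus — the two patterns single-allele dropout can produce — the
dropout-spillover null is a one-sided binomial test: conditional on a
genotyped cell showing either pattern, the spillover pattern occurs with
probability exactly d (the per-allele rate implied by the measured ADO
ratio, d = r/(2+r)). Groups that fail to reject at α = 0.01 are merged
into the larger clone (`ado_merged`); groups that reject are genuine
(sub)clones. The same test distinguishes CN-LOH progression subclones
(`loh_subclone`) from dropout images of their heterozygous parent; a hom
clone with no het counterpart is flagged `orphan_hom`. Groups matching
the union of two disjoint clones at a size within 3√λ of the
doublet-expected count λ = 2·doublet_rate·f_i·f_j·n are flagged
`putative_doublet` and excluded from the hierarchy.

Parents are assigned by mutation-set containment: the retained clone
with the largest strict-subset mutation set (zygosity-compatible), or
the het version for a clone homozygous at exactly one locus. Ties break
toward the larger clone, then lexicographic genotype, and are flagged
`ambiguous_parent`. The output is a forest; clones with no parent are
founding clones.

**Expected behavior of exact recovery.** The spillover test runs once
per dropout-satellite group large enough to be retained, so a sample
with several abundant clones performs a handful of α-level tests; a
false rejection leaves one spurious hom subclone. Measured over 400
replicates at the default conditions (10,000 cells, 3–6 clones ≥ 0.5%,
d = 0.05, 2% doublets), exact hierarchy recovery is ≈ 97%, and every
observed failure is one extra hom subclone of this kind. This is the
designed trade-off of replacing the original manual review with a
deterministic test at α = 0.01.

Serial tracking is per mutation: a timeline of (age, VAF, detected)
entries from filtered bulk calls, with fold change defined as
VAF(last detection)/VAF(first detection) and undefined for mutations
detected once.

## Bulk duplex filtering

Rules apply in fixed order (first failure recorded): on-target → alt ≥ 3
→ VAF ≥ 0.1% → strand bias → regional density → synonymous →
homopolymer indel → germline. The published ruleset leaves three
cutoffs qualitative; the package's operationalizations, all exposed in
`FilterConfig`, are: strand bias = two-sided binomial test of the
alt-read strand split against the site's depth split at p < 1e-3;
regional density = more than 3 co-surviving candidates within 50 bp
fails all of them; homopolymer rule = indel with VAF < 1% flagged
homopolymer-adjacent. Somatic status requires a comparator entry below
20% alt fraction; sites without comparator coverage are labelled
`unclassified`, never silently passed. The 10-base 5′ soft-clip of the
original pipeline has no analogue at count-table granularity and is a
documented no-op. At the design depth of 20,000 and substitution error
1e-4, a 0.2%-VAF variant clears the chain in > 99% of draws while a
zero-VAF site essentially never reaches the 20-read VAF floor.

## Copy number, phasing, CCF

tCR per target is the sample's coverage fraction divided by the panel
median fraction, making it exactly invariant to library size. Targets
are blacklisted when absent from the panel, when the panel's mean
normalized ratio leaves [0.25, 4], or when its coefficient of variation
exceeds 0.5 (all config-exposed; the original thresholds are unstated).

Segmentation is recursive binary splitting on log2 tCR: the split
statistic is the squared two-sample t statistic of the best mean shift,
and recursion stops when a within-segment permutation test (default 200
permutations) is not significant at α = 0.01. The smallest admissible
flank is 5 targets; chromosomes with fewer than 10 targets yield one
segment with a warning. In joint mode the split statistic sums across
all samples of a patient at each position, so breakpoints shared by
serial samples are recovered even when each sample alone is too weak —
this is the multi-sample adaptation the analysis relies on.

Allelic imbalance per segment is a symmetric binomial mixture: each het
SNP's alt count is Binomial(n, θ) or Binomial(n, 1−θ) depending on which
haplotype carries its alt allele. θ ∈ [0.5, 0.995] is fitted by bounded
maximum likelihood and tested against θ = 0.5 by likelihood ratio
(χ²₁, α = 0.01; the boundary makes this slightly conservative). A
two-state HMM over ordered SNPs (state = over-represented haplotype,
switch probability 0.01, optional per-SNP prior phase with weight 0.9
standing in for population phasing) yields Viterbi haplotype labels and
a phased VAF track; without priors the labeling is resolved up to the
global A/B symmetry. Classification: no significant imbalance →
balanced; otherwise deletion, CN-LOH or gain according to the segment's
mean log2 tCR against a ±0.15 window (config-exposed; "tCR ≈ 1" is not
quantified in the source analysis). Segments with fewer than 5 het SNPs
are indeterminate.

The CCF posterior evaluates the binomial likelihood of alt/depth on a
101-point grid under `f(c) = ρ·m·c/(ρ·q + 2(1−ρ))` with a uniform
prior; the mode and central 95% interval are reported. Purity and
multiplicity are inputs (truth in simulation, user-supplied otherwise);
joint purity/ploidy estimation is deliberately out of scope. With
expectation-matched counts the mode recovers truth to grid resolution;
with sampled counts at depth 1000 and purity 0.3 the sampling noise on
the mode is ~0.07 in CCF units — larger than the grid — so calibration
checks use expectation-matched counts and treat sampled-count spread as
a purity/depth budgeting question for study design.

## Cohort statistics

The two-sided Fisher exact test uses the probability-mass convention
(sum over tables with probability ≤ observed, relative tie tolerance
1e-7), which is the common software default; a zero margin returns p = 1
with a warning. Prevalence by age counts patients with ≥ 1 somatic
mutation or clonal copy-number event per age bin. Biallelic-mechanism
classification is exhaustive and mutually exclusive: two mutations in
one clone (single-cell evidence) or with both CCF intervals covering 1.0
(bulk evidence) → `two_mutations`; otherwise CN-LOH or deletion on the
relevant region; otherwise `monoallelic`. Age/sex regressions are out of
scope; the summaries emit the tables needed to run them elsewhere.

## Problem sizes used in validation

The test suite and acceptance script use: 10⁵ cells × 10 SNPs for ADO
calibration; 100 replicates of 10⁴ cells for hierarchy recovery; 20
replicate pairs for CN-LOH detection; a 4-class × 3-purity × 3-seed grid
with 750 targets and 150 SNPs per genome for copy-number classification
(150 permutations per split); 200 true + 400 background sites at depth
20,000 for the duplex floor. These sizes give the estimators enough
signal that the stated tolerances reflect method error rather than
Monte-Carlo noise, while keeping a full run in tens of seconds.

## Known limitations

- The spillover test assumes site-independent, cell-independent dropout
  at the SNP-estimated rate; locus-specific dropout (allele-biased
  amplification) would miscalibrate it.
- Doublet handling flags only unions of two *retained* clones; doublets
  involving a clone below the retention floor are absorbed silently.
- The imbalance HMM models a single clonal event per segment; mixtures
  of subclonal copy-number states produce intermediate θ and may
  classify by the dominant state only.
- Without prior phase information, haplotype labels are defined only up
  to a per-segment A/B swap.
- The Fisher test and mechanism classifier assume complete, correctly
  attributed mutation calls; they inherit any upstream filter errors.
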