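# Methods

radpop analyses multi-sample SNP genotypes from reduced-representation (RAD)
sequencing of closely related mosquito species, and ships a coalescent
generator that produces data with the same structure so that every stage can
be validated against known truth. This note records the models, the
numerical choices, and what the synthetic validation does and does not show.

## Data model and filtering

The unit of data is a samples x sites matrix of diploid alt-allele dosages
(0/1/2) with a distinct MISSING sentinel, per-site metadata (position,
quality, distance to the nearest indel) and per-sample read depth. Sites
include invariant positions — either as explicit rows (VCF input written
with `ALT=.`) or as an `extra_monomorphic` count (simulator output) — so the
denominator `L` of all per-site statistics is the number of *analysed*
bases, not the number of SNPs.

The filter cascade retains a variant site only if it is a biallelic SNP
with site quality >= 25, more than 6 bp from the nearest indel, read depth
>= 15 in every sample, and no missing genotype; invariant sites face the
same depth/completeness rules and are recounted into `L`. Each removed site
is attributed to the first rule it fails and per-rule attrition is logged,
so data-set summary tables can be reproduced exactly. Site quality is a
site-level proxy for the per-base quality threshold applied upstream in the
original pileup; with genotypes as input nothing finer is available.

RAD data arrive as pairs of ~72-bp reads flanking each restriction site.
Sites are grouped into "tag locations" by merging consecutive sites within
150 bp of the running span — wide enough to join the two reads of one cut
site (~144 bp alignment), orders of magnitude below the >100 kb between
neighbouring cut sites. Tags are the units of linkage: analyses of
genotype-frequency statistics draw one random SNP per tag (deterministic per
seed) to avoid pseudo-replication from intra-tag LD.

## Diversity, divergence, differentiation

* pi is the unbiased per-site pairwise diversity, `sum 2 c_a c_r / (m(m-1)) / L`
  with `m` sampled chromosomes; allele counts come straight from diploid
  dosages with no Hardy–Weinberg assumption. Its standard deviation is a
  delete-one-tag jackknife (tags are the natural independent unit; the
  original report does not state its method, so this is the package's
  choice).
* Watterson's theta is `S / (a1 L)`; Tajima's D uses the 1989 constants and
  is computed once from region totals (`pi L`, `S`), not averaged over
  windows. `S = 0` yields NaN with a warning.
* D_XY is the mean inter-population allele difference per site;
  D_A = D_XY − mean within-pi. With the unbiased within-pi, D_A of a
  population against itself is slightly negative (−2pq/(m−1) per site), not
  exactly zero; the identity D_XY(p,p) = uncorrected pi holds exactly and is
  what the tests assert.
* F_ST is Weir & Cockerham's (1984) theta-hat: per-locus variance
  components a (among populations), b (among individuals), c (within
  individuals), combined across loci as a ratio of sums; loci monomorphic in
  the pooled sample are skipped and negative components retained. The
  reported value is the median over five one-SNP-per-tag subsets, with
  significance from permuting individuals across population labels
  ((k+1)/(N+1)-corrected, 8,000 permutations by default). Scalar
  conversions: Nm = (1−F)/4F, Ne = theta/4mu (mu = 1.1e-9 per generation =
  1.1e-8 per year over 10 generations/year), T = D_A/2mu_year.
* F_IS = 1 − H_obs/H_exp summed over loci (H_exp with the m/(m−1)
  correction); the null re-pairs alleles within the population per locus;
  the p-value is one-sided for heterozygote deficit.
* Site classification (shared / private / fixed / monomorphic) is by
  allele-presence sets per population, with a three-population Venn
  extension.

## Individual-level structure

The pairwise individual distance is the mean allele difference over the
four allele pairings per site, divided by `L`; it equals D_XY between
singleton populations. Neighbor joining is the Saitou–Nei algorithm;
negative branch lengths are clamped to zero with the deficit moved to the
sister branch so the joined pair's path length is preserved (the behaviour
of classic phylogeny packages). PCA is correlation-based (each SNP scaled
to unit variance) with component signs fixed by making the
largest-magnitude loading positive; discrete assignment is k-means on the
leading components (50 restarts) with a silhouette-based suggestion for k.
A full admixture model would be out of proportion to its role here —
species fall into well-separated clusters.

## Inversion scan and karyotyping

A segregating inversion suppresses inter-orientation recombination, so its
tags travel as two deep haplotype classes. Pairwise r^2 between unphased
SNPs is computed by the two-locus EM (only the double heterozygote is
phase-ambiguous; tolerance 1e-8, <=1000 iterations), with a composite
dosage-correlation r^2 available as a cross-check. SNPs under 5% minor
allele frequency are excluded from LD: two rare variants carried by the
same individual give a spurious r^2 of 1.

The original analysis judged LD "triangle plots" by eye; the reproducible
replacement is: collapse the SNP-level r^2 matrix to tag-pair scores (the
*maximum* r^2 over SNP cross pairs — gene flux leaves some SNPs in every
inversion tag uninformative, so a median would dilute the signal), flag
tags whose median score among their five nearest neighbours per side
exceeds the 95% quantile of all tag-pair scores on the arm, and report runs
of >= 5 flagged tags. The false-positive rate of these defaults is
calibrated on inversion-free simulations (<= 5% of replicates).

Karyotypes come from PCA of the SNPs inside a block: k-means with k chosen
from {2, 3} by silhouette; with three clusters the PC1-middle cluster must
also be the most heterozygous to be called the heterokaryotype (otherwise
everything is flagged uncalled), and with two clusters the more
heterozygous cluster is the heterokaryotype (one homokaryotype absent from
the sample). Below silhouette 0.5 no structure is called. Homokaryotype
numbering is anchored to mean alt dosage inside the block, which makes
calls invariant to SNP order and PC sign; which orientation is the inverted
one is not identifiable from SNPs alone. Karyotype-stratified statistics
(windowed between-homokaryotype F_ST, windowed D_XY to an outgroup, shared
polymorphism counts, Hardy–Weinberg and location-homogeneity chi-squares)
operate on the called classes.

## Folded-SFS demography

Single-population size histories are fitted to the folded SFS built from
one SNP per tag, excluding the X chromosome and detected inversion blocks
(both violate the panmictic single-population model). Four models are
supported, in coalescent units (sizes relative to the ancestral population,
times in 2·N_anc generations): `standard_neutral`; `two_epoch(nu, T)`
(instantaneous change); `exp_growth(nu, T)` (exponential change reaching nu
at present); `bottle_growth(nuB, nuF, T)` (instantaneous change to nuB,
then exponential change to nuF).

Expected spectra are computed exactly from the coalescent: the
number-of-lineages process is a pure death chain whose standard-coalescent
eigendecomposition (triangular back-substitution; verified against a matrix
exponential to 1e-8 at n = 24) gives the state distribution as a mixture of
`exp(-c_m Lambda(t))` terms, where Lambda is the accumulated coalescent
intensity of the size function. Expected sojourn times per lineage count
are closed-form within constant epochs and geometric-panel Gauss–Legendre
quadratures within exponential epochs (error ~1e-5, dominated by the
quadrature); the classical combinatorial weights then give E[xi_i], folded
with the n/2 class counted once. The neutral limit reproduces xi_i
proportional to 1/i to machine precision, and two_epoch agrees with
branch-mode spectra from an independent coalescent simulator within Monte
Carlo error.

The likelihood is multinomial over folded classes (the observed spectrum
shape against the model proportions); absolute log-likelihoods therefore
depend on this choice and are not comparable to other programs' values,
but ratios between models are. Optimization is Nelder–Mead over
log-parameters with Latin-hypercube restarts (20 by default) inside bounds
nu in [1e-2, 1e2] (nuB up to 1e3), T in [1e-3, 8]; fits within 1% of a
bound are flagged. Nested models are compared by LRT with df = the
parameter-count difference; non-nested pairs by raw log-likelihood. On the
neutral null the two_epoch alternative is a ridge (T unidentified at
nu = 1), so the chi-square reference is conservative — measured type-I
error is ~2–4% at a nominal 5%, and the calibration test asserts
non-anticonservatism rather than exact nominal attainment. A
parsimony-aware selector climbs the nested ladder, accepting a more complex
model only when the LRT rejects at 5%.

Confidence intervals are nonparametric bootstrap percentile intervals
(SNPs resampled with replacement, i.e. a multinomial redraw of the
spectrum; 200 replicates by default), each replicate refitted warm-started
at the MLE. A calibration study under the two_epoch regime (nu = 1.95,
T = 0.421, S = 800, n = 24, folded) shows the T interval near nominal
(~96% marginal coverage) but the nu interval under-covering (~83–86%): the
folded spectrum leaves a likelihood ridge along which nu-hat is biased
upward, and interval variants that usually repair bias do worse here
(bias-corrected percentile ~76%, basic/reversed ~80%, on the same draws;
cold-start refits and 200 bootstrap replicates change nothing). Percentile
is therefore retained as the best-performing choice, and downstream
interpretation should treat the lower nu bound as optimistic at small S —
consistent with the original study's caution that the actual parameter
values carry large uncertainty.

## The synthetic-data generator

Per tag, an independent genealogy (no recombination within 144 bp; free
recombination across the >100 kb between tags) receives
Poisson(theta/2 x total branch length) infinite-sites mutations placed
uniformly on branches; chromosomes pair into diploids. Size histories enter
by time-rescaling the standard coalescent through the inverse intensity
Lambda^{-1}. Structured scenarios (species splits, island-model locations,
inversion orientations) run a Gillespie structured coalescent with
piecewise-constant demes and deme merges at split times.

Defaults are the study conditions: 12 diploids per location; ~144-bp tags
every 130 kb across four autosome arms; theta = 1 per tag (per-site
diversity ~0.007, the autosomal range of the study species); three species
— two splitting 0.5 x 2N generations ago with abundant shared
polymorphism, one basal at 3 x 2N with fixed differences, the basal species
at half the reference size (it is the least diverse); 2/3/1 sampling
locations per species with island-model migration 4Nm = 12, which puts
pairwise location F_ST at the exact two-deme value 1/(1 + 2*4Nm) = 0.04 —
the weak differentiation regime observed at ~200 km scales. Inversions are
implanted by drawing one orientation per chromosome (frequencies 0.4/0.6 by
default, shared across all tags of the region — this is what creates the LD
island) and re-simulating the region's tags as a two-deme coalescent over
orientations with deme sizes proportional to frequency and gene-flux rate
m_flux (0.1 by default; a deep cap at 25 x 2N generations represents the
inversion origin and keeps the m_flux = 0 limit defined). Divergence-
dependent tag dropout removes whole (tag, sample) pairs with probability
1 − exp(−scale·d), d being the expected coalescent distance to the
reference species, reproducing the loss of usable tags as more divergent
samples enter a complete-case data set.

What the generator does *not* emulate: sequencing error and allele-dropout
within retained tags, reference-alignment bias toward conserved (exonic)
regions, intra-tag recombination, selection, and explicit gene-conversion
tracts (flux is a scalar migration rate). Passing the closure tests
therefore shows the estimators are correct for the model the field's
analyses assume — not that real-data biases (which the original study
discusses at length) are absent.

## Problem sizes used in validation

The test suite and the acceptance script scale the studies to: 150 (tests)
or 60 (acceptance script) constant-size data sets of 50 tags for the
neutrality closure; 200/100 neutral replicates for LRT calibration at
S = 800; 100/40 replicates for two-epoch bootstrap coverage with 80
bootstrap refits each; 100 inversion-free replicates of 40 tags for the
block-scan false-positive calibration; and a 60-tag arm with a 10-tag
inversion in 24 diploids for the inversion closure. These sizes keep every
Monte-Carlo standard error several times smaller than the assertion
tolerances they are tested against.

## Known limitations

* Genotypes are taken as called; genotype likelihoods and phasing are out
  of scope, and base-level quality filtering is approximated at site level.
* The F_ST flavour of the original report's software is unstated; WC84 may
  differ from AMOVA-style estimates in the second decimal on real data.
* Absolute demographic log-likelihoods are multinomial-specific, and
  parameter units (coalescent) must be scaled by the user's mutation rate
  and generation time for absolute interpretation.
* Orientation identity of karyotype calls requires external anchors
  (cytogenetics or tagged reference samples).
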