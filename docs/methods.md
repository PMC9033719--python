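# Methods

`haplocharter` re-implements, as a tested and reusable pipeline, the
haplotype dissection of a major soybean seed-protein QTL (cqProt-003, on
chromosome 20): variant filtering, LD-based delimitation of the trait
region, marker-group haplotyping, nucleotide diversity with invariant
sites, trinucleotide-repeat genotyping with frame annotation,
coverage-based structural-variant calling, and genotype–phenotype
contrasts. Because the 985-accession resequencing panel underlying the
original characterisation is not redistributable, every stage is exercised
against a synthetic cohort generator that emulates the statistical
structure of that panel. This note records the models, the defaults and
why they are what they are, the numerical conventions, and what the
synthetic results do and do not show about real data.

## Coordinate conventions

VCF positions are 1-based points. All internal intervals are 1-based
half-open `[start, end)`, so `end − start` is the length: the deletion
printed as 31,728,619–31,728,923 has length 304 bp, and the linked region
31,604,127–31,777,346 rounds to 173 kb. BED input/output (0-based
half-open) is converted at the boundary.

## The synthetic cohort generator

The generator is first-class, tested code; its defaults *are* the study
conditions.

**Demography and the high-protein haplotype.** Four domestication classes
with the reference panel's composition (131 wild, 708 landraces, 44 old
cultivars, 102 modern cultivars). Each haplotype copy of each individual
is a carrier of the high-protein haplotype with its class frequency
(defaults 0.947 / 0.106 / 0.041 / 0.041). The focal SNP (default position
31,632,556) is emitted as the exact carrier indicator.

**Marker groups.** Six groups of linked SNPs (default 12 per group, the
focal group gets the focal SNP as its twelfth plus one) occupy contiguous
territories tiling the linked region. Group 1 is the carrier indicator;
groups 2–6 are planted on partially overlapping subsets of carrier
haplotypes via seven background patterns, which guarantees at least seven
distinct diploid combination vectors. Two deliberate choices:

* *Sample-level backgrounds.* The pattern (and the repeat copy number,
  below) is drawn once per sample and shared by both carrier haplotype
  copies. Soybean accessions are essentially inbred lines whose two
  haplotypes descend from the same background; independent per-haplotype
  draws would also inflate the homozygote-conditioned r² between distinct
  groups — which is exactly what the marker clustering sees after
  heterozygote masking — above the 0.9 clustering threshold and chain all
  groups into one.
* *One-directional linkage leak.* With probability `ld_leak` (default
  0.002) a carrier haplotype *loses* a group allele at a member site;
  non-carrier haplotypes never gain one. This models rare recombination
  off the haplotype while keeping member sites unbiased markers of carrier
  status. The default is small so that the planted within-group linkage
  sits in the near-perfect stratum (r² ≈ 0.995) the marker clustering
  assumes, and so that the representative site of the top group remains an
  essentially exact carrier readout whichever member is chosen.

**Phenotypes.** Dosage-additive: trait = class baseline + effect ×
(carrier dosage / 2) + Gaussian noise, so a homozygous carrier realises
the full effect (+3.32 g protein, −2.66 g oil per 100 g seed) and a
heterozygote half of it. Class baselines (protein 46/43/42/42, oil
12/19/20/20 g/100 g) are plumbing choices reflecting protein-rich,
oil-poor wild seed; they are configurable and cancel out of all
within-class contrasts. The noise standard deviations default to
0.4 g/100 g: with ~8 homozygous landrace carriers expected per default
cohort, this makes the prescribed recovery check (planted effect within
±0.1 averaged over ten replicates) a ~2-standard-error statement rather
than a coin flip. Real seed-composition variances are larger; the
generator models the *residual* noise around a haplotype-conditioned mean,
not total phenotypic variance.

**Repeat locus.** A multiallelic insertion record at position 31,727,019:
REF is the anchor base, each ALT appends k CAA units. Five invariant
copies are common to everyone, so total copies = 5 + k. Carrier samples
draw a total copy number from the reference panel's homozygous-class
distribution (6–14 copies, proportional to counts 2/10/8/21/13/24/46/30/1);
each carrier haplotype independently re-draws with probability 0.05,
emulating the hypermutability of tandem repeats and populating the
heterozygous-repeats category.

**Deletion and depth tracks.** The 304 bp deletion `[31,728,619,
31,728,923)` is carried by samples whose *both* haplotype copies are
carriers (an intact copy masks the coverage drop); a configurable
decoupling rate flips flags to emulate imperfect co-inheritance. Depth is
emitted per base over the deletion ± 1.5 kb: per-sample background level ~
U(8, 50)×, Poisson-jittered per base; inside the deletion, present samples
drop to per-base Bernoulli(u) with u ~ U(0, 1), so the "uniform 0–1×"
contrast holds with every base at most 1. A Poisson around a sub-1 mean
would scatter bases above the caller's `low_max = 1` cutoff and shred the
low-coverage run, which is why the in-deletion law is Bernoulli. A nested
25 bp insertion is planted at the deletion start in ~15.5% of
deletion-present samples.

**Background SNPs.** 200 sites across the wider 450 kb region with
class-structured allele frequencies (Balding–Nichols drift, Fst 0.05),
giving the PCA stage genuine population structure to find.

**Missingness.** Each genotype goes missing with probability 0.02; a fifth
of those lose only one allele, exercising the half-missing (HETMISS)
bookkeeping end to end.

**What the generator does not emulate:** long-range background LD beyond
the region (real panels show r² > 0.7 a megabase away), recombination
maps, kinship beyond class labels, read-level artefacts, GATK annotation
fields, and the real panel's absolute diversity levels. Passing recovery
tests therefore demonstrate estimator correctness under the planted model,
not field performance on resequencing data.

## Variant store

Filters follow the source conventions: QUAL ≥ 30, per-site missing-allele
fraction ≤ 0.10 (a half-missing genotype counts half), minor allele
frequency ≥ 0.01 over called alleles (minor = second most common allele).
The InDel streams instead use a "keep if any single non-reference allele
reaches 1%" rule. GATK annotation filters (QD/MQ/FS/…) are out of scope:
they need caller INFO fields that the synthetic VCF does not carry.

InDel records are split by allele length (longer than REF → insertion
stream, shorter → deletion stream; equal-length non-SNP alleles dropped
with a warning count), each stream is recoded to a presence/absence proxy
biallelic site (REF=T / ALT=A — reading the recoding's "Tyrosine" as a
typo for Thymine), and streams are re-merged position-sorted with a
`PROXY_TYPE=ins|del` tag so a position segregating both variant types
keeps two sites. Half-missing genotypes are kept as half-missing through
recoding.

## LD engine

Statistics are computed on phased haplotypes (the source data were
BEAGLE-phased; the generator emits phased genotypes). Unphased input is an
error rather than a silent approximation; an EM-based gamete-frequency
estimator is listed as future work. Half-missing diploids contribute their
one called haplotype.

For two biallelic sites, D = pAB − pA·pB over jointly called haplotypes;
D′ = |D| / Dmax with the usual direction-dependent Dmax; r² = D² /
(pA qA pB qB). Monomorphic pairs are undefined (NaN) and excluded.

**Gabriel blocks.** The 90% confidence interval on D′ is obtained by
profiling the multinomial likelihood of the four gamete counts over a
fixed 101-point D′ grid (allele frequencies held at their sample
estimates) — the approach popularised by Haploview/PLINK; the grid is
fixed for reproducibility. A pair is strong LD when CI = [≥0.70, ≥0.98],
strong recombination when the upper bound is < 0.90; a candidate block has
a strong-LD outermost pair and ≥95% strong among informative pairs;
non-overlapping blocks are chosen greedily by descending bp span, ties to
the leftmost start.

**Region delimitation.** Sites with r² ≥ 0.91 to the focal SNP are chained
outward from it as long as consecutive supporting sites are within
`max_gap` (default 50 kb). The original study delimited its region by eye
from decay plots; `max_gap` is this package's explicit, configurable
stand-in for that judgement and is logged in the output. In the full
pipeline the *haplotyping* stage then takes its region bounds from
configuration (as the original workflow fed the printed 173 kb bounds to
its haplotyping tool), falling back to the LD-delimited region when no
bounds are given.

## Association scan

A deliberate methodological substitution: the original discovery used
FarmCPU and MLM mixed models, which are out of scope. Here phenotype is
regressed on per-site alternate-allele dosage plus the first three
principal components of the mean-imputed dosage matrix, with the
Bonferroni threshold alpha / (tested sites). Missing dosages are
mean-imputed for the scan only — never for LD or haplotyping. The scan
exists so the pipeline is end-to-end runnable and its focal-group
discovery testable; with ~0.4 g noise every member of the focal group is
statistically indistinguishable from the focal SNP, so the tested
discovery property is that the top hit lands in the focal marker group.
Welch's unequal-variance t test (with Welch–Satterthwaite degrees of
freedom) backs all group contrasts.

## Haplotype miner

Marker filtering first sets heterozygous genotypes to missing, then drops
sites with > 60% missing alleles, > 30% heterozygous genotypes (measured
pre-masking), < 1% alternate allele frequency, or < 4 alternate alleles.
Clustering is single linkage on the graph with edges r² ≥ 0.9: marker
groups in this analysis are maximal linked sets, which is exactly what
connected components give. Kinship/structure-corrected LD ("r2vs") is not
implemented; plain r² is used, as the original analysis itself did for
cluster LD. The representative site has the lowest missingness (ties:
higher MAF, then lower position).

Groups are numbered M01, M02, … by descending |mean protein difference
between homozygous-ALT and homozygous-REF samples at the representative
site| — the source does not state how its groups were numbered, so this
package's convention makes M01 the most protein-associated group by
construction, and it is recorded in all outputs.

Pruning applies three rules in order: (1) among groups with identical
representative-state vectors over the provisional haplotype combinations,
keep the one with the most member SNPs; (2) drop groups with five or fewer
member SNPs; (3) of any pair whose member sets differ by exactly one SNP,
drop the smaller. Emptying the group list raises an error advising a
threshold change.

Haplotype combinations are defined on diploid five-state vectors
(REF/HET/ALT/HETMISS/MISS) at the representative sites, matching the
five-state accounting of the source figures; samples with a fully missing
state at any group are reported separately as unassigned rather than
folded into a combination.

**Diversity.** π and dXY use invariant-site-aware estimators: per variant
site the mismatch count over called allele pairs, with invariant sites
contributing only comparison denominators (they are assumed fully
genotyped — the per-site missingness of invariant sites is not modelled).
The invariant-site count comes from a region-length header tag in the
synthetic VCF or an explicit argument. A brute-force pairwise-difference
oracle verifies the estimator on all panels of ≤ 8 haplotypes.

## Repeat and SV calling

Insertion annotation is total: a pure whole-number CAA concatenation is a
conservative in-frame insertion (CIF); any other length-divisible-by-3
insertion is disruptive in-frame (DIF); anything else is a frameshift
(FSV). Individuals are classified as reference, homozygous repeat (by
total copies), heterozygous repeats, single repeat (one insertion + one
reference allele), other (homozygous non-repeat insertion), or missing.
The printed coordinates of the five invariant copies are ambiguous by one
base between inclusive and half-open readings, so the locus is anchored by
its VCF record position rather than by those coordinates.

The percent protein increase of repeat carriers contrasts the
count-weighted mean of the homozygous CIF copy classes against the
reference class. The four individuals homozygous for atypical insertions
are excluded by default: re-deriving the statistic from the printed class
rows gives 7.95% without them versus 7.80% with them, and the former
matches the printed 7.9%; a documented toggle
(`include_other_in_increase`) flips the choice.

The deletion caller scans per-base depth inside a candidate interval for
the longest run of bases ≤ `low_max` (default 1×); presence requires run
length ≥ 50 bp and a mean depth ≥ 8× over up to 1 kb flanking the run.
Samples with sub-8× tracks and no qualifying run are *uncallable*, not
absent. The reported interval is the median of per-sample run boundaries,
robust to single-sample depth noise. SV–SNP linkage proxy-recodes
per-sample presence onto both haplotypes and reuses the LD engine; because
presence is a per-sample (effectively recessive) readout while the focal
SNP is per-haplotype, r² against the focal SNP is attenuated in cohorts
with many heterozygous carriers even under perfect co-inheritance, while
D′ stays near 1 — the pipeline reports both.

## Pipeline

Stages run in dependency order (simulate → validate → filter → scan →
LD → haplotype → repeat → SV → report), each writing its own outputs and a
log section; the run config is serialized with a per-parameter source flag
("paper" vs "invented" defaults), and a failed stage halts with exit
code 3 naming the stage. All randomness flows from the single run seed.

## Problem sizes and verification

The shipped tests and the acceptance script run entirely on generated
cohorts: effect recovery uses ten default cohorts (985 samples, ~274
sites each), frequency recovery five cohorts with 1000 wild accessions,
the LD/π oracles 1000 and 200 random instances, and the null-calibration
check 250 phenotype permutations of a 300-sample landrace cohort — sizes
at which every check is a sharp statistical statement yet the whole suite
completes in well under a minute per file. Known limitations: no unphased
input, no BCF, no imputation, single-chromosome scope, and the caveats
about synthetic realism above.
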