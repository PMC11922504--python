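# Methods

This note documents the statistical model behind each module, the default
parameters and why they hold their values, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the design was genuinely open.

## Pseudohaploid genotyping

Low-coverage ancient genomes do not support diploid genotype calls, so
each individual is represented at each biallelic panel SNP by a single
read drawn uniformly at random among reads with base quality ≥ 30 and
mapping quality ≥ 30 (`min_bq`, `min_mq`, both config-exposed).  A drawn
base matching neither panel allele marks the site as removed; by default
removal is per individual (the site stays usable for clean individuals,
recorded as missing for the affected one), with a global-removal switch
that drops the site for everyone.  Per-individual random substreams are
derived from (seed, SHA-256 of the label), so adding an individual never
perturbs existing calls.

Post-mortem deamination in UDG-treated libraries survives mainly at
fragment termini as C→T (5′) and G→A (3′) substitutions.  Rather than
discarding all transition SNPs, terminal T bases within the first 5 bp and
terminal A bases within the last 5 bp of a fragment have their base
quality floored to 2, below the calling threshold.  The operation is
idempotent and deliberately crude: genuine terminal T/A evidence is lost
too, a price the filtering-comparison analysis quantifies (the alternative
— a transversion-only panel — loses roughly two thirds of a realistic
panel and inflates f4-ratio standard errors by ~1.6–1.7× in our
simulations).

Panel management follows the usual conventions: biallelic SNPs at minor
allele frequency ≥ 0.10 (`maf_min`), 1-based SNP coordinates, EIGENSTRAT
geno/snp/ind I/O (pseudohaploid calls written 0/2/9 by default, 0/1/9 via
a dialect flag, since both codings circulate), VCF input via cyvcf2, and a
parser for samtools pileup text.

## f-statistics and the block jackknife

f2, f3 and f4 are estimated as plain means of per-site products of
frequency differences over the sites where all involved populations have
data ("complete cases per statistic", the allsnps-style convention that
keeps low-coverage individuals usable).  No small-sample heterozygosity
correction is applied: with single pseudohaploid genomes per population —
the dominant ancient-DNA case — no unbiased correction exists, a known
bias shared with the field's standard tooling.

Uncertainty comes from a weighted delete-one block jackknife over
contiguous genomic blocks (default 5 Mbp, half-open, genomic rather than
equal-SNP-count; an equal-SNP-count constructor exists for comparison with
tools using that convention).  The weighted variance formula (Busing-type,
with block weights = usable-site counts) reduces exactly to the classical
delete-one jackknife at equal weights — for the mean, SE =
SD(block values, ddof=1)/√B — which the tests freeze as an oracle.

The f4-ratio estimator of wild ancestry,
α = 1 − f4(O1,O2;X,W)/f4(O1,O2;D,W), requires O1 to share drift with W
relative to D (here: Caucasus aurochs with European aurochs relative to
Anatolian domestic).  Its SE recomputes the full ratio on each
leave-one-block-out replicate rather than using the delta method, matching
jackknife-of-ratio practice; numerator and denominator keep separate
per-block site counts, and the jackknife weights are their sums.
Denominators below 10⁻¹² raise an error naming the degenerate
configuration; a warning flag is set when |denominator| < 2 SE.  α is not
clamped: sampling noise legitimately yields estimates outside [0, 1], and
clamping would bias the time-series averages such studies report.

## qpAdm-style admixture modelling

The target T is modelled as Σ wᵢ Sᵢ with Σw = 1.  With rights r₁..r_R
(r₁ the base), each equation f4(T,r₁;rⱼ,r₁) = Σᵢ wᵢ f4(Sᵢ,r₁;rⱼ,r₁) is
estimated per 5 Mbp block; sites missing in more than `maxmiss` (default
0.5) of the involved populations are excluded first.  Weights minimize
the GLS quadratic form under the sum constraint (KKT solve); because the
residual covariance depends on the weights, the fit iterates weights →
jackknife covariance of the residual vector → refit (3 rounds, well past
convergence in practice).  The minimized form is referred to
χ²((R−1)−(S−1)); weight SEs come from leave-one-block-out refits with the
full-data covariance (re-estimating the covariance per deletion would be
quadratic in blocks for no measurable gain at 200 blocks).  Covariances
with condition number above 10¹² receive a ridge of 10⁻⁶·trace/dim.

Weights are never sign-constrained.  Fits with p < 0.01 or weights outside
[0, 1] are flagged rejected, and `rotate_models` enumerates every
assignment of the rotatable populations to {source, right, unused} —
including saturated (dof = 0) source expansions, which carry no fit test
(p = NaN) and rank below any feasible tested model.  The p-value threshold
0.01 and the base-right convention (first listed) are config-exposed;
tests assert weight invariance to permuting the non-base rights.

This formulation reproduces the estimand, dof convention and rejection
behaviour of the original likelihood machinery without re-implementing it
verbatim; on correctly specified two-source simulations its p-value is
approximately uniform (KS test does not reject over 200 replicates) and a
hidden 20% third ancestry at 50k sites rejects the two-source model in
essentially every replicate.

## NMDS ordination

Outgroup-f3 shared drift is converted to dissimilarity as d = 1 − f3
(diagonal forced to zero; d may exceed 1 when f3 < 0, which is a valid
dissimilarity).  The embedding minimizes Kruskal stress-1 by SMACOF:
isotonic (pool-adjacent-violators, via scikit-learn's IsotonicRegression)
regression of configuration distances on the dissimilarity order —
primary/untied treatment, ties broken by input index for determinism —
alternating with the Guttman transform.  Stress is checked non-increasing
at every iteration; iteration stops when the decrease falls below `tol`
(10⁻⁷).  Start 0 is the metric (Torgerson PCoA) configuration and the
remaining starts are random, the metaMDS-style compromise: with perfectly
Euclidean input the metric start converges to the similarity-equivalent
solution (pure random starts can reach zero stress at configurations that
are only monotonically, not linearly, related to the input — a real
degree of freedom of nonmetric MDS).  Default 100 starts (10 in the
pipeline's desk-scale runs); axis signs are fixed by forcing a designated
wild reference positive on axis 1.  Procrustes alignment
(rotation/reflection/scale/translation) serves for comparing solutions,
and axis-ancestry association is an OLS of f4-profile values on axis
scores.

## Mitochondrial contamination

At sites where the sample's consensus allele is nearly private (< 5%
frequency in a panel of 278 diverse mitogenomes), a read from another
individual almost surely mismatches the consensus.  Informative sites are
private sites with ≥ 10 quality-passing reads, excluding damage-prone
sites: a C/G-consensus site is dropped when the consensus↔panel-major
pair is a transition (a stricter drop-all-C/G mode is selectable).  One
read is drawn per informative site and the contamination fraction c is
the proportion of non-consensus draws with SE = √(c(1−c)/n) and a normal
95% CI truncated to [0, 1]; a Wilson interval is available by flag.  One
draw per site — not pooled reads — is the binomial unit: pooling
pseudo-replicates reads within a site and understates the SE (a pooled
mode exists for comparison).  The worked examples 15/29 → 51.7%
[33.5, 69.9] and 9/108 → 8.3% [3.1, 13.5] are exact under this reading.

Known limitation: at high contamination the consensus *called from the
reads* flips to the contaminant allele at a substantial share of private
sites, which silently removes them and biases the estimate low; the
calibration therefore feeds the estimator the true endogenous haplotype,
isolating the binomial machinery.  Estimates near 50% from real data
should be read as "heavily contaminated", not as precise fractions.

## Molecular sexing and sex-biased admixture

Rx generalizes X/autosome coverage sexing to the 29-autosome cattle
karyotype: per chromosome, rate = (reads/total)/(length/total length);
Rx is the mean over the 29 ratios rate_X/rate_i, with the published
interval 1.96·SD(ratios)/√29.  That interval reflects only
between-autosome spread — the shared X-count noise does not shrink with
√29 — so it is used for the threshold rule it was designed for (XX when
the whole CI exceeds 0.8, XY when below 0.6, else unassigned; thresholds
from the mammalian Rx literature, config-exposed), not as a coverage-
calibrated CI.  Assignment accuracy at 10k mapped reads exceeds 95% in
simulation.  Sexing is attempted above a default 5,000 mapped reads.

Sex bias: Z = (α_auto − α_X)/√(SE_auto² + SE_X²), two-sided normal p.
Autosomal and X blocks are disjoint chromosomes, so independence is exact
at the block level; the test is conservative to within jackknife noise.
Under male-biased wild introgression the X carries less wild ancestry
(males pass no X to sons), so positive Z is the expected signature.

## The synthetic-data generator

Populations sit on a Balding–Nichols drift tree: each branch with drift F
draws child frequencies from Beta(p(1−F)/F, (1−p)(1−F)/F) around the
parent's p, ancestral frequencies ~ Uniform(0.05, 0.95) so a MAF ≥ 0.10
filter keeps most sites.  The default topology is
(yak,(bison,(indicine,((caucasus,european aurochs),anatolian domestic))))
— an aurochs clade sister to the domestic lineage, which is what makes
the f4-ratio denominator non-zero and matches the roles the real
reference genomes play.  Admixed targets mix European-aurochs and
Anatolian-domestic frequencies at known α (autosomes) and α_X (X).

Default drift values (yak 0.20, bison 0.25, indicine 0.15, internal
branches 0.03, aurochs-clade stem 0.60, Caucasus 0.08, European 0.10,
Anatolian 0.12) are chosen so that desk-scale panels — tens of thousands
of sites instead of the ~9 million genome-wide SNPs such studies use —
give comparable ancestry resolution: the f4-ratio SE scales as
1/(shared-drift × √sites), so compressing the genome 450-fold requires
proportionally stronger drift for the same CI width.  They are
illustrative separations, not inferred population-genetic parameters.
Reference populations are represented by 25 sampled haploid genomes each
(panel-like references), targets by one pseudohaploid individual at
Poisson mean depth 2 with sequencing error 10⁻³ — the regime where
low-coverage ancients are compared against better-characterized
references.  Read simulation covers fragment lengths 35–80 bp, C→T damage
with amplitude p₀ decaying exponentially from the 5′ end (G→A mirrored at
3′), and emits offsets so the rescaling rule acts on it.  The
mitochondrial simulator plants rare alleles as transversions to A or T —
never trippable by the C/G damage filter — so private-site recovery is
exact by construction.

What the generator does **not** emulate: linkage and recombination (sites
are exchangeable within blocks, so the jackknife's LD rationale is not
exercised — blocks are validated as variance bookkeeping, not as an LD
correction), reference bias, varying fragment-length/damage profiles per
library, heteroplasmy, and realistic per-breed demography.  Passing
calibrations therefore demonstrate estimator correctness under the
assumed model, not robustness to every artefact of real ancient data.

## Calibration battery (problem sizes)

`bovid_admix.calibration` fixes the experiment sizes: 200 targets at 20k
sites for f4-ratio recovery (MAE ≈ 0.01, CI coverage ≈ 95%), 200
replicates at 20k sites for qpAdm calibration, 100 replicates at 50k
sites for three-source rejection power, 100 replicates each for sexing
(10k reads) and sex-bias (20k autosomal / 2k X sites), 20 damaged targets
at 20k sites for the filtering comparison, and 60–100 replicates at 140
diagnostic sites for mitochondrial calibration.  140 sits where the
normal-approximation interval attains nominal coverage even at 2%
contamination — exact-binomial Wald coverage oscillates with n, and the
k=1 interval's upper bound ≈ 2.96/n falls below 0.02 beyond n ≈ 148.
The whole battery runs in about six minutes on one CPU.

## Degenerate inputs and tie-breaking

Monomorphic sites never pass a positive MAF filter; empty piles yield
missing, not errors; consensus ties break by base order A<C<G<T; NMDS
rejects all-equal dissimilarities; f-statistics raise a no-data error
(never silently return 0) when no site is complete; the jackknife refuses
a single block; zero informative mitochondrial sites raise an error
distinct from an estimate of 0; Rx names the offending autosome on a
zero count.
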