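# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `transplantomics`. Notation: the two selection lines are
AM (ambient) and OWA (warming + acidification); `Line_Environment` subscripts
denote transplant state, e.g. OWA_AM is the OWA-evolved line moved back to
ambient conditions. The design is 2 lines x 2 environments x 4 replicate
cultures x 3 post-transplant generations = 48 pooled libraries.

## Variant filtering and divergence testing

Filtering runs as an ordered cascade on biallelic read counts and each rule's
rejections are reported so the ledger sums to input − output:

1. every sample at >= `min_sample_coverage` (default 50x) total reads — this
   also removes any site with missing (zero-depth) data;
2. median-across-samples depth <= `max_depth_factor` (3) x the dataset-wide
   median site depth, flagging collapsed paralogs and other pile-ups;
3. within-sample minor-allele read frequency >= `min_sample_maf` (0.025) in
   >= `min_variable_samples` (4) samples. The 0.025 default is one
   heterozygote among 40 chromosomes in a pool of 20 diploids; the
   frequency is computed from reads, not genotypes, because the data are
   pooled.

The exact order of the cascade is a package choice (coverage, then depth cap,
then variability); only the combination is identifiable from the outputs, and
the rejection ledger makes the order auditable.

Divergence per generation uses the classic Cochran–Mantel–Haenszel chi-square
without continuity correction over the four replicate strata, with read
counts entering the 2x2 tables directly. Correction choice is invisible at
>= 50x coverage; strata with a zero margin carry no information about the
odds ratio and are skipped rather than 0.5-corrected. An optional rescaling
of read counts to effective chromosome counts exists but defaults to off:
read-based tests treat sequencing depth as the unit of evidence (liberal when
depth exceeds 2 x pool size), and the default mirrors the common pooled
practice. The test-suite oracle for the CMH p-value is an exact
fixed-margins permutation enumeration under the product-hypergeometric null,
scored with the mid-p convention — the standard exact comparator for an
uncorrected chi-square; agreement is asserted within a factor of two for
small tables.

The Bonferroni threshold is alpha / (n_sites x n_generations_tested); the
adaptive set is the order-preserving intersection of the per-generation
significant sets. Requiring significance in all three generations trades
false positives (linked neutral sites) against false negatives (redundant
polygenic responses that are not parallel across replicates).

## Expression model

Counts are filtered (a gene must reach 10 counts in more than 10% of
samples), normalized with median-of-ratios size factors (geometric-mean
reference over genes with all-positive counts) and transformed as
log2(normalized + 1). The log transform feeds only the discriminant-space
geometry, where rank structure is what matters; no variance-stabilizing
shrinkage is applied.

Differential expression is a two-group negative-binomial log-linear model per
gene, fitted by IRLS with the sample log size factor as offset. The NB
dispersion (variance = mu + alpha mu^2) is estimated per gene by method of
moments on normalized counts pooled within groups, floored at 1e-8, and
shrunk 50% in log space toward a log-linear trend of dispersion on mean.
The trend is fitted on the log scale and then moment-matched on the ratio
scale: the log of a noisy variance estimate is biased low (Jensen), and
without the correction the Wald test is visibly anticonservative at n = 4+4
(~7.5% of null p-values below 0.05). With it, a null simulation at the
package's defaults is calibrated (raw p approximately uniform) while a
planted 4-fold change at mean 100 and NB size 5 is detected in > 90% of
genes after BH adjustment. This estimator is deliberately simple; it does
not do empirical-Bayes per-gene shrinkage, and genes whose true dispersion
is far above the trend will be tested liberally.

Plastic gene sets are the within-line home-vs-transplant contrasts at
BH-adjusted p < 0.05. The PO/GC partition operates on genes diverged between
the two home lines: a gene is *genetic change* (GC) when the transplanted
line still differs from its destination home line, *plasticity only* (PO)
when it is plastic within the source line and not GC, and unclassified
otherwise — so PO and GC are disjoint and need not exhaust the eligible set.
The plasticity comparison between lines is an unweighted OLS slope of one
line's log2 fold changes on the other's over genes significant in either
line (union); the regression flavour (OLS vs major-axis) and the gene set
(union vs intersection) are both package choices exposed as parameters of
`lfc_slope` via its mask argument.

## Discriminant shifts

The DAPC is PCA on centered features followed by a single linear discriminant
for the two home-line groups: axis ∝ (pooled within-group covariance)^-1 x
(mean difference), computed on the retained PC scores with a 1e-8 ridge for
singular cases, unit-normalized. Defaults retain 4 PCs for expression and 3
for allele-frequency features (alt read fraction at filtered sites); a
retain-to-80%-variance mode exists because no single retention rule suits
every dataset. Transplanted samples are projected affinely; home samples
reproduce their fitted coordinates.

Shift inference is a Gibbs sampler for
coordinate = b0 + b_line + b_transplant(line) + u_culture + e, with a random
intercept per replicate culture, vague normal priors (precision 1e-4) on
fixed effects and IG(1e-3, 1e-3) priors on both variances. After 500
burn-in iterations, 2,500 draws are retained; per-effect p-values are
2 x min(Pr(>0), Pr(<0)) floored at 1/2,500 = 4e-04 (reported "at floor" when
no draw crosses zero), and the magnitude comparison is the posterior of
|shift_AM| − |shift_OWA|. A split-chain R-hat above 1.1 flags
non-convergence. With 16 observations and 8 cultures the posterior is
dominated by the data for any clear shift; the floor, not the tail shape, is
the operative precision limit.

## Nucleotide diversity

Per site, pi = 2 ref alt / (C (C−1)) is the unbiased probability that two
distinct reads differ — verified in tests against literal pair enumeration
up to 50x. No pool-size correction is applied by default: at pool 20 and
>= 50x it is a near-constant factor that cancels in the Δπ contrasts; an
n/(n−1) chromosome-count correction is available as a knob. Windows tile
each contig in 100-bp non-overlapping, 0-based half-open intervals (a
1-based site at position p maps to window (p−1)//100) and divide by the full
window length, so invariant and uncovered positions contribute zero.
"Adaptive windows" are windows containing >= 1 adaptive SNP — the minimal
reading of region-level flagging.

Median per-replicate window diversity is compared across treatment x
generation cells by one-way ANOVA with Tukey HSD (with a compact letter
display); targeted loss is a two-sided Mann–Whitney test per cell comparing
Δπ (mean over replicates, relative to the mean AM_AM F1 value of the same
window) between adaptive and non-adaptive windows, Bonferroni-corrected over
the cells tested.

## Enrichment

Functional enrichment is threshold-free: each category (flat gene sets; no
ontology-graph propagation or category merging) is tested one-sided for
whether its genes' statistics fall toward the chosen tail of the genome-wide
distribution. Mann–Whitney U uses exact enumeration when both group sizes
are <= 8 and the values are untied, and a tie- and continuity-corrected
normal approximation otherwise; BH adjustment runs across categories.
Allelic statistics are collapsed to one value per gene as the minimum
p-value over the gene's SNPs (reported as −log10).

## Life history

EPR = (E_u + E_h)/t and HS = E_h/(E_u + E_h). Records with a dead female are
excluded entirely (egg production cannot be attributed); dead-male records
keep EPR but not HS; zero-egg records have EPR = 0, undefined HS and a
fecundity of zero. Survival P_1 = 1 by convention and P_x = l_x / l_{x−1},
held at 0 after extinction. The Leslie matrix is built on the observation
grid (no interpolation between monitoring days), with fecundity
EPR x HS x (n_females/(n_females + n_males)) on all days >= the first
observed adult day — proportion female is the demographically standard
reading of sex-ratio scaling (a raw female:male ratio mode exists), and a
strict-after mode shifts fecundity one day later. Every eligible mate pair
is crossed with every eligible beaker per treatment x food cell (up to
4 x 12 = 48 matrices); lambda is the Perron root and the cell summary is
x̄ ± 1.960 SD/√n. Log-rank survivorship tests reconstruct per-individual
event times from the l_x decrements, right-censoring survivors at the last
observation.

## Synthetic data

The generator reproduces the study conditions wherever they are fixed by the
design — 48 samples, pools of 20 diploids, mean coverage 174x with
negative-binomial depth dispersion, 20 burn-in + 3 transplant generations,
4 replicate beakers and 12 mate pairs per treatment x food, 25 starting
nauplii — and desk-scale problem sizes where they are not: 4,000 loci and
3,000 genes by default, which preserve every statistical structure the
analysis exploits at a fraction of the transcriptome-scale cost.

Allele trajectories are Wright–Fisher (binomial sampling of 2 ne gametes,
ne = 1000 by default — within-culture effective size is not observable from
the design, so this is an exposed guess) with multiplicative single-locus
selection at unlinked loci: a fraction `prop_selected` (default 0.055, the
observed adaptive fraction) is favoured in the OWA line during burn-in at
s = 0.3 per generation (strong enough that parallel divergence is
detectable across four replicates in 20 generations), and the same loci are
selected in the reverse direction in OWA_AM cultures during transplant.
Read counts are binomial at the realized pool frequency; allele-biased
expression is off by default (a bias knob exists) since the original
analysis found no impact of it.

Expression is negative-binomial (size 5) around a log2 mean of
baseline + genetic effect (line) + plastic effect (environment). The
assimilated subset of plastic genes (default 90%) is modelled as
*constitutively induced* in the OWA line: the plastic effect applies in both
environments rather than being zeroed. This is the operational meaning of
genetic assimilation — the formerly plastic state becomes heritable — and it
is what generates the observable signatures at once: those genes diverge
between home lines, respond plastically only in the AM line, classify as PO
under forward adaptation and GC under reverse adaptation, and make the AM
line's discriminant-space transplant shift larger than the OWA line's. A
loss-without-assimilation variant (both-environment baseline) would silence
all of those signals and contradicts the phenotype being emulated.

Life-history parameters (daily survival 0.94–0.97 by treatment, EPR 10–15
eggs/day, hatching success 0.70–0.85, maturity at day 11 of a 14-day
series) are plausible for calanoid copepods at the experimental
temperatures; food limitation halves fecundity and starved cultures get a
daily survival low enough (0.3) that no individual reaches maturity, the
categorical outcome of the starved assays. Survivors at maturity are sexed
by a fair Bernoulli draw.

What the generator does **not** emulate: linkage (loci are independent, so
the scan's false-positive behaviour near true sweeps is not exercised),
transcriptome-wide mean-dispersion relationships estimated from real data,
batch or lane effects, development-time differences between treatments
(maturity day is fixed per run), and transgenerational plasticity. Tests
passing on synthetic data therefore demonstrate correctness of the
estimators and the recoverability of the planted structure, not robustness
to those real-data complications.

## Reproducibility and problem sizes

One top-level seed drives everything; each stochastic stage derives a child
seed from (seed, stage name) by CRC-32, so stages are independently
reproducible and the full pipeline is bit-stable (asserted in tests). The
test suite and the acceptance script use desk-scale sizes (hundreds to a few
thousand loci/genes); all estimators are vectorized, and a full default-size
run (4,000 loci, 3,000 genes, 2,500 Gibbs draws per generation and data
type) completes in seconds on one core.
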