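# Methods

## Scope and data flow

The package implements the analysis chain for two-heat-level trials of
connected bi-parental maize populations: simulation of the experiment,
genotype quality control, mixed-model trial analysis, heat susceptibility
indices (HSI) with resampled heritability and Q_ST, molecular diversity,
and GBLUP genome-wide prediction with training-set resampling schemes.
Upstream sequence processing (demultiplexing, trimming, alignment, variant
calling, haplotype-based imputation) is out of scope: those steps are the
territory of published tools, and the package starts from genotype calls
or posterior genotype probabilities.

## Simulation model

**Genome and meiosis.** Markers are placed uniformly at random on each
chromosome (allocation proportional to map length) and sorted; parents are
fully homozygous inbreds with biallelic markers, perturbed where necessary
so every marker segregates somewhere in the parent set. Meiosis follows
the Haldane model: the crossover count per chromosome is Poisson with mean
equal to the length in Morgan and crossover positions are uniform — no
interference, consistent with the use of plain map distances. Map
positions are stored in centiMorgan and converted to Morgan only inside
meiosis.

**Crossing scheme.** The default experiment crosses eight parents into six
populations (two Dent×Dent, two Flint×Flint, two Dent×Flint: D1×D2, D3×D4,
F1×F2, F3×F4, D1×F1, D4×F4) and selfs each F1 for two generations, so a
"genotype" is an F3 plant (expected heterozygosity 25% at segregating
loci; the genotyped bulk of an F3:4 family is treated as the F3 genotype).
Each population has 100 progenies by default — inside the 75–107 range of
the emulated design; the exact per-population counts are configurable
because only the range is fixed by the design.

**Phenotypes.** An observation is
mu + genetic value + condition effect + replicate effect + block effect +
residual, with the genetic value per condition
sum(additive·count) + sum(dominance·[count==1]) over the trait's QTL.
Heat-specific per-QTL effect multipliers (|N(1.4, 0.5)| by default) make
the genetic value condition-dependent, which is what gives the HSI a
non-zero genetic variance and reproduces the empirically common pattern of
larger genetic variance under heat. Defaults per trait: ~40 QTL with
additive effects scaled so the standard-condition genetic variance is near
1; residual variances drawn from U(0.8, 2.0) (heat inflated by up to 30%),
giving entry-mean heritabilities in the 0.5–0.85 band; replicate variance
0.2; block variance 0.25·sigma2_e (no block variance is dictated by the
emulated design, so a quarter of the residual is used as a realistic
incomplete-block share); mu = 60 with a heat effect of −15, i.e. a
leaf-length-like scale whose across-genotype AEM ratio stays well away
from 1 (the HSI denominator). The trial layout is a randomised
incomplete-block design: per replicate the genotypes are shuffled and cut
into 32 near-equal blocks (three replicates per condition).

**Problem sizes.** The default dense marker set has 5440 = 170·2^5 markers
on a 10-chromosome, 1823.5 cM genome, and the sparse set is a 170-marker
subset spread evenly across the dense map. These sizes preserve the
sparse-set scale and the doubling geometry of the marker-number analysis
while keeping the full simulated study (simulation, kinship, resampling)
comfortable on a single CPU; the dense count is a package default, not a
statement about any particular sequencing platform.

**Genotype probabilities.** The posterior-probability emulator assigns the
true class a mass ≥ 0.985 for accurate calls, puts 0.5–0.9 on a random
wrong class for an `error_rate` fraction, and gives near-uniform triples
to a `missing_rate` fraction (and to truly missing calls), which the
GP-cutoff filter downstream turns back into missing calls. What it does
*not* emulate: linkage-informed posteriors (neighbouring-marker
correlation of errors), allele-frequency-dependent error structure, or
depth-dependent uncertainty. Tests passing on these data therefore
validate the filtering arithmetic, not the behaviour of any specific
imputation software.

## Genotype quality control

Probability-cutoff calling supports three policies: GP1 (accept only
probability 1, read as ≥ 1−1e−9 for floating-point safety — a strict
reading would discard everything), GP0.98 (accept > 0.98) and MAX (always
accept the argmax, ties broken toward the heterozygote and then the lower
code). Created missing calls are mean-imputed per marker. The
segregation-distortion filter is a per-population two-sided *exact*
binomial test of the alternate-allele count against the expected frequency
(0.5 for progeny of an inbred cross), removing markers with P < 0.001; the
exact test was chosen over chi-square because populations are small and
exactness is directly testable. Sparse-assay marker selection takes, per
population, markers homozygous-polymorphic between its two parents and
greedily maximises the minimum pairwise map distance, preferring markers
already selected for other populations (panel overlap).

## REML engine

The mixed-model engine fits independent random factors (genotype,
genotype×condition, replicate-within-condition, block-within-replicate) by
average-information REML with an EM fallback, working on the Henderson
mixed-model equations so cost scales with the number of effect levels.
Scores and the AI matrix are computed from MME solves; each step is
accepted only if the restricted log-likelihood does not decrease (EM
otherwise); variances hitting the zero boundary are clamped and removed
from the working model. Convergence: relative log-likelihood change
< 1e−8 or 200 iterations; non-convergence is flagged, not raised. Fixed
effects use intercept + drop-last dummy coding; aliased columns are
dropped deterministically (later columns first). On balanced one-way data
the estimates agree with the closed-form ANOVA estimators to ~1e−12,
and on small crossed designs with a direct dense-V Nelder-Mead reference
to ~1e−6 (both frozen in tests).

The heat-level test is a Wald F on the condition contrast with containment
denominator degrees of freedom (replicate-within-condition levels − 2);
its empirical size is checked by simulation. Adjusted entry means are
estimated marginal means (intercept + genotype effect + average replicate
effect) from the single-condition model with genotype and replicate fixed
and blocks random; no lattice-specific recovery of inter-block information
beyond the random block effect is attempted.

## HSI, resampled heritability, Q_ST

HSI follows the susceptibility-index form given in the README; one formula
is applied to all traits, including those where larger values mean more
damage (no sign flip). For the resampled heritability, replicate and block
effects are first estimated per condition with genotype, replicate and
block all fixed, centred to mean zero, and subtracted (centring preserves
the condition means, which matter because the HSI is a ratio). Each round
pairs, independently and uniformly per genotype, the three heat with the
three standard replicates; the across-genotype means inside a round come
from the adjusted data (a permutation leaves them equal to the grand
adjusted means, so each round is self-contained). Per round a one-way
genotype-random model gives h² = sigma2_g/(sigma2_g + sigma2_e/3) — on
balanced rounds the exact closed form is used — and the median over rounds
(default 100) is reported. Q_ST partitions the same per-round data into
population and genotype-within-population variances and uses medians over
rounds with Q_ST = sigma2_among/(sigma2_among + c·sigma2_within). The
c = 2 default is the outbred convention; it is configurable because F3:4
lines are partially inbred and the appropriate c depends on the assumed
inbreeding coefficient.

## Diversity and kinship

Gene diversity D = 1 − p² − q² and G_ST sum the H components over markers
before forming the ratio. The modified Rogers distance between individuals
uses individual allele "frequencies" {0, 0.5, 1}, missing calls excluded
pairwise with per-pair renormalisation; population-level summaries average
pairwise individual distances. "PCA on a distance matrix" is implemented
as classical scaling (principal coordinates): double-centre −D²/2,
eigendecompose, report eigenvalue shares of the positive spectrum. K_A is
the centred cross-product construction W W'/(2·sum p(1−p)) (VanRaden
method 1); K_D uses the orthogonal dominance codes (−2q², 2pq, −2p²),
linearly interpolated for fractional imputed genotypes. In structured or
inbred material mean(diag K_A) exceeds 1, so the genomic heritability
reported by the prediction module rescales sigma2_u by the training-set
mean diagonal.

## Genome-wide prediction

GBLUP fits an intercept plus one or two kinship-structured random effects
by REML: a single kinship uses an exact eigendecomposition profile
likelihood in the variance ratio; two kinships (M_AD) use dense AI-REML
with EM fallback over both variances. Validation genotypes are predicted
through their genomic relationship with the training set. Non-CV abilities
r_a/r_pop are correlations between observed values and fitted genomic
values on the full data, reproducing the expected r_a > r_a,cv ordering.
Cross-validation is stratified so each fold preserves the population
proportions. The within-population bootstrap draws N genotypes with
replacement (duplicates collapse to weighted records, i.e. residual
variance sigma2/w), validates on the out-of-bag members, and reports
per-size medians. Between-population scenarios resolve their constituent
populations from the crossing scheme (same-pool, opposite-pool one/both,
mixed sharing/not-sharing a parent, and the mirrored scenarios for mixed
validation sets); training sets are subsampled to 50 preserving
constituent proportions via largest-remainder apportionment. Which of the
two opposite-pool populations TS2s uses is an explicit configuration
(default: first in scheme order). Medians aggregate everywhere.

## Expectations

N_e is the harmonic mean over generation sizes (supplied by the user:
plausible effective sizes of a bi-parental breeding funnel are not
recoverable from final population sizes alone), M_e = 2 N_e L, expected
ability r = sqrt(N h²/(N h² + M_e)), and the maximum relative cycle length
of prediction versus phenotypic selection is 100·r/h².

## Numerical choices

Variance floors at 1e−10·var(y) (residual 1e−12·var(y)); constant
responses short-circuit to all-zero variances; kinships are PSD-checked
(minimum eigenvalue ≥ −1e−6) once per matrix; prediction ability requires
≥ 3 finite pairs and returns missing for constant vectors; MRD pairs with
no shared markers are missing; HSI raises a named error when the
across-genotype AEM ratio is within 1e−12 of 1.

## Test and demonstration problem sizes

The test suite analyses the default simulated study (600 genotypes, 5440
markers) for three of the nine traits, uses 50 resampling rounds per point
for the directional checks, 10 simulation seeds for the shared-parent
comparison, and 1000 null simulations for the size of the heat-level test;
the CLI demo configuration is smaller (50 progenies per population, 1088
markers, 3 traits, 25 rounds). These are the package's choices of
demonstration scale; all sizes are parameters.

## Known limitations

No crossover interference, epistasis, or sequence-level read simulation;
no lattice-specific spatial adjustment beyond random blocks; no
Kenward-Roger degrees of freedom; no Bayesian whole-genome regressions;
the genotype-probability emulator is intentionally simple (see above). The
resampled h²_HSI is an approximation whose properties depend on the
pairing scheme; the implementation makes the scheme explicit and seeded so
it can be studied.
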