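# Methods

`radosage` genotypes mixed-ploidy cohorts (diploid, triploid, tetraploid)
from per-sample, per-locus allele read counts, such as those produced by
RAD-seq variant calling. This note describes the statistical models, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Ploidy inference from allelic ratios

At a heterozygous biallelic locus in an individual with `k` haploid
chromosome sets, the expected fraction of reads carrying the focal allele is
one of `p ∈ {1/k, …, (k−1)/k}`: a diploid has a single class at 0.5, a
triploid has classes at 1/3 and 2/3, a tetraploid at 1/4, 1/2 and 3/4.
Observed read fractions are overdispersed relative to the binomial because
extraction, library preparation and amplification bias the per-locus
sampling probability. Each dosage class is therefore modelled as a
beta-binomial with expectation `p` and correlation `ρ` (shape parameters
`α = p(1−ρ)/ρ`, `β = (1−p)(1−ρ)/ρ`); `ρ` is shared across classes within an
individual.

Observations are restricted to apparent heterozygous sites (exactly two
alleles with ≥1 read), total coverage ≥ 30×, and focal-allele ratio within
the closed interval [0.1, 0.9]. The window excludes homozygous loci that
appear heterozygous through sequencing error; the density is renormalized
over the censored support (it sums to 1 over the admissible counts, checked
to 1e−10 in the tests). Boundary membership is tested with a 1e−9 absolute
tolerance on counts because products such as 0.1 × 30 are not exact in
floating point.

The per-individual log-likelihood is
`L = Σ_l log Σ_p m_p · BBc(x_l; n_l, p, ρ)` with mixture weights `m_p`.
For fixed `ρ` this is concave in `m`, so the weights are profiled out by EM
(which then attains the global optimum of the subproblem), and the profile
likelihood is maximized over `ρ` by a 13-point geometric grid on
[5e−4, 0.5] followed by bounded Brent refinement on log ρ (tolerance 1e−5).
This profile–EM scheme replaces a joint softmax/logit multi-start: the
subproblem's concavity makes restarts unnecessary and the 1-D profile is
cheap and monotone to bracket. A 95% confidence interval for `ρ` is read
off the profile likelihood (drop of 1.92 log units).

Candidate ploidies (default {2, 3, 4}) are compared by AIC with
`(|p-grid| − 1) + 1` free parameters per model; ties break toward the lower
ploidy. Samples with fewer than 50 usable ratio observations are reported
`undetermined` rather than classified — very small numbers of variable
sites are known to produce unstable assignments. Because the diploid model
is nested in the tetraploid mixture (weights (0, 1, 0)), the tetraploid
maximum likelihood is never lower; on genuinely diploid data the decision
rests on the 2-parameter AIC penalty. The likelihood-ratio statistic of the
boundary-constrained extra components is O(1) in the number of sites, so a
small fraction of diploids (a few percent) can exceed the penalty by
chance and be called tetraploid no matter how many loci are observed; this
mirrors the occasional misassignment seen with real data and is the
expected behaviour of the criterion, not a defect of the optimizer.

Likelihood evaluations group observations by total count `n` and serve all
log-gamma terms from lookup tables over the integer range [0, max n], so
one evaluation costs a few hundred `gammaln` calls regardless of the number
of loci (~0.3 s per sample at ~1300 sites).

## Dosage genotyping

For a sample of known ploidy `n`, every possible genotype at a locus is a
dosage model: an integer partition of `n` across up to `n` alleles, sorted
descending and zero-padded (diploid: 2:0, 1:1; triploid: 3:0:0, 2:1:0,
1:1:1; tetraploid: 4:0:0:0, 3:1:0:0, 2:2:0:0, 2:1:1:0, 1:1:1:1). Read
counts are sorted descending with their mean phred qualities carried along;
ties break by allele label so results do not depend on input order; more
than `n` observed alleles are truncated to the `n` most frequent.

Each model is scored with a two-part likelihood, computed in natural-log
space via log-gamma:

* `L1` (multinomial, over positions `s` where the model expects reads):
  `(Σ x_s)! / Π x_s! · Π (m_s/n)^{x_s}`;
* `L2` (error, over positions where reads are observed but none are
  expected): `Π p^{x}` with per-read error probability `p = 10^{−q/10}`
  from the averaged phred score (conversion applied to the averaged phred,
  not averaged over per-read probabilities).

The best model minimizes `BIC = k·ln N − 2·log L` with `N` the total read
count at the locus and `k` the number of distinct alleles in the model.
The BIC's sample size and dimension are not dictated by the criterion
itself; this choice penalizes allele-rich models and is deliberately
conservative against overcalling heterozygosity. Remaining ties break
toward fewer distinct alleles, then toward the larger leading dosage. Loci
with fewer than five reads per ploidy level (10 for diploids, 20 for
tetraploids) or more than 200 reads are reported missing; both bounds are
inclusive on the retained side. The tests verify the selected model against
a brute-force oracle that evaluates `L1·L2` and the BIC comparison in exact
big-integer rational arithmetic (possible because phred scores in the
randomized suite are multiples of 10, making `10^{−q/10}` an exact
rational).

At 60× with 0.5% error and ρ = 0.02, tetraploid full-dosage accuracy is
≈92%, with the residual confusion almost entirely between 3:1 and 2:2 —
the two classes whose expected read fractions (0.75 vs 0.5) are nearest;
diploid accuracy at 30× exceeds 99%.

## Filtering cascade

Upstream of the matrix: loci are restricted to single-nucleotide variants
and single-base deletions (symbol `-`); samples with fewer than one million
raw reads are excluded (strict bound). Genotype-level coverage gating
(above) surfaces here only as missing calls. On the genotype matrix the
canonical order is: keep loci present in ≥ 80% of samples (inclusive);
drop samples with > 50% missing data computed on that locus set (strict);
re-apply the presence filter on the reduced sample set; drop loci that
became monomorphic. Each stage emits a `FilterReport`
(in/out/dropped-ids), every filter is idempotent, and dropped + kept =
input at every stage. The re-application of the presence filter after
sample removal is this package's documented choice for an ordering that a
narrative description leaves implicit.

## Population summaries

Genotypes are transformed into within-individual allele frequencies of the
counted allele (copy number / ploidy), so a tetraploid A:3,T:1 is 0.25 and
a diploid A:1,T:1 is 0.5; only biallelic loci are representable, and the
counted allele is the lexicographically second of the locus's observed
alleles. Values are exact machine rationals of the ploidy.

**F_ST.** The default estimator is the Nei-style ratio of averages
`1 − mean(H_S)/mean(H_T')` over loci, where per locus `H_S` is the
group-size-weighted mean of `2p̄_g(1−p̄_g)`, `H_T = 2p̄(1−p̄)` uses the
pooled mean, and `H_T' = H_S + s/(s−1)(H_T − H_S)` applies the Nei–Chesser
correction for the number of sampled populations `s`. Without the
correction the two-deme expectation is `(F/2)/(1−F/2)` — a large downward
bias at small `s`; with it the estimator is consistent for the
Balding–Nichols divergence `F` (recovered within ±0.02 at F = 0.1 in the
tests) while still returning exactly 1 for fixed differences and 0 for
identical frequency profiles. A frequency-based Weir–Cockerham `θ`
(sample-size-corrected, no within-individual heterozygosity term) is
selectable. Per-locus values are `1 − H_S/H_T'` with NaN where `H_T' = 0`;
small negative estimates are reported raw unless clipping is requested.
Outlier flagging marks loci above a configurable quantile (default 99th)
of the per-locus distribution.

**PCA.** Column-centered SVD; explained-variance fractions are singular
values squared over the total; the sign convention makes each component's
largest-magnitude loading positive. A numerically zero centered matrix
(identical rows) returns zero scores and zero explained fractions.
Missing data must be imputed first: per-locus mean, or an EM-PCA style
iterative low-rank scheme (default rank 2) that alternates SVD
reconstruction and re-imputation until the largest change is below 1e−6 or
100 iterations.

**Cline.** Admixture proportions Q (produced externally by a clustering
program; consumed from a table) are arcsine-square-root transformed —
`y = arcsin(√Q)`, the standard variance-stabilizing form — and fit with a
linear mixed model `y ~ latitude` with a population random intercept by
REML (statsmodels MixedLM). The slope p-value is a Wald test against a t
reference with between-population degrees of freedom (populations − 2):
when latitude is shared within populations the slope's information comes
from the population means, and a normal reference is anticonservative
(observed ~12–14% false positives at the 5% level with 20 populations,
versus ~5% with the t reference). Fitted population means
(fixed part at the population's mean latitude plus its random effect) are
exposed. On degenerate data where the mixed model cannot be estimated
(e.g. exactly linear noise-free input) an OLS fallback with zero
population variance is returned and flagged in the `method` field.

**STRUCTURE export.** Every individual occupies exactly four rows; a
tetraploid's four allele copies fill all rows, a triploid rows 1–3, and a
diploid rows 1–2 with rows 3–4 at the missing code −9 — i.e. diploids are
coded as if tetraploid so mixed-ploidy data can be analysed jointly.
Allele codes are 1-based integers in per-locus allele sort order.

## Synthetic data

The generator emulates the statistical structure the models assume: per-
locus population frequencies (uniform on [0.05, 0.95] by default),
Hardy–Weinberg dosage genotypes at the sample's ploidy (multinomial; no
inbreeding parameter), negative-binomial coverage (mean 60, dispersion 5,
truncated to ≥1, mirroring RAD coverage skew), Dirichlet-multinomial read
allocation among genotype alleles (exactly beta-binomial with correlation
ρ = 0.02 at biallelic genotypes), and per-read miscalls at rate 0.005
landing on a uniformly random non-genotype allele, with constant phred
qualities set consistently (q = −10·log10(error rate)). Optional features:
conditioning every genotype on heterozygosity (to realize "N heterozygous
sites per individual" designs), Balding–Nichols group divergence for F_ST
tests, planted tri-/tetra-allelic loci, and a separate latitudinal
admixture-gradient generator that is linear on the arcsine scale.

What it does not emulate — and hence what passing recovery tests do not
show about real data: mapping artefacts and paralog collapse, allele-
specific reference bias, linkage between loci, locus dropout correlated
with genotype (RAD allele dropout), per-locus or per-sample error-rate
variation, and real population structure beyond the island-model
frequencies. Simulation sizes in the tests (e.g. 30 individuals per ploidy
× 2000 heterozygous sites for ploidy recovery; 10 samples × 400 loci for
dosage recovery; 2×50 samples × 2000 loci for F_ST) were chosen to make
the Monte-Carlo error small relative to the thresholds being checked.

## Defaults worth knowing

| Parameter | Default | Why |
| --- | --- | --- |
| ratio min coverage | 30× | stable ratios; matches the diagnostic-histogram convention |
| censoring window | [0.1, 0.9], closed | excludes mistyped homozygotes; closed bounds are the simpler contract |
| min ratio observations | 50 | below this, AIC assignments are unstable |
| candidate ploidies | {2, 3, 4} | higher k allowed; the component grid grows as {1/k…(k−1)/k} |
| genotype coverage | [5·ploidy, 200], inclusive | five reads per haploid copy; 200 guards against collapsed repeats |
| default phred when absent | 30 | typical Illumina base quality |
| BIC (N, k) | total reads, distinct alleles | conservative against overcalling heterozygosity |
| F_ST estimator | Nei with s/(s−1) correction | consistent for Balding–Nichols F at few demes |
| imputation | per-locus mean (rank-2 EM-PCA optional) | deterministic, adequate for PCA preparation |

## Known limitations

* Ploidy inference assumes a single genome-wide ploidy; chromosome-level
  mosaicism is out of scope.
* The genotyper has no population-frequency prior; every dosage model is
  scored flat, per individual.
* The cline slope's t-based Wald p-value is still approximate (no
  Satterthwaite/Kenward–Roger adjustment); treat borderline significance
  with care.
* A diploid sample is occasionally (a few percent) assigned tetraploid by
  AIC even with abundant data (see above); inspect the ratio histogram and
  ΔAIC before acting on single-sample calls.
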