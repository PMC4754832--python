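# Methods

This note documents the models implemented in `prsgxe`, the assumptions
behind the synthetic-cohort generator, the numerical choices, and what a
green test suite does and does not establish.

## Study design being modelled

A retrospective case–control study of recurrent major depression with
two environmental exposures: adult stressful life events (SLEs; 12 binary
items, 7 classed as dependent on the respondent's behaviour and 5 as
independent, summed to a 0–12 count) and childhood trauma (CT; 25
Likert items scored 1–5, total 25–125, optionally categorized
none / mild / moderate-severe). Polygenic risk scores come from an
external discovery GWAS; the questions are (a) whether PRS, SLEs and CT
predict case status, (b) whether PRS and environment interact on the
multiplicative (odds-ratio) or additive (risk-difference) scale, and
(c) whether genetic liability correlates with exposure itself (rGE).

## Synthetic cohort generator

The generator (`prsgxe.simulate`) produces every input the analysis
consumes. It is a stated world, not a fit to any dataset.

**Genotypes.** SNPs come in contiguous blocks. One minor-allele
frequency per block is drawn uniformly from `maf_range` (default
0.05–0.5). Within a block, haplotypes follow a latent Gaussian AR(1)
process thresholded at the MAF quantile. Dichotomizing a Gaussian
attenuates correlation, so the latent correlation is solved numerically
(bivariate-normal tetrachoric inversion) such that the *dosage*
correlation of adjacent SNPs equals `within_block_r` (default 0.8,
giving adjacent r² ≈ 0.64 and decaying geometrically with distance in
the block). Blocks are independent, spaced > 300 kb apart with 10 kb
between SNPs, cycling over chromosomes 1–22, so the default clumping
window can never span two blocks. Frequencies are per-block rather than
per-SNP because a dosage correlation of 0.8 is unattainable between SNPs
of very different frequency, and SNPs in near-complete LD share
frequencies in real panels.

**Genetic architecture.** `n_causal` SNPs (default n_snps/20) spread
evenly across the panel receive N(0,1) per-allele effects rescaled so the
genetic score variance is `h2_liability` (default 0.2) on a unit-variance
liability scale. The discovery study's true per-SNP effects are the
LD-convolved marginals Cov(g_j, S)/Var(g_j), so tagged SNPs carry partial
signal — this is what makes clumping and thresholding non-trivial.
Estimated discovery effects add noise with
se² = 1/(2·f(1−f)·n_eff), n_eff = 4/(1/n_cases + 1/n_controls)
(n_eff = n at a balanced split; default 7615/7931, n = 15 546), with
two-sided Wald p-values. The validation phenotype's genetic effect is
parameterized separately as `or_g` per SD of the true score, which is
invariant to the liability scaling; `h2_liability` therefore controls
only the discovery signal-to-noise ratio.

**Environment.** SLE items are Bernoulli with a logit-linear model:
intercept −1.9 (spread ±0.6 across items, mean count ≈ 2), age slope
−0.02/year (younger people report more events), +0.3 for females, and a
shared within-person latent with weight 0.8 that makes items positively
dependent. CT items discretize a latent severity into 1–5 with
right-skewed cut-points (most respondents answer 1). Gene–environment
correlation, when requested, enters actively: the latent environment
liability is rge·Z_G + √(1−rge²)·noise, optionally restricted to the
seven behaviour-dependent SLE items.

**Phenotype.** P(case) = logistic(b₀ + log(or_g)·Z_G + log(or_e)·E +
log(or_gxe)·Z_G·E) in a source population 20× the requested cohort;
exactly `n_cases` cases and `n_controls` controls are then sampled
without replacement (quota failure raises with achieved counts). The
shipped default generates disease from the binary 2-or-more-SLEs
exposure at `or_e` = 1.82 while the analysis consumes the quantitative
adjusted count — deliberately mirroring the mismatch between how such
effects are published (binary exposure ORs) and analysed (counts).
b₀ defaults to logit(0.15), a mid-range lifetime prevalence for major
depression; scans over logit(0.08)–logit(0.27) moved downstream power
estimates by < 0.04, so the choice is not load-bearing. Controls are
screened (BDI < 10); case BDI is Normal(18, 9) clipped to 0–63 so a
realistic fraction falls in the severe band used by the sensitivity
analysis. CT items are retained for a random subsample (default 240
cases, 272 controls) and missing elsewhere.

**What the generator does not emulate:** realistic human LD maps or
recombination, imputation uncertainty, X chromosome, relatedness,
genotyping batch effects, instrument measurement error beyond item-level
Bernoulli/ordinal noise, or ascertainment other than simple case/control
quota sampling. A green test establishes internal statistical
correctness of the pipeline under this world, not agreement with any
particular clinical dataset.

## Clumping and scoring

Greedy p-value-informed clumping follows PLINK semantics: SNPs with
p < p1 are visited in ascending p (ties broken by chromosome, position,
id); each surviving visitee becomes an index and removes unassigned SNPs
with p < p2 within the window (|Δbp| ≤ window_kb·1000, same chromosome)
with dosage r² > r2_max. SNPs with p2 ≤ p < p1 can be indexed but never
removed; SNPs with p ≥ p1 are never indexed and never removable, so the
scoring set is "everything not removed". SNPs absent from the LD panel
pass through clumping untouched and are dropped (with a logged count) at
allele alignment. Monomorphic SNPs have r² defined as 0 — they cannot
evidence LD — with a warning. r² is the squared Pearson correlation of
dosages over pairwise-complete samples.

Allele harmonization distinguishes matched, flipped (weight negated),
strand-flipped (complement, either orientation) and dropped
(A/T and C/G ambiguous; otherwise mismatched) SNPs; duplicate ids are an
error naming the ids. Raw scores are weighted sums (not averages) —
standardization makes the distinction immaterial downstream — with
missing dosages imputed as 2× the panel's empirical allele frequency.
Standardized scores (mean 0, SD 1, sample SD, cases and controls jointly)
are used throughout the models; the raw columns are also written.

## Covariates and environment preparation

Principal components are the top-k left singular vectors of the per-SNP
centred, variance-standardized, mean-imputed dosage matrix, computed via
an eigendecomposition of the smaller Gram matrix (deterministic, no
iterative solver), unit norm, sign fixed so each component's
largest-magnitude SNP loading is positive. k > rank raises.

Genomic control λ = median(χ²)/0.45494 (the χ²₁ null median), accepting
either χ² statistics or p-values. Note λ estimated from m SNPs has
Monte-Carlo noise ≈ 1.4/√m, which matters when judging bands like
0.95–1.05.

Missing ages are replaced by the sex-specific mean within the same
case/control group. SLE counts in cases are adjusted using coefficients
estimated in controls only (controls proxy the general population):
adjusted = observed − β̂_age(age − mean control age) − β̂_sex(sex −
control proportion female), with total, dependent and independent counts
adjusted by their own fits and controls left untouched. Sex is coded
male = 0, female = 1. CT totals prorate missing items by the person mean
(missing if > 10% of items are absent) and clamp to [25, 125]; the
none/mild/moderate-severe cut-points default to (≤30, ≤40, >40) — the
instrument's published cut-points are defined on subscales we do not
simulate, so these are explicit configuration placeholders, and all
interaction analyses use the quantitative total.

## Models and inference

The logistic fitter is IRLS with internal unit-SD column scaling,
step-halving to guarantee likelihood ascent, convergence at gradient
max-norm < 1e-8, and observed-information standard errors. Rank
deficiency and separation raise errors naming the offending column
(separation flagged when a scaled coefficient passes |β| > 30). The
fitter matches `statsmodels.Logit` to 1e-6 in the unit tests; it exists
in-package because permutation inference and the replicate studies need
thousands of cheap warm-started fits.

Nagelkerke pseudo-R² = [1 − exp(2(ℓ₀ − ℓ₁)/n)] / [1 − exp(2ℓ₀/n)].
Variance attributed to a term is R²(full) − R²(without the term), both
against the intercept-only null, so the PCs' contribution cancels.

The interaction design is [1, PRS, E, PCs, PC×E, PC×PRS, PRS×E]; the
PC-by-main-effect products prevent ancestry from masquerading as
interaction. The additive model applies least squares to the same design
with the 0/1 outcome and reports the multiple-R² increment. rGE is the
least-squares regression of the environment on PRS + PCs within a subset
(constant environment raises).

Permutation empirical p-values permute the response only (case/control
labels for disease models, the environment for rGE), keeping the
covariate rows intact — this preserves the joint (PRS, E, PC)
distribution while breaking all associations with the response;
p = (1 + #{|stat_perm| ≥ |stat_obs|})/(B_ok + 1). Refits that fail
(e.g. separation under permutation) are discarded; more than 5% failures
raises. Residual-permutation schemes are possible but not implemented.

The Bonferroni threshold is α/m with m defaulting to 10 planned tests
(0.05/10 = 0.005). The sensitivity analysis re-runs any analysis keeping
all controls and only cases with interview BDI below a configurable
threshold (default 29, the conventional severe band).

## Power simulation

Each replicate draws G ~ N(0,1) and a binary (or integer-valued)
exposure, assigns case status from the logistic model, samples to quota,
fits the two-variable multiplicative model (no PCs — no stratification
is simulated), and records two-sided Wald rejection at α. Power is the
rejection fraction with binomial Monte-Carlo SE. Exposure prevalences
default to 0.45 (2+ SLEs) and 0.30 (moderate/severe CT), chosen as
plausible cohort marginals since the original calculations do not print
them.

Running the two published design points at 1000 replicates, the SLE
scenario (1605/1064, interaction OR 1.28) clears 80% power (~84–86%
across seeds), but the CT scenario (240/272, interaction OR 1.76,
prevalence 0.30) computes to ~77–79% — just under the published >80%
claim — and stays below 80% for any exposure prevalence outside roughly
0.35–0.45 and any baseline prevalence between 8% and 27%. The original
calculation came from a closed-form program whose exact parameterization
(population risk, exposure prevalence, G×E sampling model) is not
recoverable; the simulation here is the package's own definition of
power for this design, and its result is reported as computed rather
than adjusted to match. The corresponding acceptance test is
intentionally left failing.

## Numerical and reproducibility choices

- All randomness flows from `numpy.random.default_rng` seeds; a
  pipeline's global seed derives per-stage seeds via `SeedSequence`, and
  identical configs give byte-identical output tables.
- Tables are TSV with `#` metadata headers (config hash, seed), `NA` for
  missing, and floats printed as `%.17g` so reloading a persisted stage
  reproduces downstream outputs exactly (pandas readers use
  `float_precision="round_trip"` for the same reason).
- Ties in clumping are broken by (p, chromosome, position, id); PC signs
  by largest-loading-positive; both purely for determinism.
- Degenerate inputs have defined behaviour rather than NaNs: empty SNP
  sets score zero with a warning, zero-variance SNPs have r² = 0 with a
  warning, zero-SNP thresholds yield flagged zero columns, monomorphic
  discovery SNPs are emitted with missing estimates and excluded
  downstream.

## Known limitations

- At small samples (n ≈ 500) the logistic interaction MLE shows the
  usual O(1/n) away-from-null bias (~+2% of a log-OR of 0.57 in the CT
  subset design); no Firth-type correction is applied.
- The additive-interaction test is a linear-probability model, kept for
  comparability with common practice; it ignores heteroscedasticity, and
  no RERI-style additive summaries are provided.
- PCs are computed on the analysis panel itself; no projection onto an
  external reference is available.
- The CT category cut-points are placeholders (see above); category
  output is intended for figure stratification, not inference.
- LD is block-diagonal AR(1); clumping behaviour on long-range or
  overlapping real LD is untested by construction.
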