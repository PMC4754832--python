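# prsgxe

Polygenic-score × environment interaction analysis for case–control
psychiatric cohorts, built as a tested, reusable pipeline. It covers the
full path from discovery GWAS summary statistics and validation-cohort
genotypes to interaction inference: LD clumping, p-value-thresholded
polygenic risk scores (PRS), ancestry principal components and
genomic-control diagnostics, environment preparation (stressful life
events and childhood trauma questionnaires), multiplicative and additive
gene–environment (G×E) interaction models with permutation-based
empirical p-values, gene–environment correlation, and simulation-based
power analysis. A synthetic-cohort generator with controllable genetic
architecture, LD structure, environment structure and G×E effects stands
in for clinical data, so every stage is testable end to end.

Intended users: statistical geneticists and psychiatric-genetics analysts
who want a transparent, scriptable reference implementation of the
classic clump + threshold PRS–G×E workflow, or a simulation bench for
designing such studies.

## The statistics in brief

**PRS.** Discovery summary statistics are pruned by p-value-informed
greedy clumping against the validation panel's LD (defaults `p1=0.5`,
`p2=0.1`, `r² > 0.25`, 300 kb window — PLINK `--clump` semantics), then
thresholded at nine increasingly liberal cutoffs
p_T ∈ {1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5}. For each
individual *i* and threshold,

```
PRS_i = Σ_j  log(OR_j) · g_ij ,      j : clumped SNPs with p_j < p_T,
```

with effect alleles harmonized to the panel (flips, strand flips;
A/T–C/G SNPs dropped), missing dosages mean-imputed as 2·freq(A1), and
scores standardized to mean 0, SD 1 over the analysis sample.

**Interaction models.** With k ancestry PCs (default 2), case status y is
modelled as

- multiplicative (logistic):
  `logit P(y=1) = β0 + βG·PRS + βE·E + Σ PCs + Σ PC×E + Σ PC×PRS + βGE·PRS×E`
- additive (linear probability): the same design fit by least squares.

The PRS×E term is reported as an odds ratio with 95% Wald CI, an
asymptotic p, a permutation empirical p (case/control labels permuted,
covariate rows intact), and the variance it explains: Nagelkerke
pseudo-R² relative to the model without the term (PC contributions
excluded by construction), or the multiple-R² increment for the additive
model. Ten planned tests give a Bonferroni threshold of 0.05/10 = 0.005.
Gene–environment correlation is the linear regression of the environment
on PRS and PCs within a subset (cases by default).

**Power.** Power for detecting an interaction OR in a case–control design
is estimated by direct simulation: draw G ~ N(0,1) and a binary exposure,
assign case status from the logistic model, sample cases and controls to
quota, fit the two-variable interaction model, and count Wald rejections
at α.

## Worked example

Run the shipped default study world — 1605 cases, 1064 controls, 1200
SNPs in 120 LD blocks, discovery noise matched to a 15 546-subject
meta-analysis, disease generated with OR 1.22 per SD of true score and
OR 1.82 for the 2+-life-events exposure, childhood-trauma items observed
on a 240/272 subset:

```
prsgxe run --seed 1 --out results/demo
```

(about 20 s; equivalently `run_pipeline({"seed": 1}, out_dir=...)` from
Python). The run report prints per-stage counts:

```
simulate: {'n_samples': 2669, 'n_snps': 1200}
clump:    {'n_index': 476, 'n_retained': 821}
score:    {'thresholds': 9, 'snps_at_max': 476}
prepare:  {'n_pcs': 2, 'n_ct_observed': 512}
gxe:      {'n_results': 65, 'n_results_sensitivity': 65}
```

1200 discovery SNPs collapse to 476 clump indices; SNP counts per score
grow from 48 at p_T < 1e-4 to 476 at p_T < 0.5. `gxe_results.tsv` holds
one row per model × environment × threshold (9 thresholds × 7
model–environment combinations plus 2 single-row environment main
effects = 65). Two illustrative rows from seed 1:

| model | environment | p_T | OR | ΔR² | p | empirical p |
|---|---|---|---|---|---|---|
| main_prs | — | 0.5 | 1.11 | 0.0036 | 0.0075 | 0.01 |
| multiplicative | sle_total_adj | 0.5 | 0.99 | 0.0002 | 0.49 | 0.44 |

The estimated PRS predicts case status (OR 1.11 per SD — attenuated from
the generative 1.22 because the weights are noisy discovery estimates,
exactly as in real data), and the interaction test is null, matching the
generative world (`or_gxe` defaults to 1). Adding a power block to the
config, the SLE-design scenario (interaction OR 1.28 at α = 0.05) gives

```
n_cases  n_controls  or_gxe  power   mc_se
   1605        1064    1.28  0.832  0.017
```

`gxe_results_sensitivity.tsv` repeats the grid excluding cases severely
depressed at interview (BDI ≥ 29), and
`fig3_logodds_by_ct_category.tsv` holds predicted log-odds over the
standardized PRS per childhood-trauma category for plotting.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the two study-design power claims from scratch — the
multiplicative interaction Wald test at α = 0.05 for (1605/1064 cases/
controls, OR_G 1.22, OR_E 1.82, OR_GxE 1.28, exposure prevalence 0.45)
and for (240/272, OR_G 1.22, OR_E 2.27, OR_GxE 1.76, prevalence 0.30) —
each by 1000 fresh simulation replicates, and writes the rejection
percentages as JSON. See `docs/methods.md` for the model details,
parameter choices and known limitations.
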