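"""Synthetic case-control cohort generator.

Emulates the four inputs of a polygenic-score x environment study of major
depressive disorder so that every downstream stage (clumping, scoring,
covariate preparation, interaction modelling) is testable without access to
clinical data:

* LD-blocked genotype dosages for a validation cohort,
* noisy discovery GWAS summary statistics (odds ratios and p-values),
* environment measures — 12 binary stressful-life-event (SLE) items with a
  7-dependent / 5-independent partition, and 25 Likert childhood-trauma
  (CTQ) items,
* retrospectively sampled case-control phenotypes from a logistic disease
  model with configurable genetic, environmental and interaction odds
  ratios and optional gene-environment correlation.

The LD model is a latent multivariate Gaussian with AR(1) within-block
correlation, thresholded to per-haplotype alleles at the block's minor
allele frequency.  The latent correlation is solved numerically (tetrachoric
inversion) so that the *dosage* correlation of adjacent SNPs matches
``within_block_r`` despite the attenuation introduced by dichotomization.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import multivariate_normal, norm

__all__ = [
    "SimulationConfig",
    "GenotypePanel",
    "Cohort",
    "simulate_genotypes",
    "simulate_stratified_panel",
    "simulate_discovery_sumstats",
    "simulate_environment",
    "simulate_phenotype",
    "simulate_cohort",
    "draw_causal_effects",
    "true_marginal_log_or",
    "N_SLE_ITEMS",
    "N_SLE_DEPENDENT",
    "N_CTQ_ITEMS",
]

N_SLE_ITEMS = 12
N_SLE_DEPENDENT = 7  # items 1..7 dependent on own behaviour, 8..12 independent
N_CTQ_ITEMS = 25

_NONAMBIGUOUS_PAIRS = (
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the simulated study world.

    Defaults reproduce the published study design: 1605 cases and 1064
    controls in the validation cohort, a discovery meta-analysis of 15 546
    subjects (7615 cases, 7931 controls), a genetic main effect of OR 1.22
    per SD of the true score and an environmental main effect of OR 1.82
    for the binary 2-or-more-SLEs exposure.  ``or_gxe`` defaults to the
    null; interaction worlds set it explicitly (1.28 for SLEs, 1.76 for
    childhood trauma at OR_E 2.27 in the 240/272 subset).
    """

    n_cases: int = 1605
    n_controls: int = 1064
    n_snps: int = 1200
    n_blocks: int = 120
    within_block_r: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal: int | None = None  # default: n_snps // 20 (min 1)
    h2_liability: float = 0.2
    n_discovery: int = 15546
    discovery_case_fraction: float = 7615 / 15546
    or_g: float = 1.22
    or_e: float = 1.82
    or_gxe: float = 1.0
    rge: float = 0.0
    rge_dependent_only: bool = False
    baseline_logodds: float = -1.7346  # population prevalence ~0.15
    population_multiplier: int = 20
    n_ct_cases: int = 240
    n_ct_controls: int = 272
    # SLE item model: logit(p_item) = intercept + age_slope*(age-45) + sex_effect*female + 0.8*latent
    sle_age_slope: float = -0.02
    sle_sex_effect: float = 0.3
    sle_item_intercept: float = -1.9
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_snps, self.n_blocks) < 1:
            raise ValueError("n_cases, n_controls, n_snps, n_blocks must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range endpoints must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        for name in ("or_g", "or_e", "or_gxe"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (-1 <= self.rge <= 1):
            raise ValueError("rge must lie in [-1, 1]")
        if self.n_discovery < 1:
            raise ValueError("n_discovery must be >= 1")
        if not (0 < self.discovery_case_fraction < 1):
            raise ValueError("discovery_case_fraction must lie in (0, 1)")
        if self.n_causal is None:
            object.__setattr__(self, "n_causal", max(1, self.n_snps // 20))
        if not (0 <= self.n_causal <= self.n_snps):
            raise ValueError("n_causal must lie in [0, n_snps]")
        if not (0 < self.h2_liability < 1):
            raise ValueError("h2_liability must lie in (0, 1)")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class GenotypePanel:
    """Sample x SNP dosage matrix with per-SNP metadata.

    ``dosages`` holds A1 allele counts as float32 in [0, 2]; missing values
    are NaN.  ``snp_meta`` columns: snp, chrom, bp, a1, a2, freq (configured
    A1 frequency).
    """

    sample_ids: np.ndarray
    snp_meta: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        if len(self.snp_meta) != self.dosages.shape[1]:
            raise ValueError("snp_meta length must equal dosage column count")
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise ValueError("sample_ids length must equal dosage row count")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.dosages < 0) | (self.dosages > 2))
        if bad:
            raise ValueError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        idx = self.snp_meta.index[self.snp_meta["snp"] == snp_id]
        if len(idx) == 0:
            raise KeyError(f"SNP {snp_id!r} not in panel")
        return int(idx[0])

    def empirical_freq(self) -> np.ndarray:
        """Empirical A1 frequency per SNP over non-missing dosages."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_samples(self, rows: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            sample_ids=self.sample_ids[rows],
            snp_meta=self.snp_meta.copy(),
            dosages=self.dosages[rows],
        )


def _latent_rho_for_phi(target_phi: float, maf: float) -> float:
    """Latent Gaussian correlation whose thresholded indicators (equal
    thresholds at quantile ``maf``) have phi coefficient ``target_phi``."""
    if target_phi <= 0:
        return 0.0
    t = norm.ppf(maf)
    pq = maf * (1.0 - maf)

    def phi_of(rho: float) -> float:
        p11 = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]).cdf([t, t])
        return (p11 - maf * maf) / pq

    return brentq(lambda r: phi_of(r) - target_phi, 0.0, 0.999999, xtol=1e-10)


def _block_sizes(n_snps: int, n_blocks: int) -> list[int]:
    base = n_snps // n_blocks
    if base == 0:
        # fewer SNPs than blocks: one SNP per block until exhausted
        return [1] * n_snps
    sizes = [base] * n_blocks
    rem = n_snps - base * n_blocks
    if rem:
        sizes[-1] += rem  # last block absorbs the remainder
    return sizes


def simulate_genotypes(
    config: SimulationConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> GenotypePanel:
    """Simulate LD-blocked genotype dosages.

    SNPs are arranged in contiguous blocks.  One MAF per block is drawn
    uniformly from ``maf_range``; within a block, haplotypes follow an AR(1)
    latent Gaussian whose correlation is chosen so adjacent-SNP *dosage*
    correlation is approximately ``within_block_r``.  Blocks are
    independent.  Positions are spaced 10 kb within a block (span < 300 kb
    for blocks of up to 30 SNPs) and blocks are separated by > 300 kb;
    blocks cycle over chromosomes 1-22.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_samples is None:
        n_samples = config.population_multiplier * (config.n_cases + config.n_controls)

    sizes = _block_sizes(config.n_snps, config.n_blocks)
    lo, hi = config.maf_range
    n_snps = sum(sizes)

    dosages = np.empty((n_samples, n_snps), dtype=np.float32)
    snp, chrom, bp, a1, a2, freq = [], [], [], [], [], []

    rho_cache: dict[float, float] = {}
    col = 0
    chrom_pos = {c: 0 for c in range(1, 23)}
    for b, m in enumerate(sizes):
        maf = float(rng.uniform(lo, hi))
        key = round(maf, 6)
        if key not in rho_cache:
            rho_cache[key] = _latent_rho_for_phi(config.within_block_r, maf)
        rho = rho_cache[key]
        thr = norm.ppf(maf)

        z = np.empty((2 * n_samples, m))
        z[:, 0] = rng.standard_normal(2 * n_samples)
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, m):
            z[:, j] = rho * z[:, j - 1] + scale * rng.standard_normal(2 * n_samples)
        h = z < thr
        dosages[:, col:col + m] = (
            h[:n_samples].astype(np.float32) + h[n_samples:].astype(np.float32)
        )

        c = (b % 22) + 1
        start = chrom_pos[c] + 400_000  # > 300 kb inter-block gap
        for j in range(m):
            snp.append(f"rs{b:04d}_{j:03d}")
            chrom.append(c)
            bp.append(start + j * 10_000)
            pair = _NONAMBIGUOUS_PAIRS[rng.integers(len(_NONAMBIGUOUS_PAIRS))]
            a1.append(pair[0])
            a2.append(pair[1])
            freq.append(maf)
        chrom_pos[c] = start + (m - 1) * 10_000
        col += m

    meta = pd.DataFrame(
        {"snp": snp, "chrom": chrom, "bp": bp, "a1": a1, "a2": a2, "freq": freq}
    )
    sample_ids = np.array([f"S{i:06d}" for i in range(n_samples)])
    return GenotypePanel(sample_ids=sample_ids, snp_meta=meta, dosages=dosages)


def simulate_stratified_panel(
    n_samples: int,
    n_snps: int,
    fst: float,
    maf_range: tuple[float, float] = (0.1, 0.5),
    rng: np.random.Generator | None = None,
) -> tuple[GenotypePanel, np.ndarray]:
    """Two-subpopulation panel with Balding-Nichols frequency divergence.

    Returns the panel and the 0/1 subpopulation labels (first half / second
    half).  Used to exercise principal-component and genomic-control
    behaviour under stratification; SNPs are unlinked.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if not (0 < fst < 1):
        raise ValueError("fst must lie in (0, 1)")
    anc = rng.uniform(*maf_range, n_snps)
    a = anc * (1 - fst) / fst
    b = (1 - anc) * (1 - fst) / fst
    f1 = np.clip(rng.beta(a, b), 0.01, 0.99)
    f2 = np.clip(rng.beta(a, b), 0.01, 0.99)
    labels = np.zeros(n_samples, dtype=int)
    labels[n_samples // 2:] = 1
    f = np.where(labels[:, None] == 0, f1[None, :], f2[None, :])
    dosages = rng.binomial(2, f).astype(np.float32)
    meta = pd.DataFrame(
        {
            "snp": [f"strat{j:05d}" for j in range(n_snps)],
            "chrom": np.repeat(np.arange(1, 23), int(np.ceil(n_snps / 22)))[:n_snps],
            "bp": np.tile(np.arange(n_snps) * 500_000 + 1, 1)[:n_snps],
            "a1": "A",
            "a2": "G",
            "freq": anc,
        }
    )
    ids = np.array([f"P{i:06d}" for i in range(n_samples)])
    return GenotypePanel(sample_ids=ids, snp_meta=meta, dosages=dosages), labels


def draw_causal_effects(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Direct per-allele liability effects for ``n_causal`` SNPs.

    Causal SNPs are spread evenly across the panel; effects are N(0,1)
    draws rescaled so the genetic score variance (independence
    approximation, Var = sum d^2 * 2 f (1-f) at the mid-range MAF) equals
    ``h2_liability`` on a unit-variance liability scale.
    """
    d = np.zeros(config.n_snps)
    if config.n_causal == 0:
        return d
    idx = np.linspace(0, config.n_snps - 1, config.n_causal).astype(int)
    raw = rng.standard_normal(config.n_causal)
    f_mid = float(np.mean(config.maf_range))
    var_per_unit = float(np.sum(raw**2) * 2 * f_mid * (1 - f_mid))
    d[idx] = raw * np.sqrt(config.h2_liability / var_per_unit)
    return d


def true_marginal_log_or(
    panel: GenotypePanel, direct_effects: np.ndarray, max_rows: int = 5000
) -> np.ndarray:
    """LD-convolved marginal per-allele effects: Cov(g_j, S) / Var(g_j)
    with S the direct-effect score, estimated on up to ``max_rows`` panel
    rows.  These are the 'true' discovery log odds ratios."""
    X = np.asarray(panel.dosages[:max_rows], dtype=np.float64)
    X = np.where(np.isnan(X), np.nanmean(X, axis=0, keepdims=True), X)
    Xc = X - X.mean(axis=0)
    s = Xc @ direct_effects
    var = np.einsum("ij,ij->j", Xc, Xc)
    var[var == 0] = np.nan
    return (Xc.T @ s) / var


def simulate_discovery_sumstats(
    snp_meta: pd.DataFrame,
    true_log_or: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Noisy discovery summary statistics.

    Estimated log-OR ~ Normal(true log-OR, se^2) with
    se^2 = 1 / (2 maf (1-maf) n_eff) and
    n_eff = 4 / (1/n_case + 1/n_ctrl) for the discovery case/control split
    (n_eff = n_discovery when balanced).  P-values are two-sided Wald.
    Monomorphic SNPs (maf 0 or 1) are emitted with missing estimates.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    maf = snp_meta["freq"].to_numpy(dtype=float)
    fcase = config.discovery_case_fraction
    n_eff = 4.0 * fcase * (1.0 - fcase) * config.n_discovery
    with np.errstate(divide="ignore", invalid="ignore"):
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)
    mono = (maf <= 0) | (maf >= 1) | ~np.isfinite(se)
    est = np.asarray(true_log_or, dtype=float) + rng.standard_normal(len(maf)) * np.where(mono, 0.0, se)
    est[mono] = np.nan
    with np.errstate(invalid="ignore"):
        z = np.abs(est) / se
    p = 2.0 * norm.sf(z)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    p[mono] = np.nan
    out = snp_meta[["snp", "chrom", "bp", "a1", "a2"]].copy()
    out["or"] = np.exp(est)
    # derive from the OR so in-memory weights match a daner-file reload bit
    # for bit (log(exp(x)) can differ from x by one ulp)
    out["log_or"] = np.log(out["or"])
    out["p"] = p
    out["se"] = se
    return out


def simulate_environment(
    config: SimulationConfig,
    age: np.ndarray,
    sex: np.ndarray,
    rng: np.random.Generator,
    z_g: np.ndarray | None = None,
) -> pd.DataFrame:
    """Simulate SLE items and CTQ items for each individual.

    SLE items are Bernoulli with a logit-linear dependence on age (negative
    slope: younger individuals report more events) and sex (females report
    more), plus a shared within-person latent; CTQ items discretize a
    latent severity into 1..5 Likert scores.  When ``config.rge`` is
    non-zero and ``z_g`` is given, the latent environment liability is
    rge * z_g + sqrt(1-rge^2) * noise (active gene-environment
    correlation); with ``rge_dependent_only`` the genetic component enters
    only the 7 behaviour-dependent SLE items.
    """
    n = len(age)
    sexn = np.asarray(sex, dtype=float)  # 0=male, 1=female
    rge = config.rge
    if z_g is None or rge == 0.0:
        u_dep = rng.standard_normal(n)
        u_indep = u_dep
        u_ct = rng.standard_normal(n)
    else:
        w = np.sqrt(1.0 - rge * rge)
        u_dep = rge * z_g + w * rng.standard_normal(n)
        u_indep = u_dep if not config.rge_dependent_only else rng.standard_normal(n)
        u_ct = rng.standard_normal(n) if config.rge_dependent_only else rge * z_g + w * rng.standard_normal(n)

    item_shift = np.linspace(-0.6, 0.6, N_SLE_ITEMS)
    base = (
        config.sle_item_intercept
        + config.sle_age_slope * (age - 45.0)
        + config.sle_sex_effect * sexn
    )
    sle = np.empty((n, N_SLE_ITEMS), dtype=np.int8)
    for j in range(N_SLE_ITEMS):
        u = u_dep if j < N_SLE_DEPENDENT else u_indep
        logit = base + item_shift[j] + 0.8 * u
        pj = 1.0 / (1.0 + np.exp(-logit))
        sle[:, j] = rng.random(n) < pj

    # CTQ: latent severity -> 25 items, right-skewed (most responses 1)
    cuts = np.array([0.5, 1.3, 2.0, 2.6])
    noise = rng.standard_normal((n, N_CTQ_ITEMS)) * 0.8
    lat = u_ct[:, None] + noise
    ctq = (lat[:, :, None] > cuts[None, None, :]).sum(axis=2).astype(np.int8) + 1

    env = pd.DataFrame(
        {f"sle_item_{j + 1}": sle[:, j] for j in range(N_SLE_ITEMS)}
    )
    env["sle_total"] = sle.sum(axis=1)
    env["sle_dependent"] = sle[:, :N_SLE_DEPENDENT].sum(axis=1)
    env["sle_independent"] = sle[:, N_SLE_DEPENDENT:].sum(axis=1)
    for j in range(N_CTQ_ITEMS):
        env[f"ctq_item_{j + 1}"] = ctq[:, j]
    env["ctq_total"] = ctq.sum(axis=1, dtype=int)
    return env


def _true_score(panel: GenotypePanel, direct_effects: np.ndarray) -> np.ndarray:
    # chunked matvec: avoids a float64 copy of a large population matrix
    X = panel.dosages
    n = X.shape[0]
    col_mean = None
    s = np.empty(n, dtype=np.float64)
    for i in range(0, n, 8192):
        chunk = np.asarray(X[i:i + 8192], dtype=np.float64)
        if np.isnan(chunk).any():
            if col_mean is None:
                with np.errstate(invalid="ignore"):
                    col_mean = np.nanmean(X, axis=0, dtype=np.float64)
            nan = np.isnan(chunk)
            chunk[nan] = np.broadcast_to(col_mean, chunk.shape)[nan]
        s[i:i + 8192] = chunk @ direct_effects
    sd = s.std()
    if sd == 0:
        return np.zeros_like(s)
    return (s - s.mean()) / sd


def simulate_phenotype(
    panel: GenotypePanel,
    env_exposure: np.ndarray,
    direct_effects: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Case-control status from the logistic disease model, sampled to quota.

    P(case) = logistic(baseline + log(or_g) Z_G + log(or_e) E
    + log(or_gxe) Z_G E) with Z_G the standardized true score.  Cases and
    controls are sampled retrospectively (without replacement) from the
    source panel to exactly ``n_cases`` / ``n_controls``; raises if the
    panel cannot fill a quota, reporting achieved counts.

    Returns (phenotype frame indexed like the selected rows, selected row
    indices into ``panel``).
    """
    z = _true_score(panel, direct_effects)
    e = np.asarray(env_exposure, dtype=float)
    eta = (
        config.baseline_logodds
        + np.log(config.or_g) * z
        + np.log(config.or_e) * e
        + np.log(config.or_gxe) * z * e
    )
    p = 1.0 / (1.0 + np.exp(-eta))
    is_case = rng.random(len(p)) < p

    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise RuntimeError(
            "case/control quota unreachable: achieved "
            f"{len(case_idx)} cases (need {config.n_cases}), "
            f"{len(ctrl_idx)} controls (need {config.n_controls}); "
            "raise population_multiplier or baseline_logodds"
        )
    sel = np.concatenate(
        [
            rng.choice(case_idx, config.n_cases, replace=False),
            rng.choice(ctrl_idx, config.n_controls, replace=False),
        ]
    )
    pheno = pd.DataFrame(
        {
            "sample_id": panel.sample_ids[sel],
            "case": np.concatenate(
                [np.ones(config.n_cases, dtype=int), np.zeros(config.n_controls, dtype=int)]
            ),
            "z_g_true": z[sel],
        }
    )
    return pheno, sel


@dataclass
class Cohort:
    """One fully simulated study: validation panel plus all tables."""

    config: SimulationConfig
    panel: GenotypePanel
    sumstats: pd.DataFrame
    phenotypes: pd.DataFrame  # sample_id, case, age, sex, bdi, z_g_true
    environment: pd.DataFrame  # SLE/CTQ items and totals (CTQ NaN outside subset)
    direct_effects: np.ndarray = field(repr=False)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Run the full generative pipeline for one study world.

    Simulates a source population ``population_multiplier`` times the
    requested cohort, draws covariates and environments, generates disease
    from the binary 2+-SLEs exposure, samples cases and controls to quota,
    and builds discovery summary statistics from LD-convolved true effects.
    CTQ items are kept for a random subset of ``n_ct_cases`` cases and
    ``n_ct_controls`` controls (missing elsewhere), mirroring the study's
    childhood-trauma subsample.
    """
    rng = np.random.default_rng(config.seed)
    pop = simulate_genotypes(config, rng=rng)
    d = draw_causal_effects(config, rng)

    n = pop.n_samples
    age = np.clip(rng.normal(45.0, 12.0, n), 18.0, 80.0)
    sex = (rng.random(n) < 0.55).astype(int)  # 1 = female

    z = _true_score(pop, d)
    env = simulate_environment(config, age, sex, rng, z_g=z)
    exposure = (env["sle_total"].to_numpy() >= 2).astype(float)

    pheno, sel = simulate_phenotype(pop, exposure, d, config, rng)
    panel = pop.subset_samples(sel)
    env = env.iloc[sel].reset_index(drop=True)
    pheno = pheno.reset_index(drop=True)
    pheno["age"] = age[sel]
    pheno["sex"] = sex[sel]

    # BDI at interview: controls are screened (< 10); cases span the range
    case = pheno["case"].to_numpy() == 1
    bdi = np.where(
        case,
        np.clip(np.round(rng.normal(18.0, 9.0, len(sel))), 0, 63),
        rng.integers(0, 10, len(sel)),
    ).astype(float)
    pheno["bdi"] = bdi

    # CT subsample: CTQ observed only for a random subset of cases/controls
    ct_mask = np.zeros(len(sel), dtype=bool)
    ci = np.flatnonzero(case)
    ki = np.flatnonzero(~case)
    ct_mask[rng.choice(ci, min(config.n_ct_cases, len(ci)), replace=False)] = True
    ct_mask[rng.choice(ki, min(config.n_ct_controls, len(ki)), replace=False)] = True
    ctq_cols = [f"ctq_item_{j + 1}" for j in range(N_CTQ_ITEMS)] + ["ctq_total"]
    env[ctq_cols] = env[ctq_cols].astype(float)
    env.loc[~ct_mask, ctq_cols] = np.nan

    truth = true_marginal_log_or(pop, d)
    sumstats = simulate_discovery_sumstats(pop.snp_meta, truth, config, rng=rng)
    return Cohort(
        config=config,
        panel=panel,
        sumstats=sumstats,
        phenotypes=pheno,
        environment=env,
        direct_effects=d,
    )
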