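"""Ancestry PCs, genomic control, age imputation, SLE adjustment, CTQ scoring.

Quality-control and measure-preparation steps: principal components of the
standardized genotype matrix (ancestry covariates), the genomic-control
inflation factor, sex-stratified mean imputation of missing ages,
control-coefficient adjustment of stressful-life-event counts in cases, and
scoring/categorization of the 25-item childhood-trauma questionnaire.

Sex is coded 0 = male, 1 = female throughout; "mean sex" in the SLE
adjustment is the proportion of females among controls.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "compute_pcs",
    "genomic_control_lambda",
    "impute_missing_age",
    "adjust_sle_counts",
    "ctq_score",
    "CHI2_NULL_MEDIAN",
    "DEFAULT_CTQ_CUTPOINTS",
]

#: Median of a 1-df chi-square under the null.
CHI2_NULL_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.454936...

#: Placeholder total-score cut-points for none / mild / moderate-severe CT.
#: The study's exact cut-points come from a prior publication and are not
#: printed; these defaults are configuration, and all interaction models use
#: the quantitative total.
DEFAULT_CTQ_CUTPOINTS = (30.0, 40.0)


def compute_pcs(panel, k: int = 2) -> pd.DataFrame:
    """Top-k principal components of the standardized dosage matrix.

    Dosages are mean-imputed per SNP, centred and variance-standardized
    per SNP (monomorphic SNPs dropped); components are the left singular
    vectors, unit norm, with sign fixed so each component's
    largest-magnitude SNP loading is positive.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = panel.n_samples
    if n < k + 1:
        raise ValueError(f"need at least k+1={k + 1} samples, have {n}")
    X = np.asarray(panel.dosages, dtype=np.float64)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X = np.where(nan, np.broadcast_to(mu, X.shape), X)
    X = X - mu
    sd = X.std(axis=0)
    keep = sd > 0
    X = X[:, keep] / sd[keep]

    # eigendecomposition of the smaller Gram matrix for determinism + speed
    if X.shape[1] <= n:
        G = X.T @ X
        evals, V = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals, V = evals[order], V[:, order]
        pos = evals > 1e-9 * max(evals[0], 1.0)
        rank = int(pos.sum())
        if k > rank:
            raise ValueError(f"k={k} exceeds matrix rank {rank}")
        sv = np.sqrt(evals[:k])
        U = (X @ V[:, :k]) / sv
        load = V[:, :k]
    else:
        G = X @ X.T
        evals, U = np.linalg.eigh(G)
        order = np.argsort(evals)[::-1]
        evals, U = evals[order], U[:, order]
        pos = evals > 1e-9 * max(evals[0], 1.0)
        rank = int(pos.sum())
        if k > rank:
            raise ValueError(f"k={k} exceeds matrix rank {rank}")
        sv = np.sqrt(evals[:k])
        U = U[:, :k]
        load = (X.T @ U) / sv

    for j in range(k):
        i = int(np.argmax(np.abs(load[:, j])))
        if load[i, j] < 0:
            load[:, j] *= -1
            U[:, j] *= -1
    return pd.DataFrame(U, columns=[f"PC{j + 1}" for j in range(k)])


def genomic_control_lambda(
    chi2_stats: np.ndarray | None = None, p_values: np.ndarray | None = None
) -> float:
    """Genomic-control inflation factor: median chi-square / 0.4549.

    Supply either 1-df chi-square statistics or p-values (converted through
    the inverse upper tail).  Values near 1 indicate no inflation from
    population stratification.
    """
    if (chi2_stats is None) == (p_values is None):
        raise ValueError("supply exactly one of chi2_stats or p_values")
    if p_values is not None:
        p = np.asarray(p_values, dtype=float)
        p = p[np.isfinite(p)]
        if len(p) == 0:
            raise ValueError("no finite statistics supplied")
        stats = chi2.isf(p, 1)
    else:
        stats = np.asarray(chi2_stats, dtype=float)
        stats = stats[np.isfinite(stats)]
        if len(stats) == 0:
            raise ValueError("no finite statistics supplied")
    return float(np.median(stats) / CHI2_NULL_MEDIAN)


def impute_missing_age(table: pd.DataFrame, group: str = "both") -> pd.DataFrame:
    """Replace missing ages with the sex-specific mean within case group.

    ``group`` restricts the operation to 'cases', 'controls' or 'both'.
    Requires columns age, sex, case.  Adds/updates a boolean 'age_imputed'
    column.  A (group, sex) stratum that is entirely missing raises.
    """
    if group not in ("cases", "controls", "both"):
        raise ValueError("group must be 'cases', 'controls' or 'both'")
    out = table.copy()
    if "age_imputed" not in out.columns:
        out["age_imputed"] = False
    groups = {"cases": [1], "controls": [0], "both": [1, 0]}[group]
    for g in groups:
        for s in sorted(out.loc[out["case"] == g, "sex"].unique()):
            stratum = (out["case"] == g) & (out["sex"] == s)
            miss = stratum & out["age"].isna()
            if not miss.any():
                continue
            vals = out.loc[stratum & out["age"].notna(), "age"]
            if vals.empty:
                raise ValueError(f"all ages missing in stratum case={g}, sex={s}")
            out.loc[miss, "age"] = vals.mean()
            out.loc[miss, "age_imputed"] = True
    return out


def _control_fit(y: np.ndarray, age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(age), age, sex])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("singular design: age and sex carry no independent variation in controls")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta


def adjust_sle_counts(
    env: pd.DataFrame,
    cov: pd.DataFrame,
    case: np.ndarray,
    columns: tuple[str, ...] = ("sle_total", "sle_dependent", "sle_independent"),
) -> pd.DataFrame:
    """Adjust case SLE counts for age and sex using control coefficients.

    Controls proxy the general population: a least-squares fit of each count
    on age and sex in controls gives coefficients; each case's count is
    shifted by -b_age (age - mean control age) - b_sex (sex - control
    proportion female).  Controls keep their observed counts.  Total,
    dependent and independent counts are adjusted with their own fits.
    Output columns take an ``_adj`` suffix.
    """
    case = np.asarray(case).astype(bool)
    if not (~case).any():
        raise ValueError("no controls available for the adjustment fit")
    age = cov["age"].to_numpy(dtype=float)
    sex = cov["sex"].to_numpy(dtype=float)
    if np.isnan(age[~case]).any():
        raise ValueError("controls have missing ages; impute first")
    mean_age = age[~case].mean()
    mean_sex = sex[~case].mean()
    out = env.copy()
    for col in columns:
        y = env[col].to_numpy(dtype=float)
        beta = _control_fit(y[~case], age[~case], sex[~case])
        adj = y.copy()
        adj[case] = y[case] - beta[1] * (age[case] - mean_age) - beta[2] * (sex[case] - mean_sex)
        out[col + "_adj"] = adj
    return out


def ctq_score(
    items: np.ndarray,
    cutpoints: tuple[float, float] = DEFAULT_CTQ_CUTPOINTS,
    max_missing_frac: float = 0.10,
) -> tuple[np.ndarray, np.ndarray]:
    """Total and category for 25-item childhood-trauma questionnaires.

    ``items`` is (n, 25) with values in 1..5 or NaN.  Missing items are
    prorated by the person's mean over present items; a person missing more
    than ``max_missing_frac`` of items gets a missing total.  Totals are
    clamped to [25, 125].  Categories (by total): none <= c1 < mild <= c2 <
    moderate_severe; missing totals give category ''.
    """
    items = np.asarray(items, dtype=float)
    if items.ndim == 1:
        items = items[None, :]
    n_items = items.shape[1]
    present = ~np.isnan(items)
    bad = present & ((items < 1) | (items > 5) | (items != np.round(items)))
    if bad.any():
        raise ValueError("CTQ items must be integers in 1..5 or missing")
    n_present = present.sum(axis=1)
    too_missing = (n_items - n_present) > max_missing_frac * n_items
    with np.errstate(invalid="ignore"):
        person_mean = np.nansum(items, axis=1) / np.where(n_present > 0, n_present, np.nan)
    total = np.clip(person_mean * n_items, 25.0, 125.0)
    total[too_missing | (n_present == 0)] = np.nan

    c1, c2 = cutpoints
    category = np.full(items.shape[0], "", dtype=object)
    ok = ~np.isnan(total)
    category[ok & (total <= c1)] = "none"
    category[ok & (total > c1) & (total <= c2)] = "mild"
    category[ok & (total > c2)] = "moderate_severe"
    return total, np.asarray(category)
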