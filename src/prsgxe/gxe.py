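"""Association and interaction models with permutation inference.

Implements the study's model set: PRS and environment main effects,
multiplicative (logistic) and additive (linear-probability) PRS x E
interaction with principal-component correction including PC x E and
PC x PRS terms, gene-environment correlation regressions, Nagelkerke
pseudo-R2 variance attribution excluding the PCs, permutation empirical
p-values, Bonferroni control, and the mood-at-interview sensitivity
analysis.

The logistic fitter is an iteratively reweighted least squares (IRLS)
implementation with internal column scaling, run to gradient norm < 1e-8,
with standard errors from the observed information; it raises informative
errors on rank deficiency and separation.  Thousands of warm-started refits
make permutation inference and the replicate studies cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm, t as t_dist

__all__ = [
    "SeparationError",
    "RankDeficiencyError",
    "LogisticFit",
    "LinearFit",
    "GxEFitResult",
    "AnalysisPlan",
    "fit_logistic",
    "fit_linear",
    "nagelkerke_r2",
    "delta_r2_excluding_pcs",
    "test_multiplicative_interaction",
    "test_additive_interaction",
    "ge_correlation",
    "permutation_empirical_p",
    "bonferroni_threshold",
    "sensitivity_exclude_depressed",
    "run_threshold_grid",
    "figure_logodds_by_category",
    "interaction_design",
]

Z95 = 1.959964


class SeparationError(RuntimeError):
    pass


class RankDeficiencyError(ValueError):
    pass


@dataclass
class LogisticFit:
    beta: np.ndarray
    se: np.ndarray
    loglik: float
    cov: np.ndarray
    n_iter: int


@dataclass
class LinearFit:
    beta: np.ndarray
    se: np.ndarray
    r2: float
    df_resid: int


def _colnames(X: np.ndarray, colnames) -> list[str]:
    if colnames is None:
        return [f"x{j}" for j in range(X.shape[1])]
    return list(colnames)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    r = np.linalg.matrix_rank(X)
    if r == X.shape[1]:
        return
    # identify the first column adding no rank
    for j in range(1, X.shape[1] + 1):
        if np.linalg.matrix_rank(X[:, :j]) < j:
            raise RankDeficiencyError(
                f"design is rank deficient: column {names[j - 1]!r} is collinear"
            )
    raise RankDeficiencyError("design is rank deficient")


def _loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically safe Bernoulli log-likelihood: -log(1+exp(-(2y-1) eta))
    s = (2.0 * y - 1.0) * eta
    return float(-np.sum(np.logaddexp(0.0, -s)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    colnames=None,
    tol: float = 1e-8,
    max_iter: int = 100,
    start: np.ndarray | None = None,
    check_rank: bool = True,
) -> LogisticFit:
    """Maximum-likelihood logistic regression by IRLS.

    Converges to gradient max-norm below ``tol``; standard errors come from
    the observed information.  Raises ``RankDeficiencyError`` naming the
    collinear column and ``SeparationError`` naming the diverging column.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    names = _colnames(X, colnames)
    if y.min() == y.max():
        raise ValueError("y is constant; logistic model undefined")
    if check_rank:
        _check_rank(X, names)

    # scale non-constant columns to unit SD: conditions IRLS and puts the
    # separation check on a comparable scale for all columns
    sd = X.std(axis=0)
    scale = np.where(sd > 0, sd, 1.0)
    Xs = X / scale
    beta = np.zeros(X.shape[1]) if start is None else np.asarray(start, dtype=float) * scale

    eta = Xs @ beta
    ll = _loglik(y, eta)
    H = None
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        g = Xs.T @ (y - mu)
        if np.abs(g).max() < tol:
            break
        w = mu * (1.0 - mu)
        H = (Xs * w[:, None]).T @ Xs
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError as e:
            raise SeparationError(
                f"information matrix singular (perfect separation?): {e}"
            ) from e
        # step-halving to guarantee likelihood ascent
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            eta_c = Xs @ cand
            ll_c = _loglik(y, eta_c)
            if ll_c >= ll - 1e-12:
                break
            lam *= 0.5
        beta, eta, ll = cand, eta_c, ll_c
        if np.abs(beta).max() > 30.0:
            j = int(np.argmax(np.abs(beta)))
            raise SeparationError(
                f"coefficient for column {names[j]!r} diverging (|beta|>30 on the unit-SD scale): separation"
            )
    else:
        raise RuntimeError(f"IRLS did not converge in {max_iter} iterations (grad {np.abs(g).max():.2e})")

    mu = expit(eta)
    w = mu * (1.0 - mu)
    H = (Xs * w[:, None]).T @ Xs
    cov_s = np.linalg.inv(H)
    # undo the column scaling
    beta_out = beta / scale
    cov = cov_s / np.outer(scale, scale)
    return LogisticFit(beta=beta_out, se=np.sqrt(np.diag(cov)), loglik=ll, cov=cov, n_iter=it)


def fit_linear(X: np.ndarray, y: np.ndarray, colnames=None, check_rank: bool = True) -> LinearFit:
    """Ordinary least squares with classical standard errors."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    names = _colnames(X, colnames)
    if check_rank:
        _check_rank(X, names)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, k = X.shape
    df = n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    return LinearFit(beta=beta, se=np.sqrt(np.diag(cov)), r2=r2, df_resid=df)


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo-R2.

    R2 = [1 - exp(2 (ll_null - ll_full) / n)] / [1 - exp(2 ll_null / n)].
    Equals 0 at no improvement and 1 at perfect prediction (ll_full = 0).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if loglik_null >= 0:
        raise ValueError("null log-likelihood of 0 is degenerate (constant outcome?)")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("loglik_full must be >= loglik_null")
    loglik_full = max(loglik_full, loglik_null)
    cs = 1.0 - np.exp(2.0 * (loglik_null - loglik_full) / n)
    cs_max = 1.0 - np.exp(2.0 * loglik_null / n)
    return float(cs / cs_max)


def _design(*cols: tuple[str, np.ndarray]) -> tuple[np.ndarray, list[str]]:
    names = [c[0] for c in cols]
    X = np.column_stack([np.asarray(c[1], dtype=float) for c in cols])
    return X, names


def delta_r2_excluding_pcs(
    y: np.ndarray,
    term_columns: np.ndarray,
    pc_columns: np.ndarray | None,
    other_covariates: np.ndarray | None = None,
    term_names=None,
) -> dict:
    """Nagelkerke pseudo-R2 attributable to a term, excluding the PCs.

    Fits the full model (intercept + covariates + PCs + term) and the
    reduced model without the term; both R2 values are Nagelkerke against
    the intercept-only null, and their difference isolates the term's
    contribution net of ancestry.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    term = np.atleast_2d(np.asarray(term_columns, dtype=float))
    if term.shape[0] == n and term.ndim == 2:
        pass
    elif term.shape[1] == n:
        term = term.T
    parts: list[tuple[str, np.ndarray]] = [("intercept", np.ones(n))]
    if other_covariates is not None and np.size(other_covariates):
        oc = np.atleast_2d(np.asarray(other_covariates, dtype=float))
        if oc.shape[0] != n:
            oc = oc.T
        parts += [(f"cov{j}", oc[:, j]) for j in range(oc.shape[1])]
    if pc_columns is not None and np.size(pc_columns):
        pc = np.atleast_2d(np.asarray(pc_columns, dtype=float))
        if pc.shape[0] != n:
            pc = pc.T
        parts += [(f"PC{j + 1}", pc[:, j]) for j in range(pc.shape[1])]
    tnames = term_names or [f"term{j}" for j in range(term.shape[1])]
    full_parts = parts + list(zip(tnames, term.T))

    Xr, nr = _design(*parts)
    Xf, nf = _design(*full_parts)
    ll_null = fit_logistic(np.ones((n, 1)), y, ["intercept"]).loglik
    fit_r = fit_logistic(Xr, y, nr)
    fit_f = fit_logistic(Xf, y, nf)
    r2_full = nagelkerke_r2(fit_f.loglik, ll_null, n)
    r2_reduced = nagelkerke_r2(fit_r.loglik, ll_null, n)
    return {
        "delta_r2": r2_full - r2_reduced,
        "r2_full": r2_full,
        "r2_reduced": r2_reduced,
        "loglik_full": fit_f.loglik,
        "loglik_reduced": fit_r.loglik,
        "loglik_null": ll_null,
        "fit_full": fit_f,
    }


@dataclass
class GxEFitResult:
    """One fitted model at one threshold: estimate, inference, attribution."""

    model_tag: str
    environment: str
    p_t: float
    term: str
    estimate: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    loglik_full: float
    loglik_reduced: float
    delta_r2: float
    p_asymptotic: float
    p_empirical: float
    n_used: int

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["or"] = d.pop("or_")
        return d


def interaction_design(
    prs: np.ndarray, env: np.ndarray, pcs: np.ndarray
) -> tuple[np.ndarray, list[str]]:
    """Design matrix [1, PRS, E, PCs, PC x E, PC x PRS, PRS x E].

    The PC x E and PC x PRS products guard the interaction test against
    confounding of the interaction by ancestry.
    """
    n = len(prs)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != n:
        pcs = pcs.T
    cols = [("intercept", np.ones(n)), ("prs", prs), ("env", env)]
    for j in range(pcs.shape[1]):
        cols.append((f"PC{j + 1}", pcs[:, j]))
    for j in range(pcs.shape[1]):
        cols.append((f"PC{j + 1}:env", pcs[:, j] * env))
    for j in range(pcs.shape[1]):
        cols.append((f"PC{j + 1}:prs", pcs[:, j] * prs))
    cols.append(("prs:env", prs * env))
    return _design(*cols)


def _complete_rows(*arrays) -> np.ndarray:
    ok = np.ones(len(arrays[0]), dtype=bool)
    for a in arrays:
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            ok &= ~np.isnan(a)
        else:
            ok &= ~np.isnan(a).any(axis=1)
    return ok


def permutation_empirical_p(
    observed_stat: float,
    refit,
    y: np.ndarray,
    B: int,
    rng: np.random.Generator,
    max_failure_frac: float = 0.05,
) -> float:
    """Empirical p-value by label permutation.

    Permutes ``y`` (the response) B times, keeping all covariate rows
    intact, recomputes |statistic| via ``refit(y_perm)``, and returns
    p = (1 + #{|perm| >= |observed|}) / (B_ok + 1).  Failed refits (e.g.
    separation in a permutation) are discarded; more than
    ``max_failure_frac`` failures raises.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    obs = abs(observed_stat)
    n_ge = 0
    n_ok = 0
    n_fail = 0
    for _ in range(B):
        yp = rng.permutation(y)
        try:
            stat = refit(yp)
        except (SeparationError, RankDeficiencyError, RuntimeError):
            n_fail += 1
            if n_fail > max_failure_frac * B:
                raise RuntimeError(f"more than {max_failure_frac:.0%} of permutation refits failed")
            continue
        n_ok += 1
        if abs(stat) >= obs:
            n_ge += 1
    return (1 + n_ge) / (n_ok + 1)


def test_multiplicative_interaction(
    y: np.ndarray,
    prs: np.ndarray,
    env: np.ndarray,
    pcs: np.ndarray,
    B: int = 0,
    rng: np.random.Generator | None = None,
    p_t: float = np.nan,
    environment: str = "env",
) -> GxEFitResult:
    """Departure from multiplicativity: logistic model, PRS x E term.

    Covaries for PRS, E, PCs, PC x E and PC x PRS; reports the interaction
    log-OR with Wald inference, its Nagelkerke delta-R2 (reduced model
    omits only PRS x E), and a permutation empirical p when B >= 1.
    """
    y = np.asarray(y, dtype=float)
    ok = _complete_rows(y, prs, env, np.atleast_2d(pcs).T if np.ndim(pcs) == 1 else pcs)
    y, prs, env = y[ok], np.asarray(prs, float)[ok], np.asarray(env, float)[ok]
    pcs = np.atleast_2d(np.asarray(pcs, float))
    pcs = (pcs.T if pcs.shape[0] != len(ok) else pcs)[ok]
    X, names = interaction_design(prs, env, pcs)
    j = names.index("prs:env")

    fit_full = fit_logistic(X, y, names)
    Xr = np.delete(X, j, axis=1)
    fit_red = fit_logistic(Xr, y, names[:j] + names[j + 1:])
    n = len(y)
    ll_null = fit_logistic(np.ones((n, 1)), y, ["intercept"]).loglik
    dr2 = nagelkerke_r2(fit_full.loglik, ll_null, n) - nagelkerke_r2(fit_red.loglik, ll_null, n)

    est, se = fit_full.beta[j], fit_full.se[j]
    z = est / se
    p_asym = 2.0 * norm.sf(abs(z))
    p_emp = np.nan
    if B >= 1:
        if rng is None:
            rng = np.random.default_rng(0)
        warm = fit_full.beta

        def refit(yp):
            f = fit_logistic(X, yp, names, start=warm, check_rank=False)
            return f.beta[j] / f.se[j]

        p_emp = permutation_empirical_p(z, refit, y, B, rng)
    return GxEFitResult(
        model_tag="multiplicative",
        environment=environment,
        p_t=p_t,
        term="prs:env",
        estimate=est,
        se=se,
        or_=float(np.exp(est)),
        ci_low=float(np.exp(est - Z95 * se)),
        ci_high=float(np.exp(est + Z95 * se)),
        loglik_full=fit_full.loglik,
        loglik_reduced=fit_red.loglik,
        delta_r2=dr2,
        p_asymptotic=p_asym,
        p_empirical=p_emp,
        n_used=n,
    )


def test_additive_interaction(
    y: np.ndarray,
    prs: np.ndarray,
    env: np.ndarray,
    pcs: np.ndarray,
    B: int = 0,
    rng: np.random.Generator | None = None,
    p_t: float = np.nan,
    environment: str = "env",
) -> GxEFitResult:
    """Departure from additivity: linear-probability model, same design.

    Ordinary least squares of 0/1 case status on the multiplicative design;
    reports the interaction coefficient, its multiple-R2 increment, and
    asymptotic (t) and permutation p-values.
    """
    y = np.asarray(y, dtype=float)
    ok = _complete_rows(y, prs, env, np.atleast_2d(pcs).T if np.ndim(pcs) == 1 else pcs)
    y, prs, env = y[ok], np.asarray(prs, float)[ok], np.asarray(env, float)[ok]
    pcs = np.atleast_2d(np.asarray(pcs, float))
    pcs = (pcs.T if pcs.shape[0] != len(ok) else pcs)[ok]
    X, names = interaction_design(prs, env, pcs)
    j = names.index("prs:env")

    fit_full = fit_linear(X, y, names)
    fit_red = fit_linear(np.delete(X, j, axis=1), y, names[:j] + names[j + 1:])
    est, se = fit_full.beta[j], fit_full.se[j]
    tval = est / se
    p_asym = 2.0 * t_dist.sf(abs(tval), fit_full.df_resid)
    p_emp = np.nan
    if B >= 1:
        if rng is None:
            rng = np.random.default_rng(0)

        def refit(yp):
            f = fit_linear(X, yp, names, check_rank=False)
            return f.beta[j] / f.se[j]

        p_emp = permutation_empirical_p(tval, refit, y, B, rng)
    return GxEFitResult(
        model_tag="additive",
        environment=environment,
        p_t=p_t,
        term="prs:env",
        estimate=est,
        se=se,
        or_=np.nan,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        loglik_full=np.nan,
        loglik_reduced=np.nan,
        delta_r2=fit_full.r2 - fit_red.r2,
        p_asymptotic=p_asym,
        p_empirical=p_emp,
        n_used=len(y),
    )


def ge_correlation(
    env: np.ndarray,
    prs: np.ndarray,
    pcs: np.ndarray,
    subset: np.ndarray | None = None,
    B: int = 0,
    rng: np.random.Generator | None = None,
    p_t: float = np.nan,
    environment: str = "env",
) -> GxEFitResult:
    """Gene-environment correlation: regress environment on PRS and PCs.

    ``subset`` is a boolean mask (e.g. cases only).  Permutation (when
    B >= 1) shuffles the environment response within the subset.
    """
    env = np.asarray(env, dtype=float)
    prs = np.asarray(prs, dtype=float)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != len(env):
        pcs = pcs.T
    if subset is None:
        subset = np.ones(len(env), dtype=bool)
    subset = np.asarray(subset, dtype=bool)
    if not subset.any():
        raise ValueError("subset is empty")
    ok = subset & _complete_rows(env, prs, pcs)
    e, g, pc = env[ok], prs[ok], pcs[ok]
    if np.ptp(e) == 0:
        raise ValueError("environment is constant in the subset")
    n = len(e)
    X = np.column_stack([np.ones(n), g, pc])
    names = ["intercept", "prs"] + [f"PC{j + 1}" for j in range(pc.shape[1])]
    fit = fit_linear(X, e, names)
    fit_red = fit_linear(np.delete(X, 1, axis=1), e, [names[0]] + names[2:])
    est, se = fit.beta[1], fit.se[1]
    tval = est / se
    p_asym = 2.0 * t_dist.sf(abs(tval), fit.df_resid)
    p_emp = np.nan
    if B >= 1:
        if rng is None:
            rng = np.random.default_rng(0)

        def refit(ep):
            f = fit_linear(X, ep, names, check_rank=False)
            return f.beta[1] / f.se[1]

        p_emp = permutation_empirical_p(tval, refit, e, B, rng)
    return GxEFitResult(
        model_tag="ge_correlation",
        environment=environment,
        p_t=p_t,
        term="prs",
        estimate=est,
        se=se,
        or_=np.nan,
        ci_low=est - Z95 * se,
        ci_high=est + Z95 * se,
        loglik_full=np.nan,
        loglik_reduced=np.nan,
        delta_r2=fit.r2 - fit_red.r2,
        p_asymptotic=p_asym,
        p_empirical=p_emp,
        n_used=n,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m (0.05 over 10 planned tests = 0.005)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def sensitivity_exclude_depressed(
    analysis,
    bdi: np.ndarray,
    case: np.ndarray,
    bdi_threshold: float = 29.0,
):
    """Re-run ``analysis`` excluding cases severely depressed at interview.

    Controls are always retained; cases require BDI < ``bdi_threshold``.
    ``analysis`` is called with the boolean keep-mask.  Raises when no case
    survives the exclusion.
    """
    case = np.asarray(case).astype(bool)
    bdi = np.asarray(bdi, dtype=float)
    keep = ~case | (case & (bdi < bdi_threshold))
    if not (keep & case).any():
        raise ValueError(f"no cases with BDI < {bdi_threshold}; sensitivity subset empty")
    return analysis(keep)


def _main_effect_result(y, term, pcs, tag, environment, p_t, B, rng, logistic=True) -> GxEFitResult:
    ok = _complete_rows(y, term, pcs)
    y2, t2 = np.asarray(y, float)[ok], np.asarray(term, float)[ok]
    pcs2 = np.atleast_2d(np.asarray(pcs, float))
    pcs2 = (pcs2.T if pcs2.shape[0] != len(ok) else pcs2)[ok]
    res = delta_r2_excluding_pcs(y2, t2[:, None], pcs2, term_names=["term"])
    fit = res["fit_full"]
    est, se = fit.beta[-1], fit.se[-1]
    z = est / se
    p_asym = 2.0 * norm.sf(abs(z))
    p_emp = np.nan
    if B >= 1:
        n = len(y2)
        X = np.column_stack([np.ones(n), pcs2, t2])
        warm = fit.beta[[0] + list(range(1, 1 + pcs2.shape[1])) + [-1]]

        def refit(yp):
            f = fit_logistic(X, yp, start=None, check_rank=False)
            return f.beta[-1] / f.se[-1]

        p_emp = permutation_empirical_p(z, refit, y2, B, rng or np.random.default_rng(0))
    return GxEFitResult(
        model_tag=tag,
        environment=environment,
        p_t=p_t,
        term="term",
        estimate=est,
        se=se,
        or_=float(np.exp(est)),
        ci_low=float(np.exp(est - Z95 * se)),
        ci_high=float(np.exp(est + Z95 * se)),
        loglik_full=res["loglik_full"],
        loglik_reduced=res["loglik_reduced"],
        delta_r2=res["delta_r2"],
        p_asymptotic=p_asym,
        p_empirical=p_emp,
        n_used=len(y2),
    )


@dataclass
class AnalysisPlan:
    """Which models to fit over which environments and thresholds.

    ``m`` is the Bonferroni divisor: the study's planned-test count
    (default 10, the paper's convention).  ``B`` is the permutation count.
    """

    models: tuple[str, ...] = (
        "main_prs",
        "main_env",
        "multiplicative",
        "additive",
        "ge_correlation",
    )
    environments: tuple[str, ...] = ("sle_total_adj", "ctq_total")
    grid: tuple[float, ...] = field(default_factory=lambda: (0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5))
    B: int = 99
    m: int = 10
    alpha: float = 0.05
    ge_subset: str = "cases"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1 or self.B < 0:
            raise ValueError("m >= 1 and B >= 0 required")
        known = {"main_prs", "main_env", "multiplicative", "additive", "ge_correlation"}
        bad = set(self.models) - known
        if bad:
            raise ValueError(f"unknown model tags: {sorted(bad)}")


def run_threshold_grid(
    plan: AnalysisPlan,
    scores,
    pcs: np.ndarray | pd.DataFrame,
    y: np.ndarray,
    environments: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Fit every planned model at every threshold; one tidy row per fit.

    ``scores`` is a ScoreMatrix (standardized columns are used).  The
    returned frame carries a ``significant`` flag at the Bonferroni
    threshold alpha/m on the empirical p when available, else the
    asymptotic p — these rows are the bar-chart (delta-R2 by threshold)
    figure data.
    """
    rng = np.random.default_rng(plan.seed)
    pcs = np.asarray(pcs, dtype=float)
    y = np.asarray(y, dtype=float)
    case_mask = y == 1
    rows: list[GxEFitResult] = []
    grid = [t for t in plan.grid if t in scores.thresholds]
    if len(grid) != len(plan.grid):
        raise ValueError("plan grid contains thresholds absent from the score matrix")

    for p_t in grid:
        prs = scores.std_col(p_t)
        if "main_prs" in plan.models:
            rows.append(_main_effect_result(y, prs, pcs, "main_prs", "", p_t, plan.B, rng))
        for env_name in plan.environments:
            env = np.asarray(environments[env_name], dtype=float)
            if "multiplicative" in plan.models:
                rows.append(
                    test_multiplicative_interaction(
                        y, prs, env, pcs, B=plan.B, rng=rng, p_t=p_t, environment=env_name
                    )
                )
            if "additive" in plan.models:
                rows.append(
                    test_additive_interaction(
                        y, prs, env, pcs, B=plan.B, rng=rng, p_t=p_t, environment=env_name
                    )
                )
            if "ge_correlation" in plan.models:
                subset = {"cases": case_mask, "controls": ~case_mask, "all": np.ones_like(case_mask)}[
                    plan.ge_subset
                ]
                rows.append(
                    ge_correlation(
                        env, prs, pcs, subset=subset, B=plan.B, rng=rng, p_t=p_t, environment=env_name
                    )
                )
    if "main_env" in plan.models:
        for env_name in plan.environments:
            env = np.asarray(environments[env_name], dtype=float)
            rows.append(_main_effect_result(y, env, pcs, "main_env", env_name, np.nan, plan.B, rng))

    df = pd.DataFrame([r.to_dict() for r in rows])
    thr = bonferroni_threshold(plan.alpha, plan.m)
    p_eff = df["p_empirical"].fillna(df["p_asymptotic"])
    df["significant"] = p_eff < thr
    return df


def figure_logodds_by_category(
    y: np.ndarray,
    prs_std: np.ndarray,
    categories: np.ndarray,
    n_grid: int = 50,
) -> pd.DataFrame:
    """Predicted log-odds of disease over the standardized PRS, per exposure
    category (the 'log odds by polygenic score' figure).

    Fits a logistic of case status on PRS within each category and returns
    (category, prs, logodds) lines; categories where the fit fails (e.g. a
    category with one outcome class) are skipped.
    """
    y = np.asarray(y, dtype=float)
    prs_std = np.asarray(prs_std, dtype=float)
    categories = np.asarray(categories, dtype=object)
    out = []
    grid = np.linspace(np.nanmin(prs_std), np.nanmax(prs_std), n_grid)
    for cat in [c for c in pd.unique(categories) if c not in ("", None) and c == c]:
        mask = (categories == cat) & ~np.isnan(prs_std) & ~np.isnan(y)
        if mask.sum() < 10 or y[mask].min() == y[mask].max():
            continue
        try:
            fit = fit_logistic(np.column_stack([np.ones(mask.sum()), prs_std[mask]]), y[mask])
        except (SeparationError, RankDeficiencyError, RuntimeError):
            continue
        out.append(
            pd.DataFrame(
                {"category": cat, "prs": grid, "logodds": fit.beta[0] + fit.beta[1] * grid}
            )
        )
    if not out:
        return pd.DataFrame(columns=["category", "prs", "logodds"])
    return pd.concat(out, ignore_index=True)
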