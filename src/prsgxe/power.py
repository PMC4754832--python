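"""Simulation-based power analysis for PRS x environment interaction.

Replicates the study's power calculations by direct simulation instead of
the QUANTO program: each replicate draws a standardized genetic score,
an exposure, and disease status from the logistic model
logit P(case) = b0 + log(OR_G) G + log(OR_E) E + log(OR_GxE) G E,
retrospectively samples cases and controls to quota, fits the two-variable
multiplicative model (no PCs: no stratification is simulated), and records
Wald rejection of the interaction at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .gxe import SeparationError, fit_logistic

__all__ = ["PowerScenario", "estimate_power", "sample_case_control"]


@dataclass(frozen=True)
class PowerScenario:
    """One power-calculation design point.

    Defaults mirror the study's SLE scenario: 1605 cases / 1064 controls,
    OR_G 1.22 per SD of PRS, OR_E 1.82 for a binary exposure of prevalence
    0.45, interaction OR 1.28 at two-sided alpha 0.05.  The CT scenario is
    (240, 272, 1.22, 2.27, 1.76) at prevalence 0.30.  ``baseline_logodds``
    sets the unexposed population risk (the paper never prints the
    prevalence its calculations assumed; logit(0.15) is the default).
    """

    n_cases: int = 1605
    n_controls: int = 1064
    or_g: float = 1.22
    or_e: float = 1.82
    or_gxe: float = 1.28
    env_kind: str = "binary"
    env_prevalence: float = 0.45
    env_pmf: tuple[float, ...] | None = None  # for env_kind="count": P(E=0), P(E=1), ...
    alpha: float = 0.05
    n_reps: int = 1000
    baseline_logodds: float = -1.7346
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if min(self.n_cases, self.n_controls) < 1:
            raise ValueError("n_cases and n_controls must be >= 1")
        for nm in ("or_g", "or_e", "or_gxe"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be positive")
        if self.env_kind not in ("binary", "count"):
            raise ValueError("env_kind must be 'binary' or 'count'")
        if self.env_kind == "binary" and not (0 < self.env_prevalence < 1):
            raise ValueError("env_prevalence must lie in (0, 1)")
        if self.env_kind == "count":
            if self.env_pmf is None or abs(sum(self.env_pmf) - 1.0) > 1e-9:
                raise ValueError("env_kind='count' requires env_pmf summing to 1")


def _draw_env(s: PowerScenario, rng: np.random.Generator, m: int) -> np.ndarray:
    if s.env_kind == "binary":
        return (rng.random(m) < s.env_prevalence).astype(float)
    return rng.choice(len(s.env_pmf), size=m, p=np.asarray(s.env_pmf)).astype(float)


def sample_case_control(
    s: PowerScenario, rng: np.random.Generator, batch: int = 8192, max_draws: int = 50_000_000
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (G, E, y) with exactly n_cases cases first, n_controls after.

    Population individuals are generated in batches and assigned case
    status from the logistic model; sampling stops when both quotas fill.
    """
    lg, le, lge = np.log(s.or_g), np.log(s.or_e), np.log(s.or_gxe)
    g_case, e_case, g_ctrl, e_ctrl = [], [], [], []
    need_case, need_ctrl = s.n_cases, s.n_controls
    drawn = 0
    while need_case > 0 or need_ctrl > 0:
        if drawn >= max_draws:
            raise RuntimeError(
                f"case/control quota unreachable in {max_draws} draws: achieved "
                f"{s.n_cases - need_case} cases, {s.n_controls - need_ctrl} controls"
            )
        m = batch
        G = rng.standard_normal(m)
        E = _draw_env(s, rng, m)
        p = 1.0 / (1.0 + np.exp(-(s.baseline_logodds + lg * G + le * E + lge * G * E)))
        case = rng.random(m) < p
        drawn += m
        if need_case > 0:
            k = min(need_case, int(case.sum()))
            g_case.append(G[case][:k])
            e_case.append(E[case][:k])
            need_case -= k
        if need_ctrl > 0:
            k = min(need_ctrl, int((~case).sum()))
            g_ctrl.append(G[~case][:k])
            e_ctrl.append(E[~case][:k])
            need_ctrl -= k
    G = np.concatenate(g_case + g_ctrl)
    E = np.concatenate(e_case + e_ctrl)
    y = np.concatenate([np.ones(s.n_cases), np.zeros(s.n_controls)])
    return G, E, y


def estimate_power(s: PowerScenario) -> tuple[float, float]:
    """Estimated power of the multiplicative interaction Wald test.

    Returns (power, Monte-Carlo standard error).  Replicates hitting
    separation are discarded and counted; more than 5% discards raises.
    """
    rng = np.random.default_rng(s.seed)
    crit = norm.isf(s.alpha / 2.0)
    rejected = 0
    used = 0
    failed = 0
    for _ in range(s.n_reps):
        G, E, y = sample_case_control(s, rng)
        X = np.column_stack([np.ones_like(G), G, E, G * E])
        try:
            fit = fit_logistic(X, y, ["intercept", "g", "e", "gxe"], check_rank=False)
        except (SeparationError, RuntimeError):
            failed += 1
            if failed > 0.05 * s.n_reps:
                raise RuntimeError("more than 5% of power replicates failed to fit")
            continue
        used += 1
        if abs(fit.beta[3] / fit.se[3]) > crit:
            rejected += 1
    power = rejected / used
    mcse = float(np.sqrt(power * (1.0 - power) / used))
    return power, mcse
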