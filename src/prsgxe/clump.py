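"""P-value-informed greedy LD clumping and p-value thresholding.

Implements the PLINK-style clumping procedure used to prune discovery
summary statistics against the LD structure of the validation panel
(defaults: ``--clump-p1 0.5 --clump-p2 0.1 --clump-r2 0.25
--clump-kb 300``), and the selection of nested SNP subsets at increasingly
liberal p-value thresholds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ClumpParams",
    "ClumpIndex",
    "DEFAULT_THRESHOLD_GRID",
    "compute_ld_r2",
    "clump",
    "select_threshold_subset",
]

#: Nine increasingly liberal p-value thresholds for score construction.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (
    0.0001, 0.001, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
)


def validate_threshold_grid(grid) -> tuple[float, ...]:
    grid = tuple(float(t) for t in grid)
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    if any(not (0 < t <= 1) for t in grid):
        raise ValueError("thresholds must lie in (0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("thresholds must be strictly increasing")
    return grid


@dataclass(frozen=True)
class ClumpParams:
    """Greedy clumping parameters (PLINK --clump semantics).

    p1: index-SNP eligibility p-value threshold; p2: clump-membership
    threshold; r2_max: LD threshold above which a candidate joins a clump;
    window_kb: physical window around the index SNP.
    """

    p1: float = 0.5
    p2: float = 0.1
    r2_max: float = 0.25
    window_kb: float = 300.0

    def __post_init__(self) -> None:
        if not (0 < self.p2 <= self.p1 <= 1):
            raise ValueError("require 0 < p2 <= p1 <= 1")
        if not (0 < self.r2_max < 1):
            raise ValueError("require 0 < r2_max < 1")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class ClumpIndex:
    """Result of clumping: index SNPs, clump membership and survivors.

    ``retained`` is the scoring set: index SNPs plus every SNP never removed
    as a clump member (including SNPs with p >= p1, which can never be
    indexed, and SNPs with p2 <= p < p1, which can be indexed but never
    removed).  ``not_in_panel`` lists summary-stat SNPs absent from the
    panel; they pass through untouched here and are dropped at scoring.
    """

    retained: list[str]
    clump_members: dict[str, list[str]]
    not_in_panel: list[str] = field(default_factory=list)

    @property
    def index_snps(self) -> list[str]:
        return list(self.clump_members)

    @property
    def removed(self) -> set[str]:
        return {m for members in self.clump_members.values() for m in members}


def compute_ld_r2(panel, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation of dosages over pairwise-complete samples.

    Zero variance in either SNP gives 0 (a monomorphic SNP cannot evidence
    LD) with a warning.
    """
    ia, ib = panel.snp_index(snp_a), panel.snp_index(snp_b)
    x = np.asarray(panel.dosages[:, ia], dtype=float)
    y = np.asarray(panel.dosages[:, ib], dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        raise ValueError(f"fewer than 2 pairwise-complete samples for {snp_a}, {snp_b}")
    return _r2(x[ok], y[ok], snp_a, snp_b)


def _r2(x: np.ndarray, y: np.ndarray, snp_a: str = "?", snp_b: str = "?") -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = xc @ xc
    vy = yc @ yc
    if vx == 0 or vy == 0:
        warnings.warn(
            f"zero dosage variance for {snp_a if vx == 0 else snp_b}; r2 defined as 0",
            stacklevel=2,
        )
        return 0.0
    r = (xc @ yc) / np.sqrt(vx * vy)
    return min(float(r * r), 1.0)


def clump(sumstats: pd.DataFrame, panel, params: ClumpParams | None = None) -> ClumpIndex:
    """Greedy p-value-informed clumping of ``sumstats`` against ``panel`` LD.

    SNPs with p < p1 are visited in ascending p order (ties broken by
    chromosome, position, id); each unremoved visitee becomes an index SNP
    and removes every unassigned SNP with p < p2 within ``window_kb`` on the
    same chromosome with r² > r2_max.  Index SNPs are never removed by later
    (weaker) indices.  SNPs missing a p-value are ignored.
    """
    if params is None:
        params = ClumpParams()
    ss = sumstats.loc[sumstats["p"].notna(), ["snp", "chrom", "bp", "p"]].reset_index(drop=True)
    if ss.empty:
        return ClumpIndex(retained=[], clump_members={})
    if ss["snp"].duplicated().any():
        dups = sorted(ss.loc[ss["snp"].duplicated(), "snp"].unique())
        raise ValueError(f"duplicate SNP ids in summary statistics: {dups}")

    panel_ids = set(panel.snp_meta["snp"])
    in_panel = ss["snp"].isin(panel_ids).to_numpy()
    not_in_panel = ss.loc[~in_panel, "snp"].tolist()
    if not_in_panel:
        logger.info("%d summary-stat SNPs absent from panel; passed through untouched", len(not_in_panel))
    ss = ss.loc[in_panel].reset_index(drop=True)

    snp_ids = ss["snp"].to_numpy()
    chrom = ss["chrom"].to_numpy()
    bp = ss["bp"].to_numpy(dtype=np.int64)
    p = ss["p"].to_numpy(dtype=float)
    col = np.array([panel.snp_index(s) for s in snp_ids])
    window = int(round(params.window_kb * 1000))

    order = np.lexsort((snp_ids, bp, chrom, p))  # primary key last: p asc, then D8 tie-break
    eligible = order[p[order] < params.p1]

    removed = np.zeros(len(ss), dtype=bool)
    indexed = np.zeros(len(ss), dtype=bool)
    clumps: dict[str, list[str]] = {}
    X = panel.dosages
    for i in eligible:
        if removed[i]:
            continue
        indexed[i] = True
        cand = np.flatnonzero(
            (chrom == chrom[i])
            & (np.abs(bp - bp[i]) <= window)
            & (p < params.p2)
            & ~removed
            & ~indexed
        )
        members: list[str] = []
        if len(cand):
            xi = np.asarray(X[:, col[i]], dtype=float)
            for j in cand:
                xj = np.asarray(X[:, col[j]], dtype=float)
                ok = ~(np.isnan(xi) | np.isnan(xj))
                if ok.sum() < 2:
                    continue
                if _r2(xi[ok], xj[ok], str(snp_ids[i]), str(snp_ids[j])) > params.r2_max:
                    members.append(str(snp_ids[j]))
                    removed[j] = True
        clumps[str(snp_ids[i])] = members

    retained = [str(s) for s in snp_ids[~removed]] + not_in_panel
    return ClumpIndex(retained=retained, clump_members=clumps, not_in_panel=not_in_panel)


def select_threshold_subset(sumstats: pd.DataFrame, p_t: float) -> set[str]:
    """SNP ids with p strictly below ``p_t`` (subsets nest across a grid)."""
    if not (0 < p_t <= 1):
        raise ValueError("p_T must lie in (0, 1]")
    sel = sumstats.loc[sumstats["p"] < p_t, "snp"]
    return set(sel.astype(str))
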