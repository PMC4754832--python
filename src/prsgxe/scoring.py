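"""Allele harmonization and log-OR-weighted polygenic scoring.

Scores are the discovery log odds ratios summed over risk-allele dosages,
computed per p-value threshold and standardized to mean 0, SD 1 over the
full analysis sample (cases and controls jointly).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clump import select_threshold_subset, validate_threshold_grid

logger = logging.getLogger(__name__)

__all__ = ["align_alleles", "compute_prs", "score_grid", "ScoreMatrix"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS = ({"A", "T"}, {"C", "G"})


def align_alleles(sumstats: pd.DataFrame, panel) -> pd.DataFrame:
    """Harmonize summary-stat effect alleles to the panel's counted allele.

    Returns a frame (snp, log_or, status) for SNPs present in both sources:
    status 'matched' (same A1/A2), 'flipped' (swapped; log-OR negated),
    'strand_flipped' (complementary strand, with or without swap),
    'ambiguous_dropped' (A/T or C/G pairs, strand unresolvable) or
    'mismatched_dropped'.  Dropped SNPs carry weight NaN.  Duplicate SNP ids
    in either source raise.
    """
    for name, df in (("sumstats", sumstats), ("panel", panel.snp_meta)):
        if df["snp"].duplicated().any():
            dups = sorted(df.loc[df["snp"].duplicated(), "snp"].unique())
            raise ValueError(f"duplicate SNP ids in {name}: {dups}")

    pm = panel.snp_meta.set_index("snp")
    merged = sumstats.loc[sumstats["snp"].isin(pm.index), ["snp", "a1", "a2", "log_or"]]
    n_absent = len(sumstats) - len(merged)
    if n_absent:
        logger.info("%d summary-stat SNPs absent from panel dropped from scoring", n_absent)

    rows = []
    for snp, sa1, sa2, lor in merged.itertuples(index=False):
        pa1, pa2 = pm.at[snp, "a1"], pm.at[snp, "a2"]
        alleles = {sa1, sa2}
        if alleles in _AMBIGUOUS:
            rows.append((snp, np.nan, "ambiguous_dropped"))
            continue
        ca1, ca2 = _COMPLEMENT.get(sa1), _COMPLEMENT.get(sa2)
        if (sa1, sa2) == (pa1, pa2):
            rows.append((snp, lor, "matched"))
        elif (sa1, sa2) == (pa2, pa1):
            rows.append((snp, -lor, "flipped"))
        elif (ca1, ca2) == (pa1, pa2):
            rows.append((snp, lor, "strand_flipped"))
        elif (ca1, ca2) == (pa2, pa1):
            rows.append((snp, -lor, "strand_flipped"))
        else:
            rows.append((snp, np.nan, "mismatched_dropped"))

    out = pd.DataFrame(rows, columns=["snp", "log_or", "status"])
    counts = out["status"].value_counts().to_dict()
    logger.info("allele alignment: %s", counts)
    return out


def compute_prs(panel, weights: pd.DataFrame, snp_set) -> np.ndarray:
    """Raw polygenic score: sum over SNPs of aligned log-OR times dosage.

    Missing dosages are mean-imputed as 2 x empirical A1 frequency from the
    panel.  An empty SNP set yields all-zero scores with a warning.
    """
    usable = weights.loc[weights["log_or"].notna()]
    snp_set = set(snp_set)
    extra = snp_set - set(usable["snp"])
    if extra & set(weights["snp"]):
        raise ValueError(f"snp_set contains dropped (unaligned) SNPs: {sorted(extra)[:5]}")
    use = usable.loc[usable["snp"].isin(snp_set)]
    if use.empty:
        warnings.warn("empty SNP set: scores are all zero", stacklevel=2)
        return np.zeros(panel.n_samples)
    cols = np.array([panel.snp_index(s) for s in use["snp"]])
    w = use["log_or"].to_numpy(dtype=float)
    D = np.asarray(panel.dosages[:, cols], dtype=np.float64)
    if np.isnan(D).any():
        freq2 = 2.0 * panel.empirical_freq()[cols]
        nan = np.isnan(D)
        D[nan] = np.broadcast_to(freq2, D.shape)[nan]
    return D @ w


@dataclass
class ScoreMatrix:
    """Per-sample scores at each threshold, raw and standardized."""

    sample_ids: np.ndarray
    thresholds: tuple[float, ...]
    raw: np.ndarray  # n_samples x n_thresholds
    std: np.ndarray
    snp_counts: list[int]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.sample_ids})
        for j, t in enumerate(self.thresholds):
            df[f"prs_raw_{t:g}"] = self.raw[:, j]
            df[f"prs_std_{t:g}"] = self.std[:, j]
        return df

    def std_col(self, p_t: float) -> np.ndarray:
        return self.std[:, self.thresholds.index(p_t)]


def score_grid(panel, weights: pd.DataFrame, sumstats_retained: pd.DataFrame, grid) -> ScoreMatrix:
    """Score every sample at every threshold of ``grid``.

    ``sumstats_retained`` supplies p-values for the clump-retained SNPs.
    Standardization (mean 0, SD 1, sample SD) is over all scored samples;
    a threshold with zero aligned SNPs yields a zero column and a warning.
    """
    grid = validate_threshold_grid(grid)
    aligned = set(weights.loc[weights["log_or"].notna(), "snp"])
    n = panel.n_samples
    raw = np.zeros((n, len(grid)))
    std = np.zeros((n, len(grid)))
    counts = []
    for j, p_t in enumerate(grid):
        snps = select_threshold_subset(sumstats_retained, p_t) & aligned
        counts.append(len(snps))
        if not snps:
            warnings.warn(f"threshold p_T={p_t:g}: zero SNPs; column of zeros", stacklevel=2)
            continue
        raw[:, j] = compute_prs(panel, weights, snps)
        sd = raw[:, j].std(ddof=1)
        if sd > 0:
            std[:, j] = (raw[:, j] - raw[:, j].mean()) / sd
    return ScoreMatrix(
        sample_ids=np.asarray(panel.sample_ids),
        thresholds=grid,
        raw=raw,
        std=std,
        snp_counts=counts,
    )
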