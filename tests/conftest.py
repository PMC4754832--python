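import numpy as np
import pandas as pd
import pytest

from prsgxe import SimulationConfig, simulate_cohort
from prsgxe.simulate import GenotypePanel


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete simulated study used across test modules."""
    cfg = SimulationConfig(
        n_cases=300,
        n_controls=200,
        n_snps=200,
        n_blocks=20,
        n_ct_cases=80,
        n_ct_controls=90,
        or_gxe=1.28,
        seed=11,
    )
    return simulate_cohort(cfg)


def make_panel(dosages, chrom=None, bp=None, a1=None, a2=None, snp=None, freq=None):
    """Hand-built GenotypePanel from a dosage matrix (helpers for toys)."""
    dosages = np.asarray(dosages, dtype=np.float32)
    n, m = dosages.shape
    meta = pd.DataFrame(
        {
            "snp": snp if snp is not None else [f"snp{j}" for j in range(m)],
            "chrom": chrom if chrom is not None else [1] * m,
            "bp": bp if bp is not None else [1000 * (j + 1) for j in range(m)],
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
        }
    )
    with np.errstate(invalid="ignore"):
        meta["freq"] = freq if freq is not None else np.nanmean(dosages, axis=0) / 2.0
    ids = np.array([f"I{i:04d}" for i in range(n)])
    return GenotypePanel(sample_ids=ids, snp_meta=meta, dosages=dosages)


@pytest.fixture
def panel_factory():
    return make_panel
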