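"""Readers and writers for the pipeline's text formats.

Formats: daner-style summary statistics (SNP CHR BP A1 A2 OR P), PLINK
.raw-style dosage text (FID IID then one column per SNP named id_A1),
.bim-style SNP metadata, and tab-separated phenotype/covariate/environment
tables.  All tables are TSV with '#'-prefixed metadata header lines and
'NA' for missing values.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import GenotypePanel

NA = "NA"


def _meta_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_meta_lines(meta))
        # %.17g guarantees exact float64 round-trip on reload
        df.to_csv(fh, sep="\t", index=False, na_rep=NA, float_format="%.17g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[NA], float_precision="round_trip")


def config_hash(obj) -> str:
    return hashlib.sha1(repr(obj).encode()).hexdigest()[:12]


def write_sumstats(sumstats: pd.DataFrame, path, meta: dict | None = None) -> None:
    """daner-style columns: SNP CHR BP A1 A2 OR P."""
    out = pd.DataFrame(
        {
            "SNP": sumstats["snp"],
            "CHR": sumstats["chrom"],
            "BP": sumstats["bp"],
            "A1": sumstats["a1"],
            "A2": sumstats["a2"],
            "OR": sumstats["or"],
            "P": sumstats["p"],
        }
    )
    write_table(out, path, meta)


def read_sumstats(path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep=r"\s+", comment="#", na_values=[NA], float_precision="round_trip")
    raw.columns = [c.upper() for c in raw.columns]
    need = {"SNP", "CHR", "BP", "A1", "A2", "OR", "P"}
    missing = need - set(raw.columns)
    if missing:
        raise ValueError(f"summary statistics missing columns: {sorted(missing)}")
    out = pd.DataFrame(
        {
            "snp": raw["SNP"].astype(str),
            "chrom": raw["CHR"].astype(int),
            "bp": raw["BP"].astype(int),
            "a1": raw["A1"].astype(str),
            "a2": raw["A2"].astype(str),
            "or": raw["OR"].astype(float),
            "p": raw["P"].astype(float),
        }
    )
    with np.errstate(divide="ignore"):
        out["log_or"] = np.log(out["or"])
    return out


def write_dosage_raw(panel: GenotypePanel, path, meta: dict | None = None) -> None:
    """PLINK .raw-style dosage text: FID IID then {snp}_{A1} columns."""
    cols = {"FID": panel.sample_ids, "IID": panel.sample_ids}
    df = pd.DataFrame(cols)
    names = [f"{s}_{a}" for s, a in zip(panel.snp_meta["snp"], panel.snp_meta["a1"])]
    dos = pd.DataFrame(np.asarray(panel.dosages, dtype=float), columns=names)
    write_table(pd.concat([df, dos], axis=1), path, meta)


def write_bim(panel: GenotypePanel, path) -> None:
    """.bim-style metadata: chrom, id, cm(0), bp, a1, a2; no header."""
    m = panel.snp_meta
    out = pd.DataFrame(
        {0: m["chrom"], 1: m["snp"], 2: 0, 3: m["bp"], 4: m["a1"], 5: m["a2"]}
    )
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, header=False)


def read_bim(path) -> pd.DataFrame:
    out = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "snp", "cm", "bp", "a1", "a2"]
    )
    return out.drop(columns=["cm"])


def read_dosage_raw(path, bim: pd.DataFrame | None = None, freq: np.ndarray | None = None) -> GenotypePanel:
    """Rebuild a GenotypePanel from .raw dosage text (+ optional .bim)."""
    raw = read_table(path)
    id_col = "IID" if "IID" in raw.columns else raw.columns[0]
    sample_ids = raw[id_col].astype(str).to_numpy()
    snp_cols = [c for c in raw.columns if c not in ("FID", "IID")]
    snps = [c.rsplit("_", 1)[0] for c in snp_cols]
    a1s = [c.rsplit("_", 1)[1] for c in snp_cols]
    dosages = raw[snp_cols].to_numpy(dtype=np.float32)
    if bim is not None:
        meta = bim.set_index("snp").loc[snps].reset_index()
        if not all(meta["a1"] == a1s):
            raise ValueError(".raw counted alleles disagree with .bim A1")
    else:
        meta = pd.DataFrame(
            {"snp": snps, "chrom": 0, "bp": np.arange(len(snps)), "a1": a1s, "a2": "N"}
        )
    if "freq" not in meta.columns:
        with np.errstate(invalid="ignore"):
            meta["freq"] = np.nanmean(dosages, axis=0) / 2.0 if freq is None else freq
    return GenotypePanel(sample_ids=sample_ids, snp_meta=meta, dosages=dosages)


def write_phenotypes(pheno: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(pheno, path, meta)


def write_environment(env: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_table(env, path, meta)
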