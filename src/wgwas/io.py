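"""File formats: PLINK1 bed/bim/fam, dosage TSV, cohort and summary tables.

Genotypes travel as PLINK1 binary triples (SNP-major, two bits per call) or
as plain dosage TSV; all tabular artifacts are header-bearing TSV keyed by
individual ID.  Readers validate schemas and fail with the offending column
or line named.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from wgwas.synthetic import GenotypeSet

__all__ = [
    "SchemaError",
    "write_plink",
    "read_plink",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_cohort_tsv",
    "read_cohort_tsv",
    "write_summary_stats",
    "read_summary_stats",
    "write_weights_tsv",
    "read_weights_tsv",
    "write_yaml",
    "read_yaml",
]

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK1 magic + SNP-major flag

# two-bit codes (per SNP-major byte, LSB first): 00 hom A1, 01 missing,
# 10 het, 11 hom A2 — mapped to A1-allele dosage 2 / -1 / 1 / 0
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}


class SchemaError(ValueError):
    """A tabular file does not match the expected schema."""


# ---------------------------------------------------------------------------
# PLINK1 bed/bim/fam
# ---------------------------------------------------------------------------


def write_plink(g: GenotypeSet, prefix: str | Path, ids: Optional[Sequence[str]] = None) -> None:
    """Write a GenotypeSet as PLINK1 ``prefix.bed/.bim/.fam`` (SNP-major)."""
    prefix = Path(prefix)
    n, m = g.dosages.shape
    ids = [f"ind_{i}" for i in range(n)] if ids is None else list(ids)
    if len(ids) != n:
        raise ValueError("ids length must match individuals")

    meta = g.snp_meta
    bim = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "snp": meta["snp"],
            "cm": 0,
            "pos": meta["pos"],
            "a1": meta["a1"],
            "a2": meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": ids, "iid": ids, "pat": 0, "mat": 0, "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    dosages_t = g.dosages.T
    for dosage, code in _DOSAGE_TO_CODE.items():
        codes[dosages_t == dosage] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for k in range(4):
        cols = codes[:, k::4]
        packed[:, : cols.shape[1]] |= cols << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> tuple[GenotypeSet, list[str]]:
    """Read a PLINK1 triple; returns the GenotypeSet and individual IDs."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise SchemaError(f"{prefix}.bed is not a SNP-major PLINK1 bed file")
    n_bytes = (n + 3) // 4
    body = raw[3:].reshape(m, n_bytes)
    codes_all = np.empty((m, n_bytes * 4), dtype=np.uint8)
    for k in range(4):
        codes_all[:, k::4] = (body >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes_all[:, :n]].T.astype(np.int8)

    meta = bim[["snp", "chrom", "pos", "a1", "a2"]].copy()
    g = GenotypeSet(dosages=np.ascontiguousarray(dosages), snp_meta=meta)
    g.snp_meta["freq"] = g.allele_frequencies()
    return g, fam["iid"].tolist()


# ---------------------------------------------------------------------------
# Dosage TSV
# ---------------------------------------------------------------------------


def write_dosage_tsv(g: GenotypeSet, path: str | Path, ids: Optional[Sequence[str]] = None) -> None:
    """Plain dosage TSV: one row per individual, one column per SNP, NA missing."""
    n = g.n_individuals
    ids = [f"ind_{i}" for i in range(n)] if ids is None else list(ids)
    df = pd.DataFrame(
        g.dosages.astype(float), columns=g.snp_meta["snp"].tolist()
    ).replace(-1.0, np.nan)
    df.insert(0, "id", ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_dosage_tsv(path: str | Path, snp_meta: Optional[pd.DataFrame] = None) -> tuple[GenotypeSet, list[str]]:
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise SchemaError(f"{path}: dosage TSV must have an 'id' column")
    ids = df["id"].astype(str).tolist()
    snps = [c for c in df.columns if c != "id"]
    dosages = df[snps].to_numpy(dtype=float)
    dosages = np.where(np.isnan(dosages), -1, dosages).astype(np.int8)
    if snp_meta is None:
        snp_meta = pd.DataFrame(
            {
                "snp": snps,
                "chrom": 1,
                "pos": 1 + 5_000 * np.arange(len(snps), dtype=np.int64),
                "a1": "A",
                "a2": "G",
            }
        )
    g = GenotypeSet(dosages=dosages, snp_meta=snp_meta)
    g.snp_meta["freq"] = g.allele_frequencies()
    return g, ids


# ---------------------------------------------------------------------------
# Cohort / weights / summary tables
# ---------------------------------------------------------------------------

_COHORT_REQUIRED = ("id", "participation", "design_weight")
SUMMARY_REQUIRED = ("SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "Z", "P", "N")


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COHORT_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: cohort TSV missing column(s) {missing} (header line 1)")
    return df


def write_summary_stats(ss: pd.DataFrame, path: str | Path) -> None:
    ss.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SUMMARY_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: summary-stats TSV missing column(s) {missing} (header line 1)"
        )
    return df


def write_weights_tsv(ids: Sequence[str], P: np.ndarray, w: np.ndarray, w_in: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"id": ids, "P": P, "w": w, "w_in": w_in}).to_csv(
        path, sep="\t", index=False
    )


def read_weights_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("id", "P", "w", "w_in") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: weights TSV missing column(s) {missing} (header line 1)")
    return df


def write_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
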