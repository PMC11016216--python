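"""Reading and writing of GWAS summary-statistics tables and LD references.

The on-disk exchange format is tab-delimited text with the fixed column
order ``snp, chr, pos, ea, oa, eaf, beta, se, pval, n``; one row per
variant-trait association.  LD references are stored as a square
tab-delimited r-squared matrix plus a variant index file carrying the
variant id, chromosome and base-pair position of each row/column.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

_DTYPES = {
    "snp": str,
    "chr": str,
    "ea": str,
    "oa": str,
    "pos": np.int64,
    "eaf": float,
    "beta": float,
    "se": float,
    "pval": float,
    "n": np.int64,
}


def read_sumstats(path: str | os.PathLike) -> pd.DataFrame:
    """Read a tab-delimited GWAS summary-statistics table.

    Raises ``ValueError`` when required columns are missing or basic
    sanity constraints (positive SE, p in (0, 1], frequency in (0, 1))
    are violated.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str, "ea": str, "oa": str})
    missing = [c for c in SUMSTATS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary-statistics table missing columns: {missing}")
    df = df[SUMSTATS_COLUMNS].astype(_DTYPES)
    validate_sumstats(df)
    return df


def write_sumstats(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a summary-statistics table in the canonical column order."""
    df[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def validate_sumstats(df: pd.DataFrame) -> None:
    if (df["se"] <= 0).any():
        raise ValueError("summary statistics contain non-positive standard errors")
    if ((df["pval"] <= 0) | (df["pval"] > 1)).any():
        raise ValueError("summary statistics contain p-values outside (0, 1]")
    if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
        raise ValueError("summary statistics contain allele frequencies outside (0, 1)")
    if not np.isfinite(df[["beta", "se"]].to_numpy()).all():
        raise ValueError("summary statistics contain non-finite effects")


def write_ld(ld, matrix_path: str | os.PathLike, index_path: str | os.PathLike) -> None:
    """Write an LD reference as a square r² matrix plus a variant index."""
    np.savetxt(matrix_path, ld.r2, delimiter="\t", fmt="%.10g")
    idx = pd.DataFrame(
        {"snp": ld.variant_ids, "chr": ld.chromosome, "pos": ld.positions}
    )
    idx.to_csv(index_path, sep="\t", index=False)


def read_ld(matrix_path: str | os.PathLike, index_path: str | os.PathLike):
    """Read an LD reference written by :func:`write_ld`."""
    from .simulate import LDReference

    r2 = np.loadtxt(matrix_path, delimiter="\t", ndmin=2)
    idx = pd.read_csv(index_path, sep="\t", dtype={"snp": str, "chr": str})
    chroms = idx["chr"].unique()
    if len(chroms) != 1:
        raise ValueError("LD reference index must cover a single chromosome")
    return LDReference(
        variant_ids=list(idx["snp"]),
        r2=r2,
        positions=idx["pos"].to_numpy(dtype=np.int64),
        chromosome=str(chroms[0]),
    )
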