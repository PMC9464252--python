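"""Readers and writers for the formats the tool touches.

PLINK bed/bim/fam (variant-major, the only mode modern PLINK writes),
TSV tables for phenotypes, covariates, annotations and gene definitions,
and the results table.  Positions are 1-based throughout; variant ids
are canonically "chrom:pos:ref:alt".
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "read_table",
    "read_sample_table",
    "write_results",
    "RESULT_COLUMNS",
]

_BED_MAGIC = b"\x6c\x1b\x01"

# 2-bit codes (variant-major, pairs of bits little-endian within a byte):
# 00 -> two A1 alleles, 01 -> missing, 10 -> het, 11 -> two A2 alleles.
# Dosage counts the A1 allele.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """n x m minor-allele dosage matrix with variant metadata.

    ``dosages`` holds floats in {0, 1, 2} with NaN for missing calls,
    oriented so each column counts the minor allele (folded MAF <= 0.5).
    """

    dosages: np.ndarray
    sample_ids: list[str]
    variant_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    a1: list[str]
    a2: list[str]
    flipped: np.ndarray | None = None  # columns re-oriented on read

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        j = self.variant_ids.index(variant_id)
        return self.dosages[:, j]

    def subset_variants(self, ids: list[str]) -> "GenotypeMatrix":
        idx = [self.variant_ids.index(v) for v in ids]
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.sample_ids,
            [self.variant_ids[j] for j in idx],
            self.chrom[idx],
            self.pos[idx],
            [self.a1[j] for j in idx],
            [self.a2[j] for j in idx],
        )


def read_plink(bed: str, bim: str | None = None, fam: str | None = None) -> GenotypeMatrix:
    """Decode a PLINK bed/bim/fam triplet into minor-allele dosages.

    Columns whose A1 allele turns out to be the major allele are flipped
    so every dosage counts the minor allele.
    """
    base, ext = os.path.splitext(bed)
    if ext != ".bed":
        base = bed
        bed = base + ".bed"
    bim = bim or base + ".bim"
    fam = fam or base + ".fam"

    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"], dtype=str,
    )
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "vid", "cm", "pos", "a1", "a2"], dtype=str,
    )
    n, m = len(fam_df), len(bim_df)

    with open(bed, "rb") as fh:
        raw = fh.read()
    if raw[:2] != _BED_MAGIC[:2]:
        raise PlinkFormatError(f"{bed}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_MAGIC[2:3]:
        raise PlinkFormatError(f"{bed}: not variant-major (mode byte {raw[2:3]!r})")
    bytes_per_variant = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != bytes_per_variant * m:
        raise PlinkFormatError(
            f"{bed}: payload of {payload.size} bytes does not match "
            f"{m} variants x {bytes_per_variant} bytes"
        )
    blocks = payload.reshape(m, bytes_per_variant)
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T.copy()  # n x m

    flipped = np.zeros(m, dtype=bool)
    with np.errstate(invalid="ignore"):
        af = np.nanmean(dosages, axis=0) / 2.0
    flip = af > 0.5
    dosages[:, flip] = 2.0 - dosages[:, flip]
    flipped[flip] = True
    a1 = bim_df["a1"].tolist()
    a2 = bim_df["a2"].tolist()
    for j in np.where(flip)[0]:
        a1[j], a2[j] = a2[j], a1[j]

    return GenotypeMatrix(
        dosages,
        fam_df["iid"].tolist(),
        bim_df["vid"].tolist(),
        bim_df["chrom"].to_numpy(),
        bim_df["pos"].astype(int).to_numpy(),
        a1,
        a2,
        flipped,
    )


def write_plink(gm: GenotypeMatrix, prefix: str) -> None:
    """Write a GenotypeMatrix as bed/bim/fam (variant-major)."""
    n, m = gm.n, gm.m
    with open(prefix + ".fam", "w") as fh:
        for sid in gm.sample_ids:
            fh.write(f"{sid} {sid} 0 0 0 -9\n")
    with open(prefix + ".bim", "w") as fh:
        for j in range(m):
            fh.write(
                f"{gm.chrom[j]}\t{gm.variant_ids[j]}\t0\t{gm.pos[j]}"
                f"\t{gm.a1[j]}\t{gm.a2[j]}\n"
            )
    # dosage -> 2-bit code
    d = gm.dosages
    codes = np.full(d.shape, 1, dtype=np.uint8)  # missing
    codes[d == 2] = 0
    codes[d == 1] = 2
    codes[d == 0] = 3
    bytes_per_variant = (n + 3) // 4
    padded = np.ones((m, bytes_per_variant * 4), dtype=np.uint8) * 3  # pad homozygous A2
    padded[:, :n] = codes.T
    blocks = np.zeros((m, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        blocks |= padded[:, k::4] << (2 * k)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(blocks.tobytes())


def read_table(path: str, required: list[str] | None = None) -> pd.DataFrame:
    """Read a headered TSV with "NA" as the missing token; validates the
    required columns."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    if required:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_sample_table(
    pheno_path: str, covar_path: str, sample_ids: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phenotype and covariate tables keyed and aligned by sample id.

    Rows are reindexed to the genotype sample order; unknown sample ids
    in either table raise with the offending ids listed.
    """
    pheno = read_table(pheno_path, ["sample_id"]).set_index("sample_id")
    covar = read_table(covar_path, ["sample_id"]).set_index("sample_id")
    for name, df in (("phenotype", pheno), ("covariate", covar)):
        if df.index.duplicated().any():
            raise ValueError(f"{name} table has duplicated sample ids")
        unknown = sorted(set(df.index) - set(sample_ids))
        if unknown:
            raise ValueError(f"{name} table has unknown sample ids: {unknown[:10]}")
    return pheno.reindex(sample_ids), covar.reindex(sample_ids)


RESULT_COLUMNS = [
    "phenotype", "gene_id", "category", "test_type", "n_variants",
    "n_carriers", "score_stat", "score_p", "rlrt_stat", "rlrt_p",
    "combined_p", "final_p", "lrt_triggered", "significant", "lambda_group",
]


def write_results(df: pd.DataFrame, path: str) -> None:
    """Write the results table with a stable schema and row order.

    p-values use scientific notation with 6 significant digits.
    """
    out = df.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS].sort_values(
        ["phenotype", "gene_id", "category", "test_type"], kind="mergesort"
    )
    float_cols = [
        "score_stat", "score_p", "rlrt_stat", "rlrt_p", "combined_p",
        "final_p", "lambda_group",
    ]
    for col in float_cols:
        out[col] = out[col].map(
            lambda x: "NA" if pd.isna(x) else f"{x:.6e}"
        )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")
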