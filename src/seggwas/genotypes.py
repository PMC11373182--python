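"""SNP allele-count matrices and PLINK / TSV input-output.

Genotypes are stored as a float matrix of counted-allele dosages
(0/1/2, ``NaN`` for missing) with per-SNP metadata (id, chromosome,
position, counted allele).  Counts always refer to the file's counted
allele (PLINK A1, or the column's allele in a TSV); the sign of a
regression coefficient therefore depends on that orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class GenotypeError(ValueError):
    """Invalid genotype matrix or file."""


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele counts with per-SNP metadata."""

    ids: list[str]
    counts: np.ndarray                       # (n, p) float, NaN = missing
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)
    # snps columns: snp, chrom, pos, allele

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise GenotypeError("counts must be a 2-D matrix")
        n, p = self.counts.shape
        if len(self.ids) != n:
            raise GenotypeError(f"{len(self.ids)} ids for {n} genotype rows")
        if self.snps.empty:
            self.snps = pd.DataFrame({
                "snp": [f"snp{j}" for j in range(p)],
                "chrom": ["1"] * p, "pos": np.arange(1, p + 1),
                "allele": ["A"] * p})
        if len(self.snps) != p:
            raise GenotypeError(f"{len(self.snps)} SNP records for {p} columns")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise GenotypeError("allele counts must be 0, 1, 2 or missing")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def subset_individuals(self, ids: Sequence[str]) -> "GenotypeMatrix":
        index = {ident: i for i, ident in enumerate(self.ids)}
        missing = [i for i in ids if i not in index]
        if missing:
            raise GenotypeError(f"ids not genotyped (first: {missing[0]!r})")
        rows = [index[i] for i in ids]
        return GenotypeMatrix(list(ids), self.counts[rows], self.snps.copy())

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.ids), self.counts[:, mask],
                              self.snps.loc[mask].reset_index(drop=True))

    def allele_frequencies(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.counts, axis=0) / 2.0

    def call_rates(self) -> np.ndarray:
        return 1.0 - np.isnan(self.counts).mean(axis=0)


# --------------------------------------------------------------------------
# TSV fallback format: `id` column plus one 0/1/2/NA column per SNP
# --------------------------------------------------------------------------

def read_genotypes_tsv(path: str | Path,
                       snp_info: pd.DataFrame | None = None) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise GenotypeError(f"{path}: missing 'id' column")
    ids = df["id"].tolist()
    body = df.drop(columns="id")
    counts = body.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    if snp_info is None:
        p = counts.shape[1]
        snp_info = pd.DataFrame({"snp": body.columns, "chrom": ["1"] * p,
                                 "pos": np.arange(1, p + 1), "allele": ["A"] * p})
    return GenotypeMatrix(ids, counts, snp_info.reset_index(drop=True))


def write_genotypes_tsv(gm: GenotypeMatrix, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(gm.snps["snp"].astype(str)) + "\n")
        for i, ident in enumerate(gm.ids):
            row = ["NA" if np.isnan(c) else str(int(c)) for c in gm.counts[i]]
            fh.write(ident + "\t" + "\t".join(row) + "\n")


# --------------------------------------------------------------------------
# PLINK bed/bim/fam (SNP-major bed)
# --------------------------------------------------------------------------

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit codes in SNP-major bed, counting the A1 allele
_BED_DECODE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a PLINK ``prefix.bed/.bim/.fam`` trio (SNP-major bed).

    The counted allele is A1 (the fifth .bim column).
    """
    prefix = Path(prefix)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "phen"],
                      dtype=str)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=["chrom", "snp", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    n = len(fam)
    p = len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeError(f"{prefix}.bed: not a SNP-major PLINK bed file")
    bps = (n + 3) // 4  # bytes per SNP
    body = raw[3:]
    if body.size != bps * p:
        raise GenotypeError(f"{prefix}.bed: size mismatch "
                            f"({body.size} bytes for {n} x {p})")
    blocks = body.reshape(p, bps)
    codes = np.empty((p, bps * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0x3
    counts = _BED_DECODE[codes[:, :n]].T  # (n, p)
    snps = pd.DataFrame({"snp": bim["snp"], "chrom": bim["chrom"],
                         "pos": bim["pos"].astype(int), "allele": bim["a1"]})
    return GenotypeMatrix(fam["iid"].tolist(), counts, snps)


def write_plink(gm: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a SNP-major bed/bim/fam trio (A1 = counted allele)."""
    prefix = Path(prefix)
    n, p = gm.counts.shape
    with prefix.with_suffix(".fam").open("w", encoding="utf-8") as fh:
        for ident in gm.ids:
            fh.write(f"{ident} {ident} 0 0 0 -9\n")
    with prefix.with_suffix(".bim").open("w", encoding="utf-8") as fh:
        for _, row in gm.snps.iterrows():
            allele = row.get("allele", "A")
            fh.write(f"{row['chrom']} {row['snp']} 0 {int(row['pos'])} "
                     f"{allele} {'B' if allele == 'A' else 'A'}\n")
    code = np.full(gm.counts.shape, 1, dtype=np.uint8)  # missing
    code[gm.counts == 2.0] = 0
    code[gm.counts == 1.0] = 2
    code[gm.counts == 0.0] = 3
    bps = (n + 3) // 4
    padded = np.ones((p, bps * 4), dtype=np.uint8)
    padded[:, :n] = code.T
    packed = np.zeros((p, bps), dtype=np.uint8)
    for k in range(4):
        packed |= (padded[:, k::4] & 0x3) << (2 * k)
    with prefix.with_suffix(".bed").open("wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_genotypes(path_or_prefix: str | Path) -> GenotypeMatrix:
    """Dispatch on extension: ``.tsv`` fallback, else a PLINK prefix."""
    path = Path(path_or_prefix)
    if path.suffix in (".tsv", ".txt"):
        return read_genotypes_tsv(path)
    if path.suffix == ".bed":
        path = path.with_suffix("")
    return read_plink(path)
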