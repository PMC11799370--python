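"""Genotype and phenotype file formats.

Two genotype dialects are supported:

* PLINK binary (``.bed`` + ``.bim`` + ``.fam``), SNP-major, with the
  usual 2-bit genotype codes.  Dosage counts the A1 allele of the
  ``.bim`` record (00 = A1/A1 -> 2, 10 = het -> 1, 11 = A2/A2 -> 0,
  01 = missing).
* A plain-text dosage table: TSV with a ``sample_id`` column followed by
  one column per SNP, entries in {0, 1, 2, NA}.  SNP metadata travels in
  a sidecar ``<stem>.snps.tsv`` when written by this package.

Both round-trip bit-exactly, including missing entries.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .types import GenotypeMatrix, PHENO_COLUMNS, validate_phenotypes

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code per dosage of the counted (A1) allele; 1 encodes missing.
_DOSAGE_TO_CODE = {2.0: 0, 1.0: 2, 0.0: 3}
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """Malformed genotype file."""


def _ext(prefix: Path, ext: str) -> Path:
    # keep dots in the stem intact (Path.with_suffix would eat them)
    return Path(f"{prefix}.{ext}")


def write_plink(geno: GenotypeMatrix, prefix: str | Path) -> None:
    """Write ``prefix``.bed/.bim/.fam (SNP-major binary dialect)."""
    prefix = Path(prefix)
    n, p = geno.n_samples, geno.n_snps

    bim = geno.snps
    with open(_ext(prefix, "bim"), "w") as fh:
        for _, row in bim.iterrows():
            cm = row["cm"] if "cm" in bim.columns else 0
            fh.write(
                f"{row['chrom']}\t{row['snp_id']}\t{cm}\t{row['pos']}"
                f"\t{row['a1']}\t{row['a2']}\n"
            )
    with open(_ext(prefix, "fam"), "w") as fh:
        for sid in geno.sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")

    codes = np.full((p, n), 1, dtype=np.uint8)  # default: missing
    dos = geno.dosages.T
    for value, code in _DOSAGE_TO_CODE.items():
        codes[dos == value] = code
    n_bytes = (n + 3) // 4
    padded = np.zeros((p, 4 * n_bytes), dtype=np.uint8)
    padded[:, :n] = codes
    quads = padded.reshape(p, n_bytes, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink(prefix: str | Path) -> GenotypeMatrix:
    """Read a ``.bed``/``.bim``/``.fam`` triple into a dosage matrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, "bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        _ext(prefix, "fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n, p = len(fam), len(bim)
    raw = Path(_ext(prefix, "bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(
            f"{_ext(prefix, 'bed')}: bad magic bytes {raw[:3].hex()}"
        )
    n_bytes = (n + 3) // 4
    expected = 3 + p * n_bytes
    if len(raw) != expected:
        raise FormatError(
            f"{_ext(prefix, 'bed')}: expected {expected} bytes, "
            f"got {len(raw)} (truncation at offset {min(len(raw), expected)})"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(p, n_bytes)
    quads = np.stack(
        [packed & 0b11, (packed >> 2) & 0b11, (packed >> 4) & 0b11, packed >> 6],
        axis=2,
    ).reshape(p, 4 * n_bytes)
    dosages = _CODE_TO_DOSAGE[quads[:, :n]].T
    snps = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return GenotypeMatrix(
        dosages=dosages, snps=snps, sample_ids=fam["iid"].tolist()
    )


def write_text_dosage(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write the text dosage dialect plus a ``<stem>.snps.tsv`` sidecar."""
    path = Path(path)
    df = pd.DataFrame(geno.dosages, columns=geno.snps["snp_id"])
    df.insert(0, "sample_id", geno.sample_ids)
    with np.errstate(invalid="ignore"):
        df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.0f")
    geno.snps[["snp_id", "chrom", "pos", "a1", "a2"]].to_csv(
        path.with_suffix(".snps.tsv"), sep="\t", index=False
    )


def read_text_dosage(path: str | Path) -> GenotypeMatrix:
    """Read the text dosage dialect; 'NA' entries stay missing.

    SNP metadata is taken from the sidecar ``<stem>.snps.tsv`` when
    present; otherwise placeholder coordinates are assigned in column
    order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: first column must be 'sample_id'")
    snp_ids = [c for c in df.columns if c != "sample_id"]
    sidecar = path.with_suffix(".snps.tsv")
    if sidecar.exists():
        snps = pd.read_csv(sidecar, sep="\t", dtype={"snp_id": str})
        snps = snps.set_index("snp_id").loc[snp_ids].reset_index()
    else:
        snps = pd.DataFrame(
            {
                "snp_id": snp_ids,
                "chrom": 0,
                "pos": np.arange(1, len(snp_ids) + 1),
                "a1": "A",
                "a2": "G",
            }
        )
    return GenotypeMatrix(
        dosages=df[snp_ids].to_numpy(dtype=float),
        snps=snps,
        sample_ids=df["sample_id"].tolist(),
    )


def read_genotypes(path: str | Path, dialect: str = "plink_bed") -> GenotypeMatrix:
    """Dispatch on dialect: ``plink_bed`` (path = file prefix) or
    ``text_dosage`` (path = TSV file)."""
    if dialect == "plink_bed":
        return read_plink(path)
    if dialect == "text_dosage":
        return read_text_dosage(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_phenotypes(pheno: pd.DataFrame, path: str | Path) -> None:
    validate_phenotypes(pheno)
    pheno[PHENO_COLUMNS + [c for c in pheno.columns if c not in PHENO_COLUMNS]].to_csv(
        path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    pheno = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_phenotypes(pheno)
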