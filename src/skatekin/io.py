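"""Readers and writers for the pipeline's file formats.

Genotypes travel as CSV (rows = individuals, columns = loci, calls
0/1/2, empty = missing) or as biallelic-SNP VCF (read via cyvcf2; a
minimal text VCF writer is provided for export).  Metadata is a CSV with
id, year, sex, length and optional coordinates/station.  Every artifact
directory can carry a JSON manifest recording the configuration and
seed that produced it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Read a genotype matrix from CSV or VCF (biallelic SNPs only)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() in (".vcf", ".bcf", ".gz") else "csv"
    if fmt == "csv":
        return _read_genotypes_csv(path)
    if fmt == "vcf":
        return _read_genotypes_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_genotypes_csv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, index_col=0)
    arr = df.to_numpy()
    calls = np.full(arr.shape, MISSING, dtype=np.int8)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            v = arr[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            try:
                iv = int(v)
            except (TypeError, ValueError):
                iv = -99
            if iv not in (0, 1, 2):
                raise ValueError(
                    f"{path}: invalid call {v!r} at sample "
                    f"{df.index[i]!r} (row {i + 2}), locus {df.columns[j]!r}")
            calls[i, j] = iv
    return GenotypeMatrix(calls, df.index.to_numpy(object),
                          df.columns.to_numpy(object))


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    loci, cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            raise ValueError(f"{path}: non-biallelic-SNP record at "
                             f"{rec.CHROM}:{rec.POS}")
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = rec.gt_types
        col = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], MISSING)
        cols.append(col.astype(np.int8))
        loci.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    if not cols:
        raise ValueError(f"{path}: no usable records")
    return GenotypeMatrix(np.stack(cols, axis=1), samples,
                          np.array(loci, dtype=object))


def write_genotypes(gm: GenotypeMatrix, path) -> None:
    df = gm.to_frame()
    df.to_csv(path, float_format="%.0f")


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal biallelic-SNP VCF export (placeholder REF/ALT alleles)."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##contig=<ID=1>\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(map(str, gm.samples)) + "\n")
        for j, locus in enumerate(gm.loci):
            gts = "\t".join(gt_map[int(g)] for g in gm.calls[:, j])
            fh.write(f"1\t{j + 1}\t{locus}\tA\tC\t.\tPASS\t.\tGT\t{gts}\n")


_SEXES = {"M", "F", "unknown"}


def read_metadata(path) -> pd.DataFrame:
    """Sample metadata with validation; errors name the offending record."""
    df = pd.read_csv(path)
    required = {"id", "year", "sex", "length"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    df["sex"] = df["sex"].fillna("unknown")
    for i, row in df.iterrows():
        if row["sex"] not in _SEXES:
            raise ValueError(f"{path}: sample {row['id']!r}: sex "
                             f"{row['sex']!r} not in {sorted(_SEXES)}")
        if not row["length"] > 0:
            raise ValueError(f"{path}: sample {row['id']!r}: length "
                             f"{row['length']} must be > 0")
        if not 1900 <= int(row["year"]) <= 2100:
            raise ValueError(f"{path}: sample {row['id']!r}: implausible "
                             f"year {row['year']}")
        if "lat" in df.columns and not -90 <= row["lat"] <= 90:
            raise ValueError(f"{path}: sample {row['id']!r}: latitude "
                             f"{row['lat']} out of range")
        if "lon" in df.columns and not -180 <= row["lon"] <= 180:
            raise ValueError(f"{path}: sample {row['id']!r}: longitude "
                             f"{row['lon']} out of range")
    return df


def write_manifest(path, **payload) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        return str(o)

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
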