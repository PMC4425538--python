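"""Readers and writers for the tab-separated and VCF interchange formats.

All tabular formats are plain TSV:

* expression — first column ``probe_id``, remaining columns one per sample;
* dosages — first column ``snp_id``, values are additive dosages in [0, 2];
* cell counts — long format with columns ``sample_id``, ``cell_type``,
  ``percentage``;
* GWAS table — columns ``snp_id``, ``trait``, ``p``;
* r² table — columns ``snp_a``, ``snp_b``, ``r2``.

VCF output is v4.2 with a ``DS`` (alternate-allele dosage) FORMAT field and a
hard-called ``GT`` derived by rounding; VCF input is parsed with cyvcf2 and
prefers ``DS``, falling back to counting alternate alleles in ``GT``.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, GenotypeMatrix

logger = logging.getLogger("ctqtl")

__all__ = [
    "read_expression",
    "write_expression",
    "read_dosages",
    "write_dosages",
    "read_vcf",
    "write_vcf",
    "read_genotypes",
    "read_cell_counts",
    "write_cell_counts",
    "read_gwas",
    "read_r2_table",
    "write_r2_table",
]


def _read_feature_matrix(path: str | Path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pragma: no cover - message wrapping
        raise ValueError(f"{path}: cannot parse as TSV ({exc})") from exc
    if df.shape[1] == 0:
        raise ValueError(f"{path}: malformed header — no sample columns found")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate {index_name} {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample identifier {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        row, col = np.argwhere(bad.to_numpy())[0]
        # +2: one for the header line, one for 1-based numbering
        raise ValueError(
            f"{path}: non-numeric value {df.iat[row, col]!r} at line {row + 2}, "
            f"column {df.columns[col]!r}"
        )
    numeric.index.name = index_name
    return numeric.astype(float)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a probes x samples expression TSV."""
    return ExpressionMatrix(values=_read_feature_matrix(path, "probe_id"))


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.rename_axis("probe_id").to_csv(path, sep="\t", float_format="%.10g")


def read_dosages(path: str | Path) -> GenotypeMatrix:
    """Read a SNPs x samples dosage TSV (additive coding, values in [0, 2])."""
    return GenotypeMatrix(values=_read_feature_matrix(path, "snp_id"))


def write_dosages(geno: GenotypeMatrix, path: str | Path) -> None:
    geno.values.rename_axis("snp_id").to_csv(path, sep="\t", float_format="%.10g")


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write a VCFv4.2 file with GT (rounded) and DS (exact dosage) fields."""
    info = geno.snp_info
    samples = geno.sample_ids
    lines = [
        "##fileformat=VCFv4.2",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">',
        "##contig=<ID=1>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    for i, snp in enumerate(geno.snp_ids):
        if info is not None:
            chrom = str(info.iloc[i]["chrom"])
            pos = int(info.iloc[i]["pos"])
            ref, alt = str(info.iloc[i]["ref"]), str(info.iloc[i]["alt"])
        else:
            chrom, pos, ref, alt = "1", i + 1, "A", "G"
        fields = []
        for d in geno.values.iloc[i].to_numpy():
            if np.isnan(d):
                fields.append("./.:.")
            else:
                fields.append(f"{gt_codes[int(round(d))]}:{d:.9g}")
        lines.append(
            f"{chrom}\t{pos}\t{snp}\t{ref}\t{alt}\t.\t.\t.\tGT:DS\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read genotypes from VCF; uses DS when present, otherwise counts GT alleles."""
    from cyvcf2 import VCF

    path = str(path)
    vcf = VCF(path)
    samples = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    meta: list[tuple[str, int, str, str]] = []
    for variant in vcf:
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ds = None
        try:
            ds = variant.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            dosage = np.asarray(ds, dtype=float).reshape(-1)
            dosage = np.where(dosage < -0.5, np.nan, dosage)
        else:
            gts = variant.genotypes  # [allele0, allele1, phased]
            dosage = np.array(
                [np.nan if g[0] < 0 or g[1] < 0 else float(g[0] + g[1]) for g in gts]
            )
        snp_ids.append(snp_id)
        rows.append(dosage)
        meta.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0] if variant.ALT else "."))
    vcf.close()
    if not snp_ids:
        raise ValueError(f"{path}: VCF contains no variant records")
    index = pd.Index(snp_ids, name="snp_id")
    values = pd.DataFrame(np.vstack(rows), index=index, columns=samples)
    info = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"], index=index)
    return GenotypeMatrix(values=values, snp_info=info)


def read_genotypes(path: str | Path, format: str = "dosage") -> GenotypeMatrix:
    """Dispatch on declared format: ``dosage`` TSV or ``vcf``."""
    if format == "dosage":
        return read_dosages(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r} (expected 'dosage' or 'vcf')")


def read_cell_counts(path: str | Path) -> pd.DataFrame:
    """Read a long-format cell-count TSV (sample_id, cell_type, percentage)."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "cell_type", "percentage"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: malformed header — expected columns {sorted(required)}, got {list(df.columns)}"
        )
    df["percentage"] = pd.to_numeric(df["percentage"], errors="raise")
    if df.duplicated(["sample_id", "cell_type"]).any():
        dup = df.loc[df.duplicated(["sample_id", "cell_type"]), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate (sample, cell_type) entry for {dup!r}")
    return df


def write_cell_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gwas(path: str | Path) -> pd.DataFrame:
    """Read a GWAS association table (snp_id, trait, p).

    Duplicate (snp, trait) rows are collapsed to the minimum p-value.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"snp_id", "trait", "p"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: malformed header — expected columns {sorted(required)}, got {list(df.columns)}"
        )
    df["p"] = pd.to_numeric(df["p"], errors="raise")
    if ((df["p"] <= 0) | (df["p"] > 1)).any():
        bad = df.loc[(df["p"] <= 0) | (df["p"] > 1)].index[0]
        raise ValueError(f"{path}: association p out of (0, 1] at data line {bad + 2}")
    n_before = len(df)
    df = df.groupby(["snp_id", "trait"], as_index=False)["p"].min()
    if len(df) < n_before:
        logger.info("collapsed %d duplicate (snp, trait) rows", n_before - len(df))
    return df


def read_r2_table(path: str | Path) -> dict[frozenset, float]:
    """Read a pairwise LD table into a symmetric lookup."""
    df = pd.read_csv(path, sep="\t")
    required = {"snp_a", "snp_b", "r2"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: malformed header — expected columns {sorted(required)}")
    lookup: dict[frozenset, float] = {}
    for snp_a, snp_b, r2 in df[["snp_a", "snp_b", "r2"]].itertuples(index=False):
        r2 = float(r2)
        if not 0 <= r2 <= 1:
            raise ValueError(f"{path}: r2 value {r2} outside [0, 1]")
        lookup[frozenset((snp_a, snp_b))] = r2
    return lookup


def write_r2_table(lookup: dict[frozenset, float], path: str | Path) -> None:
    rows = [(*sorted(pair), r2) for pair, r2 in lookup.items()]
    pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).sort_values(
        ["snp_a", "snp_b"]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")
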