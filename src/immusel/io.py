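"""Readers and writers for the plain-text interchange formats.

VCF v4.2 (SNPs with GT fields), BED intervals, and the counts-matrix TSV
(header: gene_id, effective_length, then sample columns). FASTA and newick
live with their containers (CodonAlignment, Phylogeny).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=SAF,Number=1,Type=Integer,Description="Alt reads on forward strand">
##INFO=<ID=SAR,Number=1,Type=Integer,Description="Alt reads on reverse strand">
##INFO=<ID=RPL,Number=1,Type=Integer,Description="Reads placed left of variant">
##INFO=<ID=RPR,Number=1,Type=Integer,Description="Reads placed right of variant">
##INFO=<ID=AB,Number=1,Type=Float,Description="Allele balance in heterozygotes">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(variants: pd.DataFrame, path, sample_names=None) -> None:
    """Write a VariantTable data frame as uncompressed VCF v4.2."""
    if len(variants):
        n_samples = len(np.atleast_1d(variants.iloc[0]["genotypes"]))
    else:
        n_samples = 0
    if sample_names is None:
        sample_names = [f"ind{i + 1:02d}" for i in range(n_samples)]
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        for _, row in variants.iterrows():
            info = (
                f"SAF={int(row['SAF'])};SAR={int(row['SAR'])};"
                f"RPL={int(row['RPL'])};RPR={int(row['RPR'])};"
                f"AB={row['allele_balance']:.3f}"
            )
            gts = "\t".join(_GT[int(g)] for g in np.atleast_1d(row["genotypes"]))
            fh.write(
                f"{row['scaffold']}\t{int(row['pos'])}\t.\t{row['ref']}\t"
                f"{row['alt']}\t{row['qual']:.1f}\tPASS\t{info}\tGT\t{gts}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Read an uncompressed VCF into the VariantTable layout used by the
    filter cascade (missing INFO keys become NaN and are dropped by the
    filters with a logged reason)."""
    from cyvcf2 import VCF

    rows = []
    vcf = VCF(str(path), gts012=True)
    for v in vcf:
        geno = np.asarray(v.gt_types, dtype=int)
        geno = np.where(geno == 3, -1, geno)  # cyvcf2: 3 = unknown
        rows.append(
            {
                "scaffold": v.CHROM,
                "pos": v.POS,
                "ref": v.REF,
                "alt": v.ALT[0] if v.ALT else None,
                "qual": v.QUAL,
                "SAF": v.INFO.get("SAF"),
                "SAR": v.INFO.get("SAR"),
                "RPL": v.INFO.get("RPL"),
                "RPR": v.INFO.get("RPR"),
                "allele_balance": v.INFO.get("AB"),
                "genotypes": geno,
                "biallelic_snp": len(v.ALT) == 1
                and len(v.REF) == 1
                and all(len(a) == 1 for a in v.ALT),
            }
        )
    return pd.DataFrame(rows)


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals[["scaffold", "start", "end"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["scaffold", "start", "end"],
    )


def write_counts_tsv(matrix, path) -> None:
    """Counts TSV with header gene_id, effective_length, sample columns.
    The single effective_length column carries the per-gene mean."""
    df = matrix.counts.copy()
    df.insert(0, "effective_length", matrix.effective_lengths.mean(axis=1))
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_counts_tsv(path, sample_map: pd.DataFrame):
    """Read a counts TSV plus a sample map (columns: sample, tissue[, sex])
    into an ExpressionMatrix."""
    from .expression import ExpressionMatrix

    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    df.index.name = None
    lengths = df.pop("effective_length")
    tissue = dict(zip(sample_map["sample"], sample_map["tissue"]))
    sex = (
        dict(zip(sample_map["sample"], sample_map["sex"]))
        if "sex" in sample_map
        else {}
    )
    lengths_df = pd.DataFrame(
        np.tile(lengths.values[:, None], (1, df.shape[1])),
        index=df.index, columns=df.columns,
    )
    return ExpressionMatrix(
        counts=df, effective_lengths=lengths_df,
        sample_tissue=tissue, sample_sex=sex,
    )


def write_sample_map(sample_tissue: dict, path, sample_sex: dict | None = None):
    df = pd.DataFrame(
        {"sample": list(sample_tissue), "tissue": list(sample_tissue.values())}
    )
    if sample_sex:
        df["sex"] = [sample_sex.get(s, "unknown") for s in df["sample"]]
    df.to_csv(path, sep="\t", index=False)
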