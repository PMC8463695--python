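"""VCF round-trip I/O for genotype datasets.

Datasets are written as GT-only VCFv4.2 with the gene assignment and the
private flag stored in INFO keys (``GENE``, ``PRIVATE``), plus a sidecar
tab-delimited sample table (``sample_id``, ``subpop``).  Reading goes
through cyvcf2 and accepts only biallelic records; genotypes are returned
as ALT-allele dosage so that a write/read cycle reproduces the matrix
exactly (minor-allele folding is applied downstream where frequencies are
needed).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .dataset import MISSING, GenotypeDataset

__all__ = ["write_vcf", "read_vcf", "default_metadata_path"]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene assignment">
##INFO=<ID=PRIVATE,Number=1,Type=Integer,Description="1 if the variant is private (single carrier)">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def default_metadata_path(vcf_path: str) -> str:
    return str(vcf_path) + ".samples.tsv"


def write_vcf(dataset: GenotypeDataset, path: str, metadata_path: str | None = None) -> None:
    """Write ``dataset`` as an uncompressed VCF plus a sample sidecar table."""
    if metadata_path is None:
        metadata_path = default_metadata_path(path)
    v = dataset.variants
    chrom = v["chrom"].astype(str) if "chrom" in v else pd.Series(["1"] * len(v))
    pos = v["pos"] if "pos" in v else pd.Series(np.arange(1, len(v) + 1) * 100)
    ref = v["ref"] if "ref" in v else pd.Series(["A"] * len(v))
    alt = v["alt"] if "alt" in v else pd.Series(["G"] * len(v))

    with open(path, "w") as fh:
        fh.write(_HEADER)
        for contig in dict.fromkeys(chrom):  # unique, order-preserving
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(map(str, dataset.sample_ids))
            + "\n"
        )
        g = dataset.genotypes
        for j in range(dataset.n_variants):
            info = f"GENE={v['gene'].iloc[j]};PRIVATE={int(bool(v['private'].iloc[j]))}"
            gts = "\t".join(_GT_STRINGS[int(x)] for x in g[:, j])
            fh.write(
                f"{chrom.iloc[j]}\t{int(pos.iloc[j])}\t{v['variant_id'].iloc[j]}\t"
                f"{ref.iloc[j]}\t{alt.iloc[j]}\t.\t.\t{info}\tGT\t{gts}\n"
            )

    meta = pd.DataFrame({"sample_id": dataset.sample_ids, "subpop": dataset.subpop_labels})
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_vcf(path: str, metadata_path: str | None = None) -> GenotypeDataset:
    """Read a GT-only biallelic VCF and its sample sidecar table.

    Raises
    ------
    ValueError
        On a multiallelic record (named in the message) or when the sample
        sets of the VCF and the metadata table disagree.
    FileNotFoundError
        If either file is missing.
    """
    if metadata_path is None:
        metadata_path = default_metadata_path(path)
    if not os.path.exists(metadata_path):
        raise FileNotFoundError(f"sample metadata table not found: {metadata_path}")

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples)
    n = len(samples)

    columns: list[np.ndarray] = []
    records: list[dict] = []
    for rec in vcf:
        name = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if len(rec.ALT) != 1:
            raise ValueError(f"multiallelic record {name} ({rec.CHROM}:{rec.POS}); biallelic only")
        dosage = np.full(n, MISSING, dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                continue
            if a1 > 1 or a2 > 1:
                raise ValueError(f"record {name} has an allele index > 1; biallelic only")
            dosage[i] = a1 + a2
        columns.append(dosage)
        info_private = rec.INFO.get("PRIVATE")
        records.append(
            {
                "variant_id": name,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
                "gene": rec.INFO.get("GENE") or "NA",
                "private": bool(int(info_private)) if info_private is not None else False,
            }
        )
    vcf.close()

    genotypes = (
        np.column_stack(columns) if columns else np.empty((n, 0), dtype=np.int8)
    )
    variants = pd.DataFrame(
        records,
        columns=["variant_id", "chrom", "pos", "ref", "alt", "gene", "private"],
    )

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample_id" not in meta.columns or "subpop" not in meta.columns:
        raise ValueError("metadata table must have 'sample_id' and 'subpop' columns")
    if set(meta["sample_id"]) != set(samples):
        raise ValueError("sample mismatch between VCF and metadata table")
    meta = meta.set_index("sample_id").loc[samples]

    return GenotypeDataset(
        genotypes=genotypes,
        sample_ids=samples,
        subpop_labels=meta["subpop"].to_numpy(),
        variants=variants,
    )
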