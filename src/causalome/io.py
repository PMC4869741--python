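"""Readers and writers for the pipeline's file formats.

Tabular layers travel as TSV with a header row, the sample id in the
first column and an explicit missing-value token (default ``NA``).
Genotypes can also travel as minimal VCF (biallelic SNPs, GT field,
1-based positions), read back through cyvcf2.  Ground truth is JSON.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, MetaboliteMatrix, PhenotypeTable
from .simulate import GroundTruth, SimulatedStudy

NA_TOKEN = "NA"

__all__ = [
    "read_table",
    "write_table",
    "write_vcf",
    "read_vcf",
    "read_dosage_tsv",
    "write_study",
    "load_phenotypes",
]


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", na_rep=NA_TOKEN, index=True)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=[NA_TOKEN], index_col=0)


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Minimal VCF 4.2: biallelic SNPs, GT-only FORMAT."""
    gt_code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##contig=<ID=1>\n")
        samples = "\t".join(g.sample_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        dos = g.dosages.to_numpy(float)
        for j, vid in enumerate(g.variant_ids):
            rec = g.variants.loc[vid]
            calls = "\t".join(
                "./." if np.isnan(d) else gt_code[d] for d in dos[:, j]
            )
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{vid}\t{rec['ref']}\t{rec['alt']}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a (possibly uncompressed) VCF into additive ALT dosages."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            continue  # biallelic SNPs only
        dos = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            dos[i] = np.nan if a < 0 or b < 0 else float(a + b)
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        ids.append(vid)
        rows.append(dos)
        meta.append((variant.CHROM, variant.POS, variant.REF, variant.ALT[0]))
    index = pd.Index(ids, name="variant_id")
    variants = pd.DataFrame(meta, columns=["chrom", "pos", "ref", "alt"], index=index)
    dosages = pd.DataFrame(
        np.array(rows).T, index=pd.Index(samples, name="sample_id"), columns=index
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    """Additive-coded alternative to VCF: samples x variants TSV."""
    dosages = read_table(path)
    variants = pd.DataFrame(
        {"chrom": "1", "pos": np.arange(1, dosages.shape[1] + 1), "ref": "A", "alt": "G"},
        index=dosages.columns.rename("variant_id"),
    )
    return GenotypeMatrix(dosages=dosages, variants=variants)


def load_phenotypes(visits_path: str, covariates_path: str | None = None) -> PhenotypeTable:
    visits = read_table(visits_path)
    cov = read_table(covariates_path) if covariates_path else pd.DataFrame(index=visits.index)
    return PhenotypeTable(visits=visits, covariates=cov)


def write_study(study: SimulatedStudy, out_dir: str, genotype_format: str = "vcf") -> None:
    """Materialise a simulated study as plain-text files."""
    os.makedirs(out_dir, exist_ok=True)
    if genotype_format == "vcf":
        write_vcf(study.genotypes, os.path.join(out_dir, "genotypes.vcf"))
    elif genotype_format == "tsv":
        write_table(study.genotypes.dosages, os.path.join(out_dir, "genotypes.tsv"))
    else:
        raise ValueError("genotype_format must be 'vcf' or 'tsv'")
    write_table(study.metabolites.values, os.path.join(out_dir, "metabolites.tsv"))
    write_table(study.phenotypes.visits, os.path.join(out_dir, "phenotypes.tsv"))
    write_table(study.covariates, os.path.join(out_dir, "covariates.tsv"))
    with open(os.path.join(out_dir, "truth.json"), "w") as fh:
        fh.write(study.truth.to_json())
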