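"""Plain-text readers and writers for the pipeline's tabular formats.

Everything is tab-separated text; genotypes can also round-trip through a
minimal VCF dialect whose per-sample ``DS`` field carries the imputed
effect-allele dosage (read back with cyvcf2).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genetics import GenotypeMatrix

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
]


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA")


def read_tsv(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA", index_col=index_col)


def write_genotypes_tsv(gm: GenotypeMatrix, dosage_path, snv_path) -> None:
    dos = gm.dosages.copy()
    dos.index.name = "individual"
    dos.reset_index().to_csv(dosage_path, sep="\t", index=False, na_rep="NA")
    snvs = gm.snvs.copy()
    snvs.index.name = "snv_id"
    snvs.reset_index().to_csv(snv_path, sep="\t", index=False, na_rep="NA")


def read_genotypes_tsv(dosage_path, snv_path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", na_values="NA").set_index("individual")
    snvs = pd.read_csv(snv_path, sep="\t", na_values="NA").set_index("snv_id")
    return GenotypeMatrix(dos, snvs)


def write_genotypes_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal sites+samples VCF with FORMAT DS (dosage) and INFO field
    ``INFO=<imputation quality>``; missing dosages written as '.'."""
    path = Path(path)
    samples = list(gm.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Estimated alternate allele dosage">\n')
        for i in range(1, 23):
            fh.write(f"##contig=<ID={i}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos0, snv in enumerate(gm.dosages.columns):
            rec = gm.snvs.loc[snv]
            # counted (a1) allele is written as ALT so DS counts it
            ds = gm.dosages[snv].to_numpy(dtype=float)
            vals = "\t".join("." if np.isnan(d) else f"{d:.3f}" for d in ds)
            fh.write(
                f"1\t{1000 + pos0}\t{snv}\t{rec['a2']}\t{rec['a1']}\t.\tPASS\t"
                f"INFO={float(rec['info']):.4f}\tDS\t{vals}\n")


def read_genotypes_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, a1, a2, info, rows = [], [], [], [], []
    for var in vcf:
        ids.append(var.ID)
        a1.append(var.ALT[0])
        a2.append(var.REF)
        info.append(float(var.INFO.get("INFO", np.nan)))
        ds = np.asarray(var.format("DS"), dtype=float).reshape(-1)
        # '.' entries come back as NaN or a sentinel; anything outside the
        # dosage domain is treated as missing
        ds = np.where(np.isfinite(ds) & (ds >= 0) & (ds <= 2), ds, np.nan)
        rows.append(ds)
    vcf.close()
    dos = pd.DataFrame(np.column_stack(rows), index=samples, columns=ids)
    snvs = pd.DataFrame({"a1": a1, "a2": a2, "info": info}, index=ids)
    return GenotypeMatrix(dos, snvs)
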