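"""Reading and writing genotype dosages as VCF 4.2 with a DS FORMAT field."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = ["write_vcf_dosages", "read_vcf_dosages"]


def _chrom_key(c: str) -> tuple[int, str]:
    try:
        return (int(c), "")
    except ValueError:
        return (99, str(c))


def write_vcf_dosages(genotypes: GenotypeMatrix, path: str) -> None:
    """Write dosages to an uncompressed VCF 4.2 (1-based positions, DS field).

    Variants are emitted coordinate-sorted; missing dosages become ``.``.
    """
    order = sorted(
        range(genotypes.n_variants),
        key=lambda j: (
            _chrom_key(genotypes.variants["chrom"].iat[j]),
            genotypes.variants["pos"].iat[j],
            genotypes.variants["variant_id"].iat[j],
        ),
    )
    chroms = []
    for j in order:
        c = str(genotypes.variants["chrom"].iat[j])
        if c not in chroms:
            chroms.append(c)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        if "imputation_r2" in genotypes.variants.columns:
            fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R2">\n')
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.subject_ids)
            + "\n"
        )
        has_r2 = "imputation_r2" in genotypes.variants.columns
        for j in order:
            v = genotypes.variants.iloc[j]
            info = f"R2={v['imputation_r2']:.4f}" if has_r2 else "."
            ds = genotypes.dosages[:, j]
            ds_str = "\t".join(
                "." if np.isnan(d) else f"{d:.3f}" for d in ds
            )
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{v['variant_id']}\t{v['ref']}\t"
                f"{v['alt']}\t.\tPASS\t{info}\tDS\t{ds_str}\n"
            )


def read_vcf_dosages(path: str) -> GenotypeMatrix:
    """Read a VCF with DS (preferred) or GT genotypes into a GenotypeMatrix."""
    from cyvcf2 import VCF

    vcf = VCF(path)
    subjects = np.array(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        ds = None
        try:
            arr = var.format("DS")
        except KeyError:
            arr = None
        if arr is not None:
            ds = np.asarray(arr, float).reshape(-1)
            ds[(ds < 0) | (ds > 2)] = np.nan
        else:
            gts = np.asarray(var.genotype.array())[:, :2]
            ds = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1)).astype(
                float
            )
        r2 = var.INFO.get("R2")
        rows.append(ds)
        meta.append(
            {
                "variant_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0] if var.ALT else ".",
                "imputation_r2": float(r2) if r2 is not None else np.nan,
            }
        )
    vcf.close()
    dosages = np.column_stack(rows) if rows else np.empty((subjects.size, 0))
    return GenotypeMatrix(dosages, pd.DataFrame(meta), subjects)
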