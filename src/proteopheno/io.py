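"""Readers and writers for the pipeline's plain-text interchange formats.

Formats: minimal VCF v4.2 (GT only), dosage TSV (variants x samples),
protein TSV (samples x aptamers), covariate TSV, GWAS summary TSV with
columns SNP, CHR, POS, A1, A2, FREQ, BETA, SE, P, N.  VCF reading goes
through cyvcf2; everything tabular goes through pandas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import GenotypeMatrix, ProteinMatrix

GWAS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]

_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotype fields."""
    samples = list(genotypes.dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        dos = genotypes.dosages.to_numpy().T  # variants x samples
        for i, (_, v) in enumerate(genotypes.variants.iterrows()):
            gts = "\t".join(
                "./." if np.isnan(d) else _GT_CODE[d] for d in dos[i]
            )
            fh.write(
                f"{v['chrom']}\t{v['pos']}\t{v['variant_id']}\t{v['ref']}\t{v['alt']}"
                f"\t.\t.\t.\tGT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a GT-only VCF back into a GenotypeMatrix (alt-allele dosage)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta = [], []
    for rec in vcf:
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        g = rec.gt_types.astype(float)
        dos = np.where(g == 3, 2.0, np.where(g == 2, np.nan, g))
        rows.append(dos)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        meta.append((vid, rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    variants = pd.DataFrame(
        meta, columns=["variant_id", "chrom", "pos", "ref", "alt"]
    ).set_index("variant_id", drop=False)
    dosages = pd.DataFrame(np.array(rows).T, index=samples, columns=variants.index)
    variants["maf"] = np.minimum(dosages.mean(axis=0) / 2.0, 1 - dosages.mean(axis=0) / 2.0)
    sample_tab = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    sample_tab["cohort"] = "unknown"
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=sample_tab)


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Dosage TSV: one row per variant, one column per sample."""
    out = genotypes.dosages.T
    out.index.name = "variant_id"
    out.to_csv(path, sep="\t", float_format="%.6g")


def read_dosage_tsv(path, variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    tab = pd.read_csv(path, sep="\t", index_col=0)
    dosages = tab.T
    if variants is None:
        ids = dosages.columns
        parts = ids.to_series().str.split(":", expand=True)
        variants = pd.DataFrame(
            {
                "variant_id": ids,
                "chrom": parts[0].to_numpy(),
                "pos": parts[1].astype(int).to_numpy(),
                "ref": parts[2].to_numpy(),
                "alt": parts[3].to_numpy(),
            }
        ).set_index("variant_id", drop=False)
    samples = pd.DataFrame(index=dosages.index)
    samples.index.name = "sample_id"
    samples["cohort"] = "unknown"
    return GenotypeMatrix(dosages=dosages, variants=variants, samples=samples)


def write_protein_tsv(proteins: ProteinMatrix | pd.DataFrame, path) -> None:
    """Protein TSV: samples x aptamers, header row of aptamer IDs."""
    values = proteins.values if isinstance(proteins, ProteinMatrix) else proteins
    values.index.name = "sample_id"
    values.to_csv(path, sep="\t", float_format="%.10g")


def read_protein_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_covariate_tsv(covariates: pd.DataFrame, path) -> None:
    covariates.index.name = "sample_id"
    covariates.to_csv(path, sep="\t")


def read_covariate_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_gwas_tsv(gwas: pd.DataFrame, path) -> None:
    missing = [c for c in GWAS_COLUMNS if c not in gwas.columns]
    if missing:
        raise ValueError(f"GWAS table missing columns {missing}")
    gwas[GWAS_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gwas_tsv(path) -> pd.DataFrame:
    tab = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in GWAS_COLUMNS if c not in tab.columns]
    if missing:
        raise ValueError(f"GWAS table missing columns {missing}")
    return tab
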