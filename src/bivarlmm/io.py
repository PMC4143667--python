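"""File formats: phenotype CSV, dosage TSV, minimal VCF, YAML configs.

Phenotypes travel as tidy CSV with the documented column set; genotypes as
either an additive-dosage TSV (subjects x SNPs, accompanied by a SNP
metadata TSV) or a minimal VCFv4.2 with GT genotypes (read back through
cyvcf2).  Configuration objects round-trip through YAML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .data import GenotypeMatrix, PHENOTYPE_COLUMNS, SNP_META_COLUMNS, validate_phenotypes
from .errors import InvalidParameterError
from .simulate import SimulationConfig

__all__ = [
    "read_phenotypes", "write_phenotypes",
    "read_genotypes_tsv", "write_genotypes_tsv",
    "read_vcf", "write_vcf",
    "read_config", "write_config",
]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    validate_phenotypes(df)
    df.to_csv(path, index=False, columns=list(PHENOTYPE_COLUMNS))


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_phenotypes(df)
    return df


def write_genotypes_tsv(gm: GenotypeMatrix, dosage_path, meta_path=None) -> None:
    """Dosage TSV: subject_id column + one 0/1/2 column per SNP (blank = missing)."""
    out = pd.DataFrame(gm.dosages, columns=gm.snp_ids)
    out.insert(0, "subject_id", gm.subjects)
    out.to_csv(dosage_path, sep="\t", index=False, float_format="%.0f")
    if meta_path is not None:
        gm.snps.to_csv(meta_path, sep="\t", index=False)


def read_genotypes_tsv(dosage_path, meta_path=None) -> GenotypeMatrix:
    df = pd.read_csv(dosage_path, sep="\t")
    if "subject_id" not in df.columns:
        raise InvalidParameterError("dosage TSV must have a subject_id column")
    subjects = df["subject_id"].to_numpy()
    dosages = df.drop(columns="subject_id").to_numpy(float)
    snp_ids = [c for c in df.columns if c != "subject_id"]
    if meta_path is not None:
        snps = pd.read_csv(meta_path, sep="\t")
        snps = snps[list(SNP_META_COLUMNS)]
    else:
        snps = pd.DataFrame(
            {"snp_id": snp_ids, "chrom": "0", "pos": np.arange(1, len(snp_ids) + 1),
             "minor_allele": "A", "major_allele": "G"}
        )
    return GenotypeMatrix(dosages, subjects, snps)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Minimal VCFv4.2 with GT genotypes; ALT is the minor allele.

    Dosage d = number of ALT (minor) copies: 0 -> 0/0, 1 -> 0/1, 2 -> 1/1,
    missing -> ./.
    """
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in gm.subjects) + "\n")
        for j in range(gm.n_snps):
            meta = gm.snps.iloc[j]
            gts = [
                gt_map.get(d, "./.") if not np.isnan(d) else "./."
                for d in gm.dosages[:, j]
            ]
            fh.write(
                f"{meta['chrom']}\t{int(meta['pos'])}\t{meta['snp_id']}\t"
                f"{meta['major_allele']}\t{meta['minor_allele']}\t.\tPASS\t.\tGT\t"
                + "\t".join(gts) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (ALT-allele dosage) via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    subjects = np.asarray(vcf.samples)
    dosages, meta = [], []
    for var in vcf:
        # count ALT copies per sample from the genotype calls
        col = np.full(len(subjects), np.nan)
        for i, g in enumerate(var.genotypes):
            alleles = [a for a in g[:-1] if a is not None and a >= 0]
            if alleles:
                col[i] = float(sum(a > 0 for a in alleles))
        dosages.append(col)
        meta.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "minor_allele": var.ALT[0] if var.ALT else "N",
                "major_allele": var.REF,
            }
        )
    vcf.close()
    if not meta:
        raise InvalidParameterError(f"no variants in {path}")
    return GenotypeMatrix(np.column_stack(dosages), subjects, pd.DataFrame(meta))


def write_config(config, path) -> None:
    """Serialize a SimulationConfig (or any object with ``to_dict``) to YAML."""
    d = config.to_dict() if hasattr(config, "to_dict") else dict(config)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SimulationConfig.from_dict(d)
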