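"""Cohort table and genotype file input/output.

The native interchange format is a TSV with header and column order
``id, age, sex, bmi, whr, vd, tpoab, <rsid...>``. Genotypes may alternatively
arrive as a VCF 4.2 of hard calls (GT field only) paired with a phenotype TSV
keyed by sample id. Missing-value tokens accepted on read: empty string, NA,
NaN, "." (the VCF convention).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .genetics import MISSING_TOKENS, GenotypeMatrix, SNPSpec, validate_panel
from .simulate import COHORT_COLUMNS


def cohort_column_order(panel: Iterable[SNPSpec]) -> list[str]:
    return list(COHORT_COLUMNS) + [s.rsid for s in panel]


def write_cohort(cohort: pd.DataFrame, path, panel: Iterable[SNPSpec] | None = None) -> None:
    """Write the cohort TSV with the documented column order, index as ``id``."""
    cols = cohort_column_order(validate_panel(panel)) if panel is not None else list(cohort.columns)
    out = cohort[cols].copy()
    out.index.name = "id"
    out.to_csv(path, sep="\t", na_rep="NA")


def read_cohort(path, panel: Iterable[SNPSpec] | None = None) -> tuple[pd.DataFrame, dict]:
    """Read a cohort TSV/CSV.

    Returns the typed table and a read log (unparseable-cell counts per
    column). Dosage columns are validated to {0, 1, 2, missing}; duplicate ids
    are an error; if a panel is given, its rsid columns must be present.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    raw = pd.read_csv(
        path, sep=sep, index_col="id", dtype=str, keep_default_na=False,
        na_values=list(MISSING_TOKENS),
    )
    if raw.index.duplicated().any():
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate ids in {path}: {dupes[:5]}")
    log: dict[str, int] = {}
    table = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        numeric = pd.to_numeric(raw[col], errors="coerce")
        unparseable = int((numeric.isna() & raw[col].notna()).sum())
        if unparseable:
            log[col] = unparseable
        table[col] = numeric
    if panel is not None:
        missing_cols = [s.rsid for s in validate_panel(panel) if s.rsid not in table.columns]
        if missing_cols:
            raise KeyError(f"cohort file {path} lacks dosage columns for: {missing_cols}")
        rsids = [s.rsid for s in panel]
        GenotypeMatrix(table[rsids])  # validates the dosage domain
    return table, log


def write_vcf(genotypes: GenotypeMatrix, panel: Iterable[SNPSpec], path) -> None:
    """Write hard-called genotypes as a minimal VCF 4.2 (GT only).

    Only the effect allele is known for each site, so it is written as ALT
    against a synthetic placeholder REF base; dosage d becomes the genotype
    with d copies of ALT (0/0, 0/1, 1/1), missing calls become ``./.``.
    """
    panel = sorted(validate_panel(panel), key=lambda s: (str(s.chromosome), s.position))
    samples = list(genotypes.ids)
    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=grsmr\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for snp in panel:
            ref = "A" if snp.effect_allele != "A" else "C"
            calls = [
                gt_codes.get(d, "./.") if not np.isnan(d) else "./."
                for d in genotypes.dosages[snp.rsid].to_numpy()
            ]
            fh.write(
                f"{snp.chromosome}\t{snp.position}\t{snp.rsid}\t{ref}\t{snp.effect_allele}"
                "\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf_genotypes(path, panel: Iterable[SNPSpec]) -> GenotypeMatrix:
    """Read effect-allele dosages from a VCF 4.2 of hard calls.

    Variants are matched to the panel by ID (rsid). The dosage counts copies
    of the effect allele: if the effect allele is ALT the ALT count is used,
    if it is REF the count is 2 minus the ALT count, and a site whose alleles
    include neither is treated as all-missing. Half calls and phased
    separators are accepted; any missing allele makes the call missing.
    """
    from cyvcf2 import VCF

    panel = validate_panel(panel)
    by_rsid = {s.rsid: s for s in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    for variant in vcf:
        snp = by_rsid.get(variant.ID)
        if snp is None:
            continue
        # genotypes: per sample [allele0, allele1, phased]; -1 marks missing
        gts = variant.genotypes
        alt = variant.ALT[0] if variant.ALT else None
        if snp.effect_allele == alt:
            effect_index = 1
        elif snp.effect_allele == variant.REF:
            effect_index = 0
        else:
            columns[snp.rsid] = np.full(len(samples), np.nan)
            continue
        dosage = np.full(len(samples), np.nan)
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles) or len(alleles) != 2:
                continue
            if any(a > 1 for a in alleles):  # allele beyond REF/ALT[0]
                continue
            dosage[i] = sum(1 for a in alleles if a == effect_index)
        columns[snp.rsid] = dosage
    vcf.close()
    absent = [s.rsid for s in panel if s.rsid not in columns]
    if absent:
        raise KeyError(f"VCF {path} lacks panel variants: {absent}")
    df = pd.DataFrame(columns, index=pd.Index(samples, name="id"))
    return GenotypeMatrix(df[[s.rsid for s in panel]])


def read_cohort_vcf(vcf_path, phenotype_path, panel: Iterable[SNPSpec]) -> tuple[pd.DataFrame, dict]:
    """Assemble a cohort table from a genotype VCF plus a phenotype TSV.

    The phenotype TSV must carry the ``id`` column matching VCF sample names
    and the phenotype/covariate columns (age, sex, bmi, whr, vd, tpoab).
    """
    gm = read_vcf_genotypes(vcf_path, panel)
    pheno, log = read_cohort(phenotype_path)
    missing_ids = [i for i in gm.ids if i not in pheno.index]
    if missing_ids:
        raise ValueError(f"phenotype file lacks ids present in VCF: {missing_ids[:5]}")
    cohort = pheno.loc[gm.ids].copy()
    for rsid in gm.snps:
        cohort[rsid] = gm.dosages[rsid]
    return cohort, log
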