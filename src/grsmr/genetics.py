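"""SNP panel handling, genotype quality statistics and weighted genetic risk scores.

The instruments are two allele scores built from an 8-SNP panel: four variants
associated with circulating 25-hydroxyvitamin D (GC, CYP2R1, DHCR7, CYP24A1) and
four associated with thyroid peroxidase antibody concentration (HLA-DPB1, TPO,
RERE, HCP5). Each score is the weighted sum of effect-allele dosages (additive
coding 0/1/2), the standard allele-score construction.

The shipped default panel file carries the published per-SNP metadata (gene,
position, effect allele, effect-allele frequency). The *weights* in that file are
synthetic placeholders: the true weights are external GWAS effect sizes that are
not part of this package's inputs. The placeholders are scaled so each score
lands on the tertile scale reported for the source cohort, which keeps downstream
output comparable; any real analysis should supply its own weights file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

# Trait labels for the two allele scores.
VITAMIN_D = "25ohd"
TPOAB = "tpoab"
TRAITS = (VITAMIN_D, TPOAB)

#: Maximum number of missing panel genotypes an individual may have and still be
#: scored (missing dosages are mean-imputed as 2*EAF); above this the individual
#: is excluded from analysis.
MAX_MISSING_GENOTYPES = 2

MISSING_TOKENS = ("", "NA", "NaN", "nan", ".")


@dataclass(frozen=True)
class SNPSpec:
    """One instrument SNP: identity, effect allele, frequency and per-trait weight."""

    rsid: str
    gene: str
    chromosome: str
    position: int
    effect_allele: str
    eaf: float
    weight: float
    trait: str

    def __post_init__(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise ValueError(
                f"{self.rsid}: effect allele frequency must be in (0, 1), got {self.eaf}"
            )
        if self.trait not in TRAITS:
            raise ValueError(f"{self.rsid}: trait must be one of {TRAITS}, got {self.trait!r}")
        if len(self.effect_allele) != 1 or self.effect_allele not in "ACGT":
            raise ValueError(f"{self.rsid}: effect allele must be a single base, got {self.effect_allele!r}")


def validate_panel(panel: Iterable[SNPSpec]) -> list[SNPSpec]:
    panel = list(panel)
    rsids = [s.rsid for s in panel]
    if len(set(rsids)) != len(rsids):
        dupes = sorted({r for r in rsids if rsids.count(r) > 1})
        raise ValueError(f"duplicate rsids in panel: {dupes}")
    return panel


def panel_for_trait(panel: Iterable[SNPSpec], trait: str) -> list[SNPSpec]:
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    subset = [s for s in panel if s.trait == trait]
    if not subset:
        raise ValueError(f"panel contains no SNPs for trait {trait!r}")
    return subset


def read_weights(path) -> list[SNPSpec]:
    """Read a SNP-weights TSV (columns rsid, gene, chr, pos, effect_allele, eaf, weight, trait)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rsid", "gene", "chr", "pos", "effect_allele", "eaf", "weight", "trait"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"weights file {path} is missing columns: {missing}")
    panel = [
        SNPSpec(
            rsid=row["rsid"],
            gene=row["gene"],
            chromosome=row["chr"],
            position=int(row["pos"]),
            effect_allele=row["effect_allele"],
            eaf=float(row["eaf"]),
            weight=float(row["weight"]),
            trait=row["trait"],
        )
        for _, row in df.iterrows()
    ]
    return validate_panel(panel)


def write_weights(panel: Iterable[SNPSpec], path) -> None:
    rows = [
        {
            "rsid": s.rsid,
            "gene": s.gene,
            "chr": s.chromosome,
            "pos": s.position,
            "effect_allele": s.effect_allele,
            "eaf": s.eaf,
            "weight": s.weight,
            "trait": s.trait,
        }
        for s in panel
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def default_panel() -> list[SNPSpec]:
    """The shipped 8-SNP panel (published metadata, synthetic placeholder weights)."""
    ref = resources.files("grsmr.data").joinpath("default_panel_synthetic_weights.tsv")
    with resources.as_file(ref) as path:
        return read_weights(path)


class GenotypeMatrix:
    """Individuals x SNPs additive dosages (0/1/2), NaN for missing calls.

    Thin wrapper over a pandas DataFrame indexed by individual id with one
    column per rsid; validates the dosage domain on construction.
    """

    def __init__(self, dosages: pd.DataFrame):
        values = dosages.to_numpy(dtype=float, copy=False)
        bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage must be 0, 1, 2 or missing; found {values[i, j]!r} "
                f"for individual {dosages.index[i]!r} at {dosages.columns[j]!r}"
            )
        if dosages.index.duplicated().any():
            raise ValueError("duplicate individual ids in genotype matrix")
        self.dosages = dosages.astype(float)

    @property
    def ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def snps(self) -> list[str]:
        return list(self.dosages.columns)

    @property
    def n_individuals(self) -> int:
        return len(self.dosages)

    def call_rate(self, rsid: str) -> float:
        col = self._column(rsid)
        return float(col.notna().mean())

    def _column(self, rsid: str) -> pd.Series:
        if rsid not in self.dosages.columns:
            raise KeyError(f"SNP {rsid!r} not present in genotype matrix")
        return self.dosages[rsid]


@dataclass
class GRSVector:
    """Per-individual weighted genetic risk score.

    ``grs`` is NaN for individuals with more than :data:`MAX_MISSING_GENOTYPES`
    missing panel genotypes; ``n_missing`` counts missing panel calls per
    individual before imputation.
    """

    trait: str
    grs: pd.Series
    n_missing: pd.Series

    @property
    def scored(self) -> pd.Series:
        return self.grs.notna()


class HWEResult(NamedTuple):
    chi2: float
    p: float
    degenerate: bool  # monomorphic SNP: statistic is 0 by convention


def genotype_counts(genotypes: GenotypeMatrix, rsid: str) -> tuple[int, int, int]:
    col = genotypes._column(rsid).dropna()
    return (int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()))


def effect_allele_frequency(genotypes: GenotypeMatrix, rsid: str) -> float:
    """Sample effect-allele frequency: sum of dosages over twice the call count."""
    col = genotypes._column(rsid).dropna()
    if col.empty:
        raise ValueError(f"SNP {rsid!r} has no non-missing genotype calls")
    return float(col.sum() / (2.0 * len(col)))


def hwe_chi_square_from_counts(n0: int, n1: int, n2: int) -> HWEResult:
    """1-df Pearson chi-square for Hardy-Weinberg equilibrium from genotype counts.

    Expected counts are n(1-p)^2, 2np(1-p), np^2 with p the sample effect-allele
    frequency. A monomorphic SNP has no degree of freedom; it is reported as
    chi2 = 0 with the ``degenerate`` flag set.
    """
    n = n0 + n1 + n2
    if n <= 0:
        raise ValueError("no genotype calls")
    p = (n1 + 2 * n2) / (2 * n)
    if p <= 0.0 or p >= 1.0:
        return HWEResult(chi2=0.0, p=1.0, degenerate=True)
    expected = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(chi2=chi2, p=float(stats.chi2.sf(chi2, df=1)), degenerate=False)


def hwe_chi_square(genotypes: GenotypeMatrix, rsid: str) -> HWEResult:
    col = genotypes._column(rsid).dropna()
    if col.empty:
        raise ValueError(f"SNP {rsid!r} has no non-missing genotype calls")
    return hwe_chi_square_from_counts(*genotype_counts(genotypes, rsid))


def weighted_grs(genotypes: GenotypeMatrix, panel: Iterable[SNPSpec], trait: str) -> GRSVector:
    """Weighted allele score: sum over the trait's panel of weight x dosage.

    Individuals with at most :data:`MAX_MISSING_GENOTYPES` missing panel calls
    have the missing dosages mean-imputed as 2*EAF (EAF from the panel file);
    individuals with more are left unscored (NaN).
    """
    subset = panel_for_trait(validate_panel(panel), trait)
    absent = [s.rsid for s in subset if s.rsid not in genotypes.dosages.columns]
    if absent:
        raise KeyError(f"panel SNPs absent from genotype matrix: {absent}")
    dosages = genotypes.dosages[[s.rsid for s in subset]]
    n_missing = dosages.isna().sum(axis=1)
    imputed = dosages.fillna({s.rsid: 2.0 * s.eaf for s in subset})
    weights = pd.Series({s.rsid: s.weight for s in subset})
    grs = imputed.mul(weights, axis=1).sum(axis=1)
    grs[n_missing > MAX_MISSING_GENOTYPES] = np.nan
    return GRSVector(trait=trait, grs=grs.rename(f"grs_{trait}"), n_missing=n_missing)


@dataclass
class ExclusionAccounting:
    """Stage-by-stage removal counts from the complete-case exclusion filter."""

    n_input: int
    n_excluded_missing_genotypes: int
    n_excluded_missing_tpoab: int
    n_excluded_missing_vd: int
    n_final: int
    empty_result: bool = field(default=False)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "excluded_gt_gt2_missing_snps": self.n_excluded_missing_genotypes,
            "excluded_missing_tpoab": self.n_excluded_missing_tpoab,
            "excluded_missing_25ohd": self.n_excluded_missing_vd,
            "n_final": self.n_final,
        }


def genotyping_coverage_percent(n_genotyped: int, n_recruited: int) -> float:
    """Genotyped share of the recruited sample, in percent (one decimal)."""
    if n_recruited <= 0:
        raise ValueError("n_recruited must be positive")
    return round(100.0 * n_genotyped / n_recruited, 1)


def exclusion_filter(
    cohort: pd.DataFrame, panel: Iterable[SNPSpec]
) -> tuple[pd.DataFrame, ExclusionAccounting]:
    """Remove, in order: individuals missing >2 of the 8 panel genotypes, then
    those missing TPOAb, then those missing 25(OH)D.

    The cohort table must carry one dosage column per panel rsid plus ``tpoab``
    and ``vd`` phenotype columns. Returns the filtered table and a stage-wise
    accounting; an empty result is permitted but flagged.
    """
    panel = validate_panel(panel)
    rsids = [s.rsid for s in panel]
    absent = [r for r in rsids if r not in cohort.columns]
    if absent:
        raise KeyError(f"cohort table lacks dosage columns for panel SNPs: {absent}")
    for col in ("tpoab", "vd"):
        if col not in cohort.columns:
            raise KeyError(f"cohort table lacks phenotype column {col!r}")

    n_input = len(cohort)
    stage1 = cohort[cohort[rsids].isna().sum(axis=1) <= MAX_MISSING_GENOTYPES]
    stage2 = stage1[stage1["tpoab"].notna()]
    stage3 = stage2[stage2["vd"].notna()]
    accounting = ExclusionAccounting(
        n_input=n_input,
        n_excluded_missing_genotypes=n_input - len(stage1),
        n_excluded_missing_tpoab=len(stage1) - len(stage2),
        n_excluded_missing_vd=len(stage2) - len(stage3),
        n_final=len(stage3),
        empty_result=len(stage3) == 0,
    )
    return stage3.copy(), accounting


def panel_summary(genotypes: GenotypeMatrix, panel: Iterable[SNPSpec]) -> pd.DataFrame:
    """Per-SNP table of sample EAF, call rate and the HWE chi-square test."""
    rows = []
    for snp in validate_panel(panel):
        hwe = hwe_chi_square(genotypes, snp.rsid)
        rows.append(
            {
                "rsid": snp.rsid,
                "gene": snp.gene,
                "chr": snp.chromosome,
                "pos": snp.position,
                "effect_allele": snp.effect_allele,
                "trait": snp.trait,
                "eaf_configured": snp.eaf,
                "eaf_observed": effect_allele_frequency(genotypes, snp.rsid),
                "call_rate": genotypes.call_rate(snp.rsid),
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p,
            }
        )
    return pd.DataFrame(rows)
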