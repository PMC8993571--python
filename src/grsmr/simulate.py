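"""Synthetic cohort generator with the statistical structure the MR analysis assumes.

Genotypes are drawn under Hardy-Weinberg equilibrium at each SNP's configured
effect-allele frequency (two independent Bernoulli alleles), without linkage
disequilibrium between SNPs. Phenotypes are generated on the natural-log scale
from a recursive structural model and exponentiated:

    lnVD    = a0 + b_gx (VD_GRS - E[VD_GRS]) + covariate terms + u_x U + e1
    lnTPOAb = b0 + b_c (lnVD - a0) + b_gt (TPO_GRS - E[TPO_GRS])
                 + b_pleio (VD_GRS - E[VD_GRS]) + covariate terms + u_y U + e2

where U ~ N(0,1) is an optional shared latent confounder (off by default),
b_c is the causal effect of ln-exposure on ln-outcome, b_gt the TPOAb score's
own first-stage effect, and b_pleio a direct (pleiotropic) path from the
vitamin-D score to the outcome. Centring the genetic and covariate terms keeps
the marginal phenotype location at (a0, b0) whatever the effect sizes. A
reverse-causal variant (lnTPOAb -> lnVD) is available; the model stays
recursive, so only one causal direction may be non-zero at a time.

Covariate margins default to the source cohort's demographics: age 55 +/- 13
years, 40% male, waist-to-hip ratio 0.86 +/- 0.08, BMI 24.6 +/- 3.6 kg/m^2.
Missingness is injected cell-wise (genotypes and phenotypes separately) after
generation, mirroring the complete-case exclusion the analysis applies.

All randomness flows from a single integer seed through named child streams
(genotypes, covariates, phenotypes, missingness), so any stage rerun with the
same config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import genetics
from .genetics import GenotypeMatrix, SNPSpec

COHORT_COLUMNS = ("age", "sex", "bmi", "whr", "vd", "tpoab")


@dataclass
class CovariateEffects:
    """Coefficients of age, sex (male=1) and waist-to-hip ratio on each ln-phenotype."""

    age_on_exposure: float = -0.002  # ln nmol/L per year
    sex_on_exposure: float = 0.08    # men run slightly higher 25(OH)D here
    whr_on_exposure: float = -0.15
    age_on_outcome: float = 0.002    # ln U/ml per year
    sex_on_outcome: float = -0.25    # thyroid autoimmunity commoner in women
    whr_on_outcome: float = 0.20


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the study conditions it emulates."""

    n_individuals: int = 10636
    seed: int = 20220401
    snp_panel: list[SNPSpec] = field(default_factory=genetics.default_panel)

    # structural effects (ln scale)
    beta_grs_exposure: float = -0.093   # VD_GRS -> ln 25(OH)D, per GRS unit
    beta_grs_tpoab: float = 0.345       # TPOAb_GRS -> ln TPOAb (its first stage)
    beta_causal: float = -0.72          # ln 25(OH)D -> ln TPOAb
    beta_reverse_causal: float = 0.0    # ln TPOAb -> ln 25(OH)D (mutually exclusive)
    beta_grs_outcome_direct: float = 0.0  # pleiotropic VD_GRS -> ln TPOAb path
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    confounding_exposure: float = 0.0   # loading of the latent confounder on lnVD
    confounding_outcome: float = 0.0    # loading of the latent confounder on lnTPOAb

    # marginal locations and dispersions (ln scale)
    intercept_ln_exposure: float = 3.66   # exp(.) ~ 40 nmol/L
    intercept_ln_outcome: float = 3.70    # exp(.) ~ 40 U/ml median, long right tail
    noise_sd_exposure: float = 0.30
    noise_sd_outcome: float = 1.40

    # covariate margins
    age_mean: float = 55.0
    age_sd: float = 13.0
    male_fraction: float = 0.40
    whr_mean: float = 0.86
    whr_sd: float = 0.08
    bmi_mean: float = 24.6
    bmi_sd: float = 3.6

    # missingness
    missing_gt_rate: float = 0.0
    missing_pheno_rate: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for name in ("noise_sd_exposure", "noise_sd_outcome", "age_sd", "whr_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("missing_gt_rate", "missing_pheno_rate", "male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.beta_causal != 0.0 and self.beta_reverse_causal != 0.0:
            raise ValueError(
                "the structural model is recursive: beta_causal and "
                "beta_reverse_causal cannot both be non-zero"
            )
        genetics.validate_panel(self.snp_panel)

    def _streams(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(4)
        names = ("genotypes", "covariates", "phenotypes", "missingness")
        return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


def _expected_grs(panel: list[SNPSpec], trait: str) -> float:
    return sum(s.weight * 2.0 * s.eaf for s in genetics.panel_for_trait(panel, trait))


def simulate_genotypes(panel: list[SNPSpec], n: int, seed) -> GenotypeMatrix:
    """Draw dosages as Binomial(2, EAF) per SNP — two independent alleles, so
    genotype frequencies satisfy Hardy-Weinberg proportions in expectation."""
    panel = genetics.validate_panel(panel)
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dosages = {s.rsid: rng.binomial(2, s.eaf, size=n).astype(float) for s in panel}
    ids = pd.Index([f"id{i:06d}" for i in range(n)], name="id")
    return GenotypeMatrix(pd.DataFrame(dosages, index=ids))


def _simulate_covariates(n: int, config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(config.age_mean, config.age_sd, size=n),
            "sex": rng.binomial(1, config.male_fraction, size=n).astype(float),
            "bmi": rng.normal(config.bmi_mean, config.bmi_sd, size=n),
            "whr": rng.normal(config.whr_mean, config.whr_sd, size=n),
        }
    )


def simulate_phenotypes(genotypes: GenotypeMatrix, config: SimulationConfig) -> pd.DataFrame:
    """Generate covariates and both phenotypes for complete genotypes.

    Returns the cohort table (age, sex, bmi, whr, vd, tpoab, one dosage column
    per rsid) on the natural measurement scale; phenotypes are strictly
    positive by construction.
    """
    if genotypes.dosages.isna().any().any():
        raise ValueError("genotypes must be complete; missingness is injected afterwards")
    streams = config._streams()
    n = genotypes.n_individuals
    cov = _simulate_covariates(n, config, streams["covariates"])
    cov.index = genotypes.ids
    rng = streams["phenotypes"]

    panel = config.snp_panel
    vd_grs = genetics.weighted_grs(genotypes, panel, genetics.VITAMIN_D).grs.to_numpy()
    tpo_grs = genetics.weighted_grs(genotypes, panel, genetics.TPOAB).grs.to_numpy()
    vd_grs_c = vd_grs - _expected_grs(panel, genetics.VITAMIN_D)
    tpo_grs_c = tpo_grs - _expected_grs(panel, genetics.TPOAB)

    ce = config.covariate_effects
    age_c = cov["age"].to_numpy() - config.age_mean
    sex_c = cov["sex"].to_numpy() - config.male_fraction
    whr_c = cov["whr"].to_numpy() - config.whr_mean
    cov_exposure = ce.age_on_exposure * age_c + ce.sex_on_exposure * sex_c + ce.whr_on_exposure * whr_c
    cov_outcome = ce.age_on_outcome * age_c + ce.sex_on_outcome * sex_c + ce.whr_on_outcome * whr_c

    u = rng.standard_normal(n)
    e1 = rng.normal(0.0, config.noise_sd_exposure, size=n)
    e2 = rng.normal(0.0, config.noise_sd_outcome, size=n)

    if config.beta_reverse_causal == 0.0:
        ln_vd = (
            config.intercept_ln_exposure
            + config.beta_grs_exposure * vd_grs_c
            + cov_exposure
            + config.confounding_exposure * u
            + e1
        )
        ln_tpo = (
            config.intercept_ln_outcome
            + config.beta_causal * (ln_vd - config.intercept_ln_exposure)
            + config.beta_grs_tpoab * tpo_grs_c
            + config.beta_grs_outcome_direct * vd_grs_c
            + cov_outcome
            + config.confounding_outcome * u
            + e2
        )
    else:
        ln_tpo = (
            config.intercept_ln_outcome
            + config.beta_grs_tpoab * tpo_grs_c
            + config.beta_grs_outcome_direct * vd_grs_c
            + cov_outcome
            + config.confounding_outcome * u
            + e2
        )
        ln_vd = (
            config.intercept_ln_exposure
            + config.beta_reverse_causal * (ln_tpo - config.intercept_ln_outcome)
            + config.beta_grs_exposure * vd_grs_c
            + cov_exposure
            + config.confounding_exposure * u
            + e1
        )

    cohort = cov.copy()
    cohort["vd"] = np.exp(ln_vd)
    cohort["tpoab"] = np.exp(ln_tpo)
    for rsid in genotypes.snps:
        cohort[rsid] = genotypes.dosages[rsid]
    return cohort


def inject_missingness(
    cohort: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Set genotype cells missing at ``missing_gt_rate`` and each phenotype at
    ``missing_pheno_rate`` (independent Bernoulli per cell).

    Returns the degraded cohort and the boolean mask of blanked cells, from
    which per-class missingness counts can be recomputed exactly.
    """
    rng = config._streams()["missingness"]
    out = cohort.copy()
    rsids = [s.rsid for s in config.snp_panel if s.rsid in cohort.columns]
    mask = pd.DataFrame(False, index=cohort.index, columns=rsids + ["vd", "tpoab"])
    if config.missing_gt_rate > 0 and rsids:
        gt_mask = rng.random((len(cohort), len(rsids))) < config.missing_gt_rate
        mask.loc[:, rsids] = gt_mask
        out[rsids] = out[rsids].mask(gt_mask)
    if config.missing_pheno_rate > 0:
        for col in ("vd", "tpoab"):
            m = rng.random(len(cohort)) < config.missing_pheno_rate
            mask[col] = m
            out[col] = out[col].mask(m)
    return out, mask


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full generator: genotypes -> phenotypes -> missingness.

    Returns (cohort, missingness_mask); deterministic given the config.
    """
    streams = config._streams()
    genotypes = simulate_genotypes(config.snp_panel, config.n_individuals, streams["genotypes"])
    cohort = simulate_phenotypes(genotypes, config)
    return inject_missingness(cohort, config)
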