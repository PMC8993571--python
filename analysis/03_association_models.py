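#!/usr/bin/env python
"""Covariate-adjusted association models on the filtered synthetic cohort.

Builds GRS tertiles, tabulates cohort characteristics across them with
ANOVA/chi-square trend tests, and fits the model-1 (age, sex) and model-2
(age, sex, waist-to-hip ratio) linear associations of each GRS — continuous,
as tertile contrasts, and as an ordinal trend term — with the opposite
ln-phenotype as outcome.
"""

import numpy as np
from pathlib import Path

from grsmr import genetics
from grsmr.io import read_cohort
from grsmr.pipeline import _association_table
from grsmr.regression import MODEL1_COVARIATES, MODEL2_COVARIATES, assign_tertiles, tertile_characteristics

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    panel = genetics.default_panel()
    cohort, _ = read_cohort(OUT / "filtered_cohort.tsv", panel=panel)
    gm = genetics.GenotypeMatrix(cohort[[s.rsid for s in panel]])
    vd_grs = genetics.weighted_grs(gm, panel, genetics.VITAMIN_D).grs.rename("vd_grs")
    tpo_grs = genetics.weighted_grs(gm, panel, genetics.TPOAB).grs.rename("tpoab_grs")
    ln_vd = np.log(cohort["vd"]).rename("ln_vd")
    ln_tpo = np.log(cohort["tpoab"]).rename("ln_tpoab")

    for grs in (vd_grs, tpo_grs):
        tert = assign_tertiles(grs)
        table = tertile_characteristics(
            cohort, tert, ["age", "bmi", "whr", "vd", "tpoab"], categorical=["sex"]
        )
        table.to_csv(OUT / f"tertile_characteristics_{grs.name}.tsv", sep="\t", index=False)
        print(f"\n{grs.name} tertile cutpoints: "
              f"Q1 <= {tert.cutpoints[0]:.3f}, Q3 >= {tert.cutpoints[1]:.3f}")
        print(table.to_string(index=False))

    for covs, label in ((MODEL1_COVARIATES, "model 1"), (MODEL2_COVARIATES, "model 2")):
        fwd = _association_table(cohort, ln_tpo, vd_grs, ln_vd, covs, label, 3)
        rev = _association_table(cohort, ln_vd, tpo_grs, ln_tpo, covs, label, 3)
        suffix = label.replace(" ", "")
        fwd.to_csv(OUT / f"associations_tpoab_outcome_{suffix}.tsv", sep="\t", index=False)
        rev.to_csv(OUT / f"associations_vd_outcome_{suffix}.tsv", sep="\t", index=False)
        print(f"\nln TPOAb outcome ({label}):")
        print(fwd[["term", "B", "SE", "ci_low", "ci_high", "p"]].to_string(index=False))
        print(f"\nln 25(OH)D outcome ({label}):")
        print(rev[["term", "B", "SE", "ci_low", "ci_high", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
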