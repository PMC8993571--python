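#!/usr/bin/env python
"""Bidirectional IV-ratio estimation.

Two complementary runs:

1. From the published model-2 GRS regression coefficients (no individual-level
   data needed): reproduces the reported causal estimates exactly —
   -0.720 (95% CI -1.429, -0.012) for 25(OH)D -> TPOAb and
   -0.087 (95% CI -0.271, 0.097) for the reverse direction.
2. From the filtered synthetic cohort: the full pipeline (GRS construction,
   component regressions, Wald ratio, delta-method interval, instrument F),
   whose forward interval should cover the generator's true causal effect.
"""

from pathlib import Path

from grsmr import genetics, mr
from grsmr.io import read_cohort

OUT = Path(__file__).resolve().parent.parent / "results"
TRUE_CAUSAL = -0.72


def show(estimates: dict, title: str) -> None:
    print(f"\n{title}")
    for direction, est in estimates.items():
        f_part = (
            f", F = {est.diagnostics.f_statistic:.2f}" if est.diagnostics else ""
        )
        flag = "  [weak instrument]" if est.weak_instrument else ""
        print(f"  {direction}: beta_IV = {est.beta_iv:.3f} "
              f"(95% CI {est.ci_low:.3f}, {est.ci_high:.3f}){f_part}{flag}")


def main() -> None:
    published = mr.iv_from_coefficient_table(mr.published_coefficients())
    show(published, "IV estimates from published component coefficients:")
    mr.mr_report(published).to_csv(OUT / "mr_published.tsv", sep="\t", index=False)

    panel = genetics.default_panel()
    cohort, _ = read_cohort(OUT / "filtered_cohort.tsv", panel=panel)
    simulated = mr.bidirectional_mr(cohort, panel)
    show(simulated, "IV estimates on the synthetic cohort:")
    mr.mr_report(simulated).to_csv(OUT / "mr_synthetic.tsv", sep="\t", index=False)

    fwd = simulated[mr.FORWARD]
    covered = fwd.ci_low <= TRUE_CAUSAL <= fwd.ci_high
    print(f"\nforward interval covers the generator's true effect ({TRUE_CAUSAL}): {covered}")


if __name__ == "__main__":
    main()
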