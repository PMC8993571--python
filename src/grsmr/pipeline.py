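"""End-to-end orchestration: simulate/read -> filter -> GRS -> associations -> MR.

``run_pipeline`` sequences the whole analysis and persists every report table
as plain TSV plus one machine-readable JSON summary, so each table can be
re-derived from the persisted filtered cohort and the config alone.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import genetics, mr, regression
from .genetics import GenotypeMatrix, SNPSpec
from .io import read_cohort, write_cohort
from .regression import (
    MODEL1_COVARIATES,
    MODEL2_COVARIATES,
    assign_tertiles,
    ln_transform,
    ols_fit,
    ordinal_trend_fit,
    tertile_characteristics,
)
from .simulate import SimulationConfig, simulate_cohort

from importlib.metadata import version as _pkg_version


@dataclass
class RunConfig:
    """One analysis run: input mode, paths, model choice, seed, output knobs."""

    mode: str = "simulate"  # "simulate" | "cohort-file"
    cohort_path: str | None = None
    weights_path: str | None = None
    output_dir: str = "results"
    model: int = 2
    seed: int = 20220401
    alpha: float = 0.05
    rounding: int = 3
    simulation: SimulationConfig | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "cohort-file"):
            raise ValueError(f"mode must be 'simulate' or 'cohort-file', got {self.mode!r}")
        if self.mode == "cohort-file" and not self.cohort_path:
            raise ValueError("cohort-file mode requires cohort_path")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim_raw is not None:
            cfg.simulation = SimulationConfig(**sim_raw)
        return cfg

    def covariates(self) -> tuple[str, ...]:
        return MODEL1_COVARIATES if self.model == 1 else MODEL2_COVARIATES


@dataclass
class RunReport:
    """Paths of the emitted tables plus the in-memory results."""

    output_dir: Path
    accounting: genetics.ExclusionAccounting
    panel_table: pd.DataFrame
    pleiotropy: pd.DataFrame
    tertile_tables: dict[str, pd.DataFrame]
    association_tables: dict[str, pd.DataFrame]
    mr_table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _association_table(
    cohort: pd.DataFrame,
    ln_outcome: pd.Series,
    grs: pd.Series,
    ln_obs_predictor: pd.Series,
    covariates: tuple[str, ...],
    label: str,
    rounding: int,
) -> pd.DataFrame:
    """One outcome's association table: GRS, GRS tertiles and the observational
    ln-phenotype predictor under the chosen adjustment model."""
    covs = cohort[list(covariates)]
    rows = []

    def add(res: regression.RegressionResult, term: str) -> None:
        rows.append(
            {
                "term": term,
                "B": round(res.beta, rounding),
                "SE": round(res.se, rounding),
                "ci_low": round(res.ci_low, rounding),
                "ci_high": round(res.ci_high, rounding),
                "p": res.p,
                "n": res.n,
                "model": res.model_label,
            }
        )

    add(ols_fit(ln_outcome, grs, covs, model_label=label), grs.name)
    tert = assign_tertiles(grs)
    ref = tert.labels == "Q1"
    for g in ("Q2", "Q3"):
        indicator = (tert.labels == g).astype(float).where(ref | (tert.labels == g))
        indicator.name = f"{grs.name}_{g}_vs_Q1"
        add(ols_fit(ln_outcome, indicator, covs, model_label=label), indicator.name)
    add(ordinal_trend_fit(ln_outcome, tert, covs, model_label=label), f"{grs.name}_p_trend")
    add(ols_fit(ln_outcome, ln_obs_predictor, covs, model_label=label), str(ln_obs_predictor.name))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> RunReport:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    if config.weights_path:
        panel = genetics.read_weights(config.weights_path)
    else:
        panel = genetics.default_panel()

    input_hashes: dict[str, str] = {}
    if config.mode == "simulate":
        sim = config.simulation or SimulationConfig(seed=config.seed)
        cohort, _mask = simulate_cohort(sim)
        panel = sim.snp_panel
        log_lines.append(f"simulated cohort: n={sim.n_individuals}, seed={sim.seed}")
    else:
        cohort, read_log = read_cohort(config.cohort_path, panel=panel)
        input_hashes[str(config.cohort_path)] = _hash_file(config.cohort_path)
        for col, n_bad in read_log.items():
            log_lines.append(f"column {col}: {n_bad} unparseable cells set missing")
    if config.weights_path:
        input_hashes[str(config.weights_path)] = _hash_file(config.weights_path)

    filtered, accounting = genetics.exclusion_filter(cohort, panel)
    log_lines.append(f"exclusion: {accounting.as_dict()}")
    write_cohort(filtered, out / "filtered_cohort.tsv", panel)

    rsids = [s.rsid for s in panel]
    gm = GenotypeMatrix(filtered[rsids])
    panel_table = genetics.panel_summary(gm, panel)
    panel_table.to_csv(out / "panel_summary.tsv", sep="\t", index=False)

    ln_vd, n_bad_vd = ln_transform(filtered["vd"])
    ln_tpo, n_bad_tpo = ln_transform(filtered["tpoab"])
    if n_bad_vd or n_bad_tpo:
        log_lines.append(f"non-positive phenotypes set missing: vd={n_bad_vd}, tpoab={n_bad_tpo}")
    ln_vd = ln_vd.rename("ln_vd")
    ln_tpo = ln_tpo.rename("ln_tpoab")

    vd_grs = genetics.weighted_grs(gm, panel, genetics.VITAMIN_D).grs.rename("vd_grs")
    tpo_grs = genetics.weighted_grs(gm, panel, genetics.TPOAB).grs.rename("tpoab_grs")

    pleio = mr.pleiotropy_screen(filtered, panel, alpha=config.alpha)
    pleio.to_csv(out / "pleiotropy_screen.tsv", sep="\t", index=False)

    characteristics_vars = ["age", "bmi", "whr", "vd", "tpoab"]
    tertile_tables: dict[str, pd.DataFrame] = {}
    for grs in (vd_grs, tpo_grs):
        tert = assign_tertiles(grs)
        table = tertile_characteristics(filtered, tert, characteristics_vars, categorical=["sex"])
        table.insert(1, "cutpoints", [f"<= {tert.cutpoints[0]:.3f} / >= {tert.cutpoints[1]:.3f}"] + [""] * (len(table) - 1))
        tertile_tables[str(grs.name)] = table
        table.to_csv(out / f"tertile_characteristics_{grs.name}.tsv", sep="\t", index=False)

    label = f"model {config.model}"
    association_tables = {
        "tpoab_outcome": _association_table(
            filtered, ln_tpo, vd_grs, ln_vd, config.covariates(), label, config.rounding
        ),
        "vd_outcome": _association_table(
            filtered, ln_vd, tpo_grs, ln_tpo, config.covariates(), label, config.rounding
        ),
    }
    for name, table in association_tables.items():
        table.to_csv(out / f"associations_{name}.tsv", sep="\t", index=False)

    estimates = mr.bidirectional_mr(filtered, panel, covariates=config.covariates())
    mr_table = mr.mr_report(estimates)
    mr_table.to_csv(out / "mr_estimates.tsv", sep="\t", index=False)
    for est in estimates.values():
        if est.weak_instrument:
            log_lines.append(
                f"warning: weak instrument for {est.direction} "
                f"(F = {est.diagnostics.f_statistic:.2f} < {mr.WEAK_INSTRUMENT_F})"
            )

    summary = {
        "seed": config.seed,
        "mode": config.mode,
        "model": config.model,
        "exclusion": accounting.as_dict(),
        "mr": {
            row["direction"]: {
                "beta_iv": round(row["beta_iv"], config.rounding),
                "ci_low": round(row["ci_low"], config.rounding),
                "ci_high": round(row["ci_high"], config.rounding),
                "f_statistic": round(row["f_statistic"], 2),
                "weak_instrument": bool(row["weak_instrument"]),
            }
            for _, row in mr_table.iterrows()
        },
        "provenance": {
            "package_version": _pkg_version("grsmr"),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "input_hashes": input_hashes,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")

    return RunReport(
        output_dir=out,
        accounting=accounting,
        panel_table=panel_table,
        pleiotropy=pleio,
        tertile_tables=tertile_tables,
        association_tables=association_tables,
        mr_table=mr_table,
        summary=summary,
    )
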