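"""Unit and property tests for panel handling, EAF/HWE statistics, weighted
GRS construction and the complete-case exclusion filter."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import hwe_chi2_from_counts

from grsmr import genetics
from grsmr.genetics import (
    ExclusionAccounting,
    GenotypeMatrix,
    effect_allele_frequency,
    exclusion_filter,
    genotyping_coverage_percent,
    hwe_chi_square,
    hwe_chi_square_from_counts,
    weighted_grs,
)
from grsmr.simulate import SimulationConfig, simulate_cohort, simulate_genotypes


class TestSNPSpec:
    def test_degenerate_frequency_rejected(self, make_snp):
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError, match="frequency"):
                make_snp(eaf=bad)

    def test_unknown_trait_rejected(self, make_snp):
        with pytest.raises(ValueError, match="trait"):
            make_snp(trait="height")

    def test_duplicate_rsids_rejected(self, make_snp):
        with pytest.raises(ValueError, match="duplicate"):
            genetics.validate_panel([make_snp(rsid="rs1"), make_snp(rsid="rs1")])

    def test_default_panel_has_both_four_snp_scores(self, panel):
        assert len(panel) == 8
        assert sum(s.trait == genetics.VITAMIN_D for s in panel) == 4
        assert sum(s.trait == genetics.TPOAB for s in panel) == 4


class TestGenotypeMatrix:
    def test_rejects_out_of_domain_dosage(self):
        df = pd.DataFrame({"rs1": [0.0, 3.0]}, index=pd.Index(["a", "b"], name="id"))
        with pytest.raises(ValueError, match="dosage"):
            GenotypeMatrix(df)

    def test_rejects_duplicate_ids(self):
        df = pd.DataFrame({"rs1": [0.0, 1.0]}, index=pd.Index(["a", "a"], name="id"))
        with pytest.raises(ValueError, match="duplicate"):
            GenotypeMatrix(df)


class TestEffectAlleleFrequency:
    @pytest.mark.parametrize(
        "dosages, expected",
        [([0, 1, 2], 0.5), ([2, 2, 2, 2], 1.0), ([0, 0, 1], 1 / 6)],
    )
    def test_exact_counts(self, make_matrix, dosages, expected):
        gm = make_matrix({"rs1": dosages})
        assert effect_allele_frequency(gm, "rs1") == pytest.approx(expected)

    def test_all_missing_errors_with_snp_name(self, make_matrix):
        gm = make_matrix({"rs1": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="rs1"):
            effect_allele_frequency(gm, "rs1")

    def test_recovers_simulated_frequency(self, make_snp):
        # rs6013897-like SNP at EAF 0.16, 1000 individuals: estimate within 3
        # binomial standard errors of truth
        snp = make_snp(rsid="rs6013897", eaf=0.16, effect_allele="A")
        gm = simulate_genotypes([snp], 1000, seed=42)
        est = effect_allele_frequency(gm, "rs6013897")
        se = np.sqrt(0.16 * 0.84 / (2 * 1000))
        assert abs(est - 0.16) < 3 * se


class TestHWE:
    @pytest.mark.parametrize("counts", [(25, 50, 25), (36, 48, 16)])
    def test_exact_hwe_proportions_give_zero(self, counts):
        res = hwe_chi_square_from_counts(*counts)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert not res.degenerate

    def test_monomorphic_is_degenerate_zero(self, make_matrix):
        gm = make_matrix({"rs1": [0, 0, 0, 0]})
        res = hwe_chi_square(gm, "rs1")
        assert res.chi2 == 0.0 and res.degenerate

    def test_matches_textbook_oracle_on_random_counts(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n0, n1, n2 = rng.integers(1, 200, size=3)
            got = hwe_chi_square_from_counts(int(n0), int(n1), int(n2))
            chi2, p = hwe_chi2_from_counts(int(n0), int(n1), int(n2))
            assert got.chi2 == pytest.approx(chi2, abs=1e-10)
            assert got.p == pytest.approx(p, abs=1e-10)

    def test_null_calibration_at_large_n(self, make_snp):
        # under HWE-by-construction sampling, the 1-df test exceeds the 5%
        # critical value (3.841) in about 5% of replicates
        snp = make_snp(rsid="rs1", eaf=0.3)
        exceed = sum(
            hwe_chi_square(simulate_genotypes([snp], 5000, seed=1000 + r), "rs1").chi2 > 3.841
            for r in range(200)
        )
        # binomial(200, 0.05): 99.9% interval roughly [2, 21]
        assert 2 <= exceed <= 21


class TestWeightedGRS:
    def test_hand_summation(self, make_snp, make_matrix):
        weights = (0.1, 0.2, 0.05, 0.15)
        dosages = (1, 0, 2, 1)
        panel = [make_snp(rsid=f"rs{i}", weight=w) for i, w in enumerate(weights)]
        gm = make_matrix({f"rs{i}": [d] for i, d in enumerate(dosages)})
        res = weighted_grs(gm, panel, genetics.VITAMIN_D)
        assert res.grs.iloc[0] == pytest.approx(0.35)

    def test_zero_dosages_give_zero_score(self, make_snp, make_matrix):
        panel = [make_snp(rsid="rs1", weight=0.5)]
        gm = make_matrix({"rs1": [0, 0, 0]})
        assert (weighted_grs(gm, panel, genetics.VITAMIN_D).grs == 0).all()

    def test_single_snp_linearity(self, make_snp, make_matrix):
        panel = [make_snp(rsid="rs1", weight=0.37)]
        gm = make_matrix({"rs1": [2]})
        assert weighted_grs(gm, panel, genetics.VITAMIN_D).grs.iloc[0] == pytest.approx(0.74)

    def test_mean_imputation_up_to_two_missing(self, make_snp, make_matrix):
        panel = [make_snp(rsid=f"rs{i}", weight=1.0, eaf=0.25) for i in range(4)]
        gm = make_matrix(
            {
                "rs0": [1, np.nan, np.nan],
                "rs1": [1, 1, np.nan],
                "rs2": [1, np.nan, np.nan],
                "rs3": [1, 1, 1],
            }
        )
        res = weighted_grs(gm, panel, genetics.VITAMIN_D)
        # row 1: two missing, each imputed as 2*EAF = 0.5
        assert res.grs.iloc[1] == pytest.approx(1 + 1 + 2 * 0.5)
        # row 2: three missing -> unscored
        assert np.isnan(res.grs.iloc[2])
        assert list(res.n_missing) == [0, 2, 3]

    def test_absent_panel_snp_named_in_error(self, make_snp, make_matrix):
        panel = [make_snp(rsid="rs_absent")]
        gm = make_matrix({"rs1": [0, 1]})
        with pytest.raises(KeyError, match="rs_absent"):
            weighted_grs(gm, panel, genetics.VITAMIN_D)

    @staticmethod
    def _spec(rsid, weight):
        return genetics.SNPSpec(
            rsid=rsid, gene="GENE", chromosome="1", position=1000,
            effect_allele="G", eaf=0.3, weight=weight, trait=genetics.VITAMIN_D,
        )

    @settings(derandomize=True, max_examples=25)
    @given(scale=st.floats(-5, 5, allow_nan=False), seed=st.integers(0, 10**6))
    def test_scaling_weights_scales_scores(self, scale, seed):
        rng = np.random.default_rng(seed)
        panel = [self._spec(f"rs{i}", w) for i, w in enumerate((0.1, 0.3, 0.2))]
        scaled = [self._spec(f"rs{i}", w * scale) for i, w in enumerate((0.1, 0.3, 0.2))]
        df = pd.DataFrame(
            {f"rs{i}": rng.integers(0, 3, size=20).astype(float) for i in range(3)},
            index=pd.Index([f"s{i}" for i in range(20)], name="id"),
        )
        gm = GenotypeMatrix(df)
        base = weighted_grs(gm, panel, genetics.VITAMIN_D).grs
        got = weighted_grs(gm, scaled, genetics.VITAMIN_D).grs
        np.testing.assert_allclose(got, base * scale, atol=1e-12)


def _toy_cohort(panel, n=50, seed=0):
    cfg = SimulationConfig(n_individuals=n, seed=seed, snp_panel=panel)
    cohort, mask = simulate_cohort(cfg)
    return cohort, mask


class TestExclusionFilter:
    def test_no_missingness_is_identity_and_idempotent(self, panel):
        cohort, _ = _toy_cohort(panel)
        out1, acc1 = exclusion_filter(cohort, panel)
        pd.testing.assert_frame_equal(out1, cohort)
        assert acc1.n_final == acc1.n_input == len(cohort)
        out2, acc2 = exclusion_filter(out1, panel)
        pd.testing.assert_frame_equal(out2, out1)
        assert acc2.n_excluded_missing_genotypes == 0
        assert acc2.n_excluded_missing_tpoab == 0
        assert acc2.n_excluded_missing_vd == 0

    def test_accounting_matches_injected_missingness_mask(self, panel):
        cfg = SimulationConfig(
            n_individuals=800, seed=11, snp_panel=panel,
            missing_gt_rate=0.08, missing_pheno_rate=0.01,
        )
        cohort, mask = simulate_cohort(cfg)
        _, acc = exclusion_filter(cohort, panel)
        rsids = [s.rsid for s in panel]
        gt_fail = mask[rsids].sum(axis=1) > genetics.MAX_MISSING_GENOTYPES
        tpo_fail = ~gt_fail & mask["tpoab"]
        vd_fail = ~gt_fail & ~tpo_fail & mask["vd"]
        assert acc.n_excluded_missing_genotypes == int(gt_fail.sum())
        assert acc.n_excluded_missing_tpoab == int(tpo_fail.sum())
        assert acc.n_excluded_missing_vd == int(vd_fail.sum())
        assert acc.n_final == len(cohort) - int((gt_fail | tpo_fail | vd_fail).sum())

    def test_stagewise_order_small_example(self, make_snp, panel):
        cohort, _ = _toy_cohort(panel, n=10, seed=3)
        rsids = [s.rsid for s in panel]
        # one individual failing each stage, in order
        cohort.loc[cohort.index[0], rsids[:3]] = np.nan  # >2 missing genotypes
        cohort.loc[cohort.index[0], "tpoab"] = np.nan    # would also fail stage 2
        cohort.loc[cohort.index[1], "tpoab"] = np.nan
        cohort.loc[cohort.index[2], "vd"] = np.nan
        _, acc = exclusion_filter(cohort, panel)
        assert acc.as_dict() == {
            "n_input": 10,
            "excluded_gt_gt2_missing_snps": 1,
            "excluded_missing_tpoab": 1,
            "excluded_missing_25ohd": 1,
            "n_final": 7,
        }

    def test_empty_result_allowed_but_flagged(self, panel):
        cohort, _ = _toy_cohort(panel, n=4)
        cohort["tpoab"] = np.nan
        out, acc = exclusion_filter(cohort, panel)
        assert len(out) == 0 and acc.empty_result


def test_genotyping_coverage_percent_rounding():
    assert genotyping_coverage_percent(10672, 12666) == 84.3
    with pytest.raises(ValueError):
        genotyping_coverage_percent(1, 0)
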