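"""HWE, allele-frequency, geography and meta-analysis diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from assortmr import SimulationConfig, simulate_cohort
from assortmr.concordance import genotypic_concordance
from assortmr.errors import DataError
from assortmr.stratification import (allele_freq_diff, birth_distance_km,
                                     distance_stratify, genotype_counts,
                                     hwe_test, meta_fixed, meta_from_table,
                                     snp_geo_assoc, within_centre_meta)


class TestHWE:
    def test_exact_hwe_proportions_give_zero(self):
        # p = 0.5, n = 100: (25, 50, 25)
        r = hwe_test((25, 50, 25))
        assert r.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_example(self):
        """(10, 80, 10): p=0.5, expected (25, 50, 25), chi2 = 9+18+9 = 36."""
        r = hwe_test((10, 80, 10))
        assert r.chi2 == pytest.approx(36.0, abs=1e-12)
        assert r.expected == pytest.approx((25.0, 50.0, 25.0))
        assert r.heterozygote_deficit is False  # excess here

    def test_allele_relabel_invariance(self):
        for counts in ((30, 40, 130), (5, 50, 145), (0, 10, 90)):
            assert hwe_test(counts).chi2 == pytest.approx(
                hwe_test(counts[::-1]).chi2, rel=1e-12)

    def test_monomorphic_flagged(self):
        r = hwe_test((0, 0, 50))
        assert r.monomorphic and r.chi2 == 0.0

    def test_invalid_counts_rejected(self):
        with pytest.raises(DataError):
            hwe_test((0, 0, 0))

    def test_pooled_cline_strata_show_wahlund_deficit(self):
        """Two HWE strata with different allele frequencies pooled together
        show fewer heterozygotes than expected; each stratum alone is fine."""
        rng = np.random.default_rng(17)
        g1 = rng.binomial(2, 0.10, 50_000)
        g2 = rng.binomial(2, 0.40, 50_000)
        pooled = hwe_test(genotype_counts(np.r_[g1, g2]))
        assert pooled.heterozygote_deficit
        assert pooled.p < 1e-6
        for g in (g1, g2):
            assert hwe_test(genotype_counts(g)).p > 0.001


class TestAlleleFreqDiff:
    def test_identical_frequencies_near_zero(self):
        chi2, p = allele_freq_diff((810, 180, 10), (810, 180, 10))
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_matches_textbook_chi_square(self):
        """Hand 2x2 table: chi-square = N (ad-bc)^2 / (row/col products)."""
        c1, c2 = (70, 25, 5), (50, 40, 10)
        a = 2 * c1[2] + c1[1]; b = 2 * c1[0] + c1[1]
        c = 2 * c2[2] + c2[1]; d = 2 * c2[0] + c2[1]
        n = a + b + c + d
        expect = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        chi2, _ = allele_freq_diff(c1, c2)
        assert chi2 == pytest.approx(expect, rel=1e-9)

    def test_zero_margin_rejected(self):
        with pytest.raises(DataError, match="zero margin"):
            allele_freq_diff((10, 0, 0), (5, 0, 0))


class TestGeoAssociation:
    def test_cline_direction_and_magnitude_recovered(self):
        """Steep-cline cohort: the km-per-allele slope matches the analytic
        expectation 2 g p q var(coord) / var(G) with the design's sign."""
        cfg = SimulationConfig(n_individuals=5000,
                               cline_gradients=(-3.0e-3, 1.5e-3), seed=47)
        c = simulate_cohort(cfg)
        g = c.genotypes["rs_focal"]
        coords = c.individuals[["birth_north_km", "birth_east_km"]]
        res = snp_geo_assoc(g, coords)
        # effect (major) allele is more northern and more western by design
        assert res["birth_north_km"].z > 4
        assert res["birth_east_km"].z < -4
        p = 1 - g.mean() / 2  # minor-allele frequency
        expect_north = (2 * 3.0e-3 * p * (1 - p)
                        * coords["birth_north_km"].var() / g.var())
        assert res["birth_north_km"].beta == pytest.approx(
            expect_north, abs=3 * res["birth_north_km"].se)

    def test_no_cline_is_null(self):
        c = simulate_cohort(SimulationConfig(
            n_individuals=4000, cline_gradients=(0.0, 0.0), seed=29))
        res = snp_geo_assoc(c.genotypes["rs_focal"],
                            c.individuals[["birth_north_km", "birth_east_km"]])
        assert abs(res["birth_north_km"].z) < 3
        assert abs(res["birth_east_km"].z) < 3

    def test_constant_coordinate_gives_zero(self, small_cohort):
        coords = small_cohort.individuals[["birth_north_km"]].copy()
        coords["birth_north_km"] = 42.0
        res = snp_geo_assoc(small_cohort.genotypes["rs_focal"], coords)
        assert res["birth_north_km"].beta == 0.0


class TestMeta:
    def test_single_stratum_passthrough(self):
        t = pd.DataFrame({"label": ["only"], "n": [100], "beta": [0.05],
                          "ci_lo": [0.01], "ci_hi": [0.09]})
        m = meta_from_table(t)
        assert m.combined_beta == pytest.approx(0.05)
        assert m.Q == pytest.approx(0.0, abs=1e-12)
        assert m.k_used == 1

    def test_two_strata_hand_arithmetic(self):
        res = meta_fixed([0.2, 0.4], [0.1, 0.2])
        w1, w2 = 1 / 0.01, 1 / 0.04
        assert res["beta"] == pytest.approx((0.2 * w1 + 0.4 * w2) / (w1 + w2))
        assert res["se"] == pytest.approx(1 / np.sqrt(w1 + w2))
        assert res["se"] <= 0.1  # combined never worse than best stratum

    def test_missing_estimates_excluded_with_reason(self):
        t = pd.DataFrame({"label": ["a", "b"], "n": [10, 500],
                          "beta": [np.nan, 0.02], "ci_lo": [np.nan, 0.0],
                          "ci_hi": [np.nan, 0.04]})
        m = meta_from_table(t)
        assert list(m.excluded["label"]) == ["a"]
        assert list(m.excluded["reason"]) == ["no_estimate"]
        assert m.k_used == 1

    def test_single_stratum_meta_equals_unstratified(self, small_cohort):
        """Combining all pairs as one stratum reproduces the plain estimate."""
        pairs = small_cohort.couple_frame()[["id_a", "id_b"]].reset_index(drop=True)
        ind = small_cohort.individuals.copy()
        ind["centre"] = "ALL"
        m = within_centre_meta(pairs, small_cohort.genotypes, "rs_focal", ind,
                               seed=3)
        direct = genotypic_concordance(pairs, small_cohort.genotypes, "rs_focal",
                                       seed=3)
        assert m.combined_beta == pytest.approx(direct.beta, rel=1e-9)
        assert m.combined_se == pytest.approx(direct.se, rel=1e-9)

    def test_small_strata_excluded(self, small_cohort):
        pairs = small_cohort.couple_frame()[["id_a", "id_b"]].reset_index(drop=True)
        m = within_centre_meta(pairs, small_cohort.genotypes, "rs_focal",
                               small_cohort.individuals, min_pairs=40, seed=3)
        assert (m.strata["n"] >= 40).all()
        assert set(m.excluded["reason"]) <= {"too_few_pairs", "regression_failed"}

    def test_Q_p_uniform_under_homogeneity(self):
        """Across replicates drawn from a common true beta, Q's p-value is
        uniform (KS check)."""
        rng = np.random.default_rng(31)
        ps = []
        for _ in range(400):
            ses = rng.uniform(0.05, 0.2, 8)
            betas = rng.normal(0.1, ses)
            ps.append(meta_fixed(betas, ses)["Q_p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestDistanceStratification:
    def test_boundary_and_triangle(self, small_cohort):
        ind = small_cohort.individuals.copy()
        pairs = small_cohort.couple_frame()[["id_a", "id_b"]].head(2).reset_index(drop=True)
        a0, b0 = pairs.loc[0, "id_a"], pairs.loc[0, "id_b"]
        ind.loc[a0, ["birth_north_km", "birth_east_km"]] = [0.0, 0.0]
        ind.loc[b0, ["birth_north_km", "birth_east_km"]] = [60.0, 80.0]
        a1, b1 = pairs.loc[1, "id_a"], pairs.loc[1, "id_b"]
        ind.loc[a1, ["birth_north_km", "birth_east_km"]] = [10.0, 10.0]
        ind.loc[b1, ["birth_north_km", "birth_east_km"]] = [10.0, 10.0]
        d = birth_distance_km(pairs, ind)
        assert d.iloc[0] == pytest.approx(100.0)  # 3-4-5 triangle
        assert d.iloc[1] == 0.0
        # exactly-100km pair belongs to the "within" stratum by convention
        dist = d.to_numpy()
        assert ((dist <= 100.0).sum()) == 2

    def test_geographic_homogamy_detected_by_stratified_contrast(self):
        """Cline-only geographic homogamy: the pooled genotypic concordance is
        strong, close-born pairs carry it (shared local gene pool), and the
        within-centre meta-analysis — which removes between-region
        allele-frequency variation — attenuates it toward zero.  This is the
        population-stratification signature the centre stratification is
        designed to expose."""
        # a common structured variant (MAF 0.2) on a steep cline, couples
        # formed purely on birth-location proximity along the cline axis
        cfg = SimulationConfig(
            n_individuals=30_000, mechanism="homogamy",
            homogamy_basis="geography", assort_C=0.9, maf_focal=0.2,
            cline_gradients=(-3.0e-3, 0.0), n_centres=6, seed=43)
        c = simulate_cohort(cfg)
        pairs = c.couple_frame()[["id_a", "id_b"]].reset_index(drop=True)
        full = genotypic_concordance(pairs, c.genotypes, "rs_focal", seed=1)
        assert full.z > 4                      # cline-driven concordance exists
        res = distance_stratify(pairs, c.individuals, c.genotypes, "rs_focal",
                                threshold_km=100.0, seed=1)
        assert res["n_within"] + res["n_beyond"] == len(pairs)
        # far-born pairs have nearly independent local frequencies
        assert res["beyond"]["genotypic"].beta < full.beta
        meta = within_centre_meta(pairs, c.genotypes, "rs_focal",
                                  c.individuals, seed=1)
        assert meta.combined_beta < 0.5 * full.beta
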