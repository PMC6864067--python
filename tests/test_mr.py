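"""MR estimator suite: hand-checked examples, regression algebra, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from assortmr.errors import DataError
from assortmr.mr import (MRInput, compare_additive_dominant, cross_spouse_mr,
                         ivw_fixed, mr_egger, snp_association, wald_ratio,
                         weighted_median, weighted_mode, z_difference)


def _inp(bx, by, sy=0.1, sx=0.1, name="v"):
    return MRInput(name, bx, sx, by, sy)


class TestWaldRatio:
    def test_published_stage_estimates(self):
        """1.06 / 3.99 = 0.266; CI bounds scale as 0.59/3.99 and 1.52/3.99."""
        r = wald_ratio(_inp(3.99, 1.06, sy=(1.52 - 0.59) / (2 * 1.96)))
        assert r.beta == pytest.approx(1.06 / 3.99, abs=1e-12)
        assert r.beta == pytest.approx(0.26, abs=0.01)
        assert r.ci95[1] == pytest.approx(1.52 / 3.99, abs=0.005)

    def test_zero_outcome_gives_zero(self):
        assert wald_ratio(_inp(2.0, 0.0)).beta == 0.0

    def test_zero_exposure_rejected(self):
        with pytest.raises(DataError, match="weak instrument"):
            wald_ratio(_inp(0.0, 1.0))

    @given(bx=st.floats(0.1, 5), by=st.floats(-5, 5), sy=st.floats(0.01, 1))
    @settings(max_examples=100, derandomize=True)
    def test_matches_direct_division(self, bx, by, sy):
        r = wald_ratio(_inp(bx, by, sy=sy))
        assert r.beta == pytest.approx(by / bx, rel=1e-12)
        assert r.se == pytest.approx(sy / abs(bx), rel=1e-12)

    def test_second_order_se_is_larger(self):
        first = wald_ratio(_inp(2.0, 1.0, sy=0.2, sx=0.3))
        second = wald_ratio(_inp(2.0, 1.0, sy=0.2, sx=0.3), second_order=True)
        assert second.se > first.se


class TestIVW:
    def test_single_variant_equals_wald(self):
        i = _inp(3.0, 0.9, sy=0.2)
        assert ivw_fixed([i]).beta == pytest.approx(wald_ratio(i).beta)
        assert ivw_fixed([i]).se == pytest.approx(wald_ratio(i).se)

    def test_two_variant_hand_example(self):
        """Ratios 0.2 (se 0.1) and 0.4 (se 0.2) combine to 0.24."""
        ins = [_inp(1.0, 0.2, sy=0.1), _inp(1.0, 0.4, sy=0.2)]
        assert ivw_fixed(ins).beta == pytest.approx(0.24, abs=1e-12)

    def test_homogeneous_ratios_give_zero_Q(self):
        ins = [_inp(1.0, 0.3, sy=s) for s in (0.1, 0.2, 0.3)]
        r = ivw_fixed(ins)
        assert r.Q == pytest.approx(0.0, abs=1e-12)
        assert r.I2 == 0.0

    def test_I2_definition_and_range(self):
        rng = np.random.default_rng(0)
        ins = [_inp(1.0, rng.normal(0.3, 0.3), sy=0.05) for _ in range(8)]
        r = ivw_fixed(ins)
        assert r.I2 == pytest.approx(max(0.0, (r.Q - 7) / r.Q))
        assert 0 <= r.I2 < 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, derandomize=True)
    def test_invariant_to_allele_flip(self, seed):
        """Negating both stage betas of any variant leaves IVW unchanged."""
        rng = np.random.default_rng(seed)
        k = 5
        ins = [_inp(rng.uniform(0.2, 1), rng.normal(0.2, 0.2),
                    sy=rng.uniform(0.05, 0.3), name=f"v{j}") for j in range(k)]
        j = rng.integers(k)
        flipped = list(ins)
        flipped[j] = MRInput(ins[j].variant, -ins[j].beta_exposure,
                             ins[j].se_exposure, -ins[j].beta_outcome,
                             ins[j].se_outcome)
        a, b = ivw_fixed(ins), ivw_fixed(flipped)
        assert a.beta == pytest.approx(b.beta, rel=1e-12)
        assert a.Q == pytest.approx(b.Q, rel=1e-9)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            ivw_fixed([])


class TestEgger:
    def test_requires_three_variants(self):
        with pytest.raises(DataError, match="at least 3"):
            mr_egger([_inp(1, 0.2), _inp(1, 0.3)])

    def test_additive_offset_moves_intercept_not_slope(self):
        """Adding b to every outcome beta shifts the intercept by b exactly."""
        rng = np.random.default_rng(3)
        ins = [_inp(rng.uniform(0.2, 1.5), rng.normal(0.25, 0.1),
                    sy=rng.uniform(0.05, 0.2), name=f"v{j}") for j in range(8)]
        base = mr_egger(ins)
        b = 0.37
        shifted = [MRInput(i.variant, i.beta_exposure, i.se_exposure,
                           i.beta_outcome + b, i.se_outcome) for i in ins]
        moved = mr_egger(shifted)
        assert moved.egger_intercept == pytest.approx(base.egger_intercept + b,
                                                      rel=1e-9)
        assert moved.beta == pytest.approx(base.beta, rel=1e-9)

    def test_zero_pleiotropy_simulation_agrees_with_ivw(self):
        rng = np.random.default_rng(7)
        bx = rng.uniform(0.3, 1.5, 50)
        sy = rng.uniform(0.02, 0.08, 50)
        by = rng.normal(0.3 * bx, sy)
        ins = [_inp(bx[j], by[j], sy=sy[j], name=f"v{j}") for j in range(50)]
        eg, ivw = mr_egger(ins), ivw_fixed(ins)
        assert abs(eg.egger_intercept) < 3 * eg.intercept_se
        assert eg.beta == pytest.approx(ivw.beta, abs=3 * eg.se)


class TestMedianMode:
    def test_equal_weights_median_is_plain_median(self):
        ins = [_inp(1.0, r, sy=0.1) for r in (0.1, 0.2, 0.9)]
        assert weighted_median(ins, n_boot=50, seed=0).beta == pytest.approx(0.2)

    def test_majority_valid_median_resists_contamination(self):
        """60% of instruments near truth, 40% shifted: median stays near
        truth while IVW is dragged."""
        rng = np.random.default_rng(11)
        truth, shift = 0.3, 1.5
        ins = []
        for j in range(30):
            target = truth if j < 18 else shift
            ins.append(_inp(1.0, rng.normal(target, 0.02), sy=0.05, name=f"v{j}"))
        med = weighted_median(ins, n_boot=200, seed=1).beta
        ivw = ivw_fixed(ins).beta
        assert abs(med - truth) < 0.1
        assert abs(ivw - truth) > 0.3

    def test_mode_finds_tight_cluster(self):
        ins = [_inp(1.0, r, sy=0.05)
               for r in (0.30, 0.31, 0.29, 0.305, 0.295, 2.0)]
        r = weighted_mode(ins, n_boot=50, seed=0)
        assert r.beta == pytest.approx(0.30, abs=0.05)

    def test_small_k_rejected(self):
        with pytest.raises(DataError):
            weighted_median([_inp(1, 0.2), _inp(1, 0.3)])
        with pytest.raises(DataError):
            weighted_mode([_inp(1, 0.2), _inp(1, 0.3)])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_median_lies_within_ratio_range(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 9))
        ins = [_inp(rng.uniform(0.2, 2), rng.normal(0, 1),
                    sy=rng.uniform(0.05, 0.5), name=f"v{j}") for j in range(k)]
        ratios = [i.beta_outcome / i.beta_exposure for i in ins]
        m = weighted_median(ins, n_boot=10, seed=0).beta
        assert min(ratios) - 1e-12 <= m <= max(ratios) + 1e-12

    def test_bootstrap_se_is_seed_deterministic(self):
        ins = [_inp(1.0, r, sy=0.1) for r in (0.1, 0.25, 0.4, 0.15)]
        a = weighted_median(ins, n_boot=300, seed=5)
        b = weighted_median(ins, n_boot=300, seed=5)
        assert a.se == b.se


class TestZDifference:
    def test_equal_betas_give_p_one(self):
        z, p = z_difference(0.3, 0.1, 0.3, 0.2)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_published_estimates_are_marginally_different(self):
        """Phenotypic 0.37 vs Wald 0.266 from printed inputs: p of order 0.07."""
        se_ph = (0.38 - 0.36) / (2 * 1.96)
        se_mr = (1.52 - 0.59) / (2 * 1.96) / 3.99
        _, p = z_difference(0.37, se_ph, 1.06 / 3.99, se_mr)
        assert 0.04 < p < 0.12

    def test_infinite_uncertainty_gives_p_one(self):
        _, p = z_difference(0.3, 0.1, 5.0, 1e6)
        assert p == pytest.approx(1.0, abs=1e-4)


class TestSnpAssociation:
    def test_dominant_recode(self):
        g = pd.DataFrame({"v": [0.0, 1.0, 2.0, 2.0]})
        y = pd.Series([0.0, 1.0, 1.0, 1.0])
        r = snp_association(g, y, model="dominant")
        assert r.loc["v", "beta"] == pytest.approx(1.0)

    def test_recovers_simulated_effect(self, small_cohort):
        ind = small_cohort.individuals
        r = snp_association(small_cohort.genotypes[["rs_focal"]],
                            ind["latent_pheno"])
        beta, se = r.loc["rs_focal", "beta"], r.loc["rs_focal", "se"]
        assert beta == pytest.approx(3.99, abs=3 * se)

    def test_null_outcome(self, small_cohort):
        rng = np.random.default_rng(8)
        y = pd.Series(rng.normal(size=len(small_cohort.individuals)),
                      index=small_cohort.individuals.index)
        r = snp_association(small_cohort.genotypes[["rs_focal"]], y)
        assert abs(r.loc["rs_focal", "beta"] / r.loc["rs_focal", "se"]) < 3

    def test_collinear_covariates_rejected(self, small_cohort):
        ind = small_cohort.individuals
        cov = pd.DataFrame({"a": ind["age"], "b": 2 * ind["age"]})
        with pytest.raises(DataError, match="collinear"):
            snp_association(small_cohort.genotypes[["rs_focal"]],
                            ind["latent_pheno"], covariates=cov)


class TestAdditiveVsDominant:
    @staticmethod
    def _geno(rng, n=4000, maf=0.25):
        return pd.Series(rng.binomial(2, maf, n).astype(float))

    def test_additive_truth_preferred(self):
        rng = np.random.default_rng(21)
        g = self._geno(rng)
        y = pd.Series(1.0 * g + rng.normal(0, 1, len(g)))
        assert compare_additive_dominant(g, y)["recommendation"] == "additive"

    def test_dominant_truth_preferred(self):
        rng = np.random.default_rng(22)
        g = self._geno(rng)
        y = pd.Series(1.0 * (g > 0) + rng.normal(0, 1, len(g)))
        assert compare_additive_dominant(g, y)["recommendation"] == "dominant"

    def test_null_outcome_flags_neither(self):
        rng = np.random.default_rng(23)
        g = self._geno(rng)
        y = pd.Series(rng.normal(0, 1, len(g)))
        assert compare_additive_dominant(g, y)["recommendation"] == "neither"


def test_cross_spouse_mr_recovers_assortment(small_cohort):
    """Wald rescaling on the simulated cohort approximates assort_C."""
    pairs = small_cohort.couple_frame()[["id_a", "id_b"]]
    res = cross_spouse_mr(pairs, small_cohort.individuals,
                          small_cohort.genotypes, "rs_focal", "weekly_units")
    wald = res["wald"]
    assert res["exposure_stage"].beta == pytest.approx(3.99, abs=1.5)
    assert wald.beta == pytest.approx(0.37, abs=3 * wald.se)
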