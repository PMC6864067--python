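"""Spouse-pair derivation: matching, filters, LD pruning, relatedness, ledger."""

import numpy as np
import pandas as pd
import pytest

from assortmr.errors import DataError
from assortmr.pairs import (STEP_ORDER, derive_spouse_pairs,
                            estimate_relatedness, evaluate_derivation,
                            filter_parental_death, filter_same_sex, ld_prune,
                            match_households)


def _record(id, sex="M", **kw):
    base = dict(sex=sex, spouse_cohab=1, years_at_address=10, n_occupants=2,
                n_vehicles=1, accommodation="house", rental="own",
                home_north_km=500, home_east_km=300, centre="C01",
                father_death_age=np.nan, mother_death_age=np.nan)
    base.update(kw)
    return pd.Series(base, name=id)


def _records(*rows):
    df = pd.DataFrame(rows)
    df.index.name = "id"
    return df


class TestHouseholdMatching:
    def test_identical_key_gives_one_pair(self):
        recs = _records(_record("a", "M"), _record("b", "F"))
        pairs, _ = match_households(recs)
        assert len(pairs) == 1

    def test_key_shared_by_three_excluded_entirely(self):
        recs = _records(_record("a"), _record("b"), _record("c"))
        pairs, ledger = match_households(recs)
        assert len(pairs) == 0
        trio = ledger.reasons[ledger.reasons["reason"] == "key_trio"]
        assert sorted(trio["id"]) == ["a", "b", "c"]

    def test_coordinate_off_by_one_km_does_not_match(self):
        recs = _records(_record("a"), _record("b", "F", home_north_km=501))
        pairs, _ = match_households(recs)
        assert len(pairs) == 0

    def test_missing_field_skips_individual(self):
        recs = _records(_record("a"), _record("b", "F", n_vehicles=np.nan))
        pairs, ledger = match_households(recs)
        assert len(pairs) == 0
        assert list(ledger.reasons["reason"]) == ["missing_field"]

    def test_non_cohabiting_not_candidates(self):
        recs = _records(_record("a"), _record("b", "F", spouse_cohab=0))
        pairs, _ = match_households(recs)
        assert len(pairs) == 0


class TestDemographicFilters:
    def test_same_sex_filter(self):
        recs = _records(_record("a", "M"), _record("b", "F"),
                        _record("c", "F"), _record("d", "F"))
        pairs = pd.DataFrame({"id_a": ["a", "c"], "id_b": ["b", "d"]})
        kept, ledger = filter_same_sex(pairs, recs)
        assert list(kept.itertuples(index=False)) == [("a", "b")]
        assert set(ledger.reasons["id"]) == {"c", "d"}

    def test_same_sex_empty_input(self):
        kept, _ = filter_same_sex(pd.DataFrame(columns=["id_a", "id_b"]),
                                  _records(_record("a")))
        assert len(kept) == 0

    @pytest.mark.parametrize(
        "fa,ma,fb,mb,excluded",
        [
            (70, 81, 70, 81, True),        # both parents match -> removed
            (70, 81, 70, 80, False),       # father only -> retained
            (np.nan, np.nan, 70, 81, False),  # missing never matches
            (np.nan, 81, np.nan, 81, False),  # missing father on both sides
        ],
    )
    def test_parental_death_rule(self, fa, ma, fb, mb, excluded):
        recs = _records(
            _record("a", "M", father_death_age=fa, mother_death_age=ma),
            _record("b", "F", father_death_age=fb, mother_death_age=mb))
        pairs = pd.DataFrame({"id_a": ["a"], "id_b": ["b"]})
        kept, _ = filter_parental_death(pairs, recs)
        assert (len(kept) == 0) == excluded


class TestLDPrune:
    def test_perfectly_correlated_neighbours_keep_one(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.3, 200).astype(float)
        geno = pd.DataFrame({"v1": g, "v2": g})
        kept = ld_prune(geno, pd.Series({"v1": 1000, "v2": 2000}))
        assert kept == ["v1"]

    def test_independent_snps_all_kept(self):
        rng = np.random.default_rng(1)
        geno = pd.DataFrame({f"v{i}": rng.binomial(2, 0.4, 500).astype(float)
                             for i in range(5)})
        pos = pd.Series({f"v{i}": 1000 * (i + 1) for i in range(5)})
        kept = ld_prune(geno, pos)
        assert set(kept) == set(geno.columns)

    def test_monomorphic_dropped_first(self):
        geno = pd.DataFrame({"v1": np.ones(50), "v2": np.r_[np.zeros(25), np.ones(25)]})
        kept = ld_prune(geno, pd.Series({"v1": 100, "v2": 200}))
        assert kept == ["v2"]

    def test_correlated_block_leaves_no_high_r2_pair(self):
        """Brute-force check: every retained within-window pair has r2 < 0.1."""
        from assortmr import SimulationConfig, simulate_cohort
        c = simulate_cohort(SimulationConfig(
            n_individuals=600, n_pgs_snps=10, n_ld_block_snps=5,
            ld_block_r2=0.5, seed=9))
        kept = ld_prune(c.genotypes, c.variants["pos"], c.variants["chrom"])
        block = [v for v in kept if v.startswith("ld") or v == "snp0000"]
        assert len(block) == 1  # one survivor per correlated block
        pos = c.variants["pos"]
        G = c.genotypes
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                same_chr = c.variants.loc[a, "chrom"] == c.variants.loc[b, "chrom"]
                if same_chr and abs(pos[a] - pos[b]) < 50_000:
                    r = np.corrcoef(G[a], G[b])[0, 1]
                    assert r * r < 0.1


class TestRelatedness:
    def test_identical_genotypes_estimate_near_one(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, rng.uniform(0.1, 0.5, 500), size=(40, 500)).astype(float)
        geno = pd.DataFrame(g, index=[f"i{k}" for k in range(40)],
                            columns=[f"v{j}" for j in range(500)])
        geno.loc["twin"] = geno.loc["i0"]
        # allele frequencies come from the candidate sample, so estimate the
        # MZ-like pair alongside ordinary unrelated pairs
        pairs = pd.DataFrame(
            {"id_a": ["i0"] + [f"i{k}" for k in range(1, 39, 2)],
             "id_b": ["twin"] + [f"i{k}" for k in range(2, 40, 2)]})
        rel = estimate_relatedness(geno, pairs)
        assert rel.iloc[0] == pytest.approx(1.0, abs=0.15)
        assert rel.iloc[1:].abs().mean() < 0.15

    def test_unrelated_rarely_exceed_threshold(self, decoy_cohort):
        truth = decoy_cohort.couple_frame()
        pairs = truth[["id_a", "id_b"]].head(1000).reset_index(drop=True)
        markers = [v for v in decoy_cohort.genotypes.columns if v != "rs_focal"]
        rel = estimate_relatedness(decoy_cohort.genotypes, pairs, markers)
        assert abs(rel.mean()) < 0.01
        assert (rel.abs() > 0.1).mean() < 0.01  # var ~ 1/M at M=1000

    def test_no_informative_markers_raises(self):
        geno = pd.DataFrame({"v1": [2.0, 2.0]}, index=["a", "b"])
        with pytest.raises(DataError):
            estimate_relatedness(geno, pd.DataFrame({"id_a": ["a"], "id_b": ["b"]}))


class TestFullDerivation:
    def test_recall_and_decoy_reasons(self, decoy_cohort, decoy_derivation):
        ev = evaluate_derivation(decoy_derivation, decoy_cohort.truth,
                                 decoy_cohort.individuals)
        assert ev["recall"] >= 0.99
        assert ev["n_false_pairs"] == 0
        assert ev["decoy_outcomes"]["same_sex"]["reasons"] == ["same_sex"]
        assert ev["decoy_outcomes"]["sib"]["reasons"] == ["relatedness"]
        assert ev["decoy_outcomes"]["key_trio"]["reasons"] == ["key_trio"]
        for cls in ("same_sex", "sib", "key_trio"):
            assert ev["decoy_outcomes"][cls]["n_retained"] == 0

    def test_sib_decoys_fall_at_relatedness_step_not_before(self, decoy_cohort,
                                                            decoy_derivation):
        """Ledger order: sibs survive matching and demographic filters."""
        ledger = decoy_derivation.ledger
        sib_ids = set(decoy_cohort.truth.loc[
            decoy_cohort.truth["decoy_class"] == "sib", "id_a"])
        reasons = ledger.reasons.set_index("id")
        for sid in sib_ids:
            assert reasons.loc[sid, "step"] == "relatedness"
            assert (ledger.step_index("relatedness")
                    == ledger.step_index(STEP_ORDER[-1]))

    def test_derivation_idempotent_on_own_output(self, decoy_cohort, decoy_derivation):
        """Re-deriving from only the retained individuals changes nothing."""
        kept_ids = pd.unique(np.r_[decoy_derivation.pairs["id_a"],
                                   decoy_derivation.pairs["id_b"]])
        again = derive_spouse_pairs(
            decoy_cohort.individuals.loc[kept_ids],
            decoy_cohort.genotypes.loc[kept_ids],
            positions=decoy_cohort.variants["pos"],
            chrom=decoy_cohort.variants["chrom"])
        a = set(map(tuple, decoy_derivation.pairs.to_numpy()))
        b = set(map(tuple, again.pairs.to_numpy()))
        assert a == b

    def test_cohort_of_singletons_yields_empty_set(self):
        recs = _records(*[
            _record(f"s{i}", "M", home_north_km=i * 7, home_east_km=i * 3)
            for i in range(6)])
        geno = pd.DataFrame(
            np.random.default_rng(0).binomial(2, 0.3, (6, 20)).astype(float),
            index=recs.index, columns=[f"v{j}" for j in range(20)])
        out = derive_spouse_pairs(recs, geno)
        assert len(out) == 0

    def test_ledger_counts_are_consistent(self, decoy_derivation):
        s = decoy_derivation.ledger.summary()
        assert list(s["step"]) == list(STEP_ORDER)
        assert (s["n_pairs_in"] - s["n_excluded"] == s["n_pairs_out"]).all()
        # each step's input is the previous step's output
        assert (s["n_pairs_out"].iloc[:-1].to_numpy()
                == s["n_pairs_in"].iloc[1:].to_numpy()).all()
        assert s["n_pairs_out"].iloc[-1] == len(decoy_derivation.pairs)
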