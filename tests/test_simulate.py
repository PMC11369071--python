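"""Synthetic-data generators: reproducibility and generating-truth recovery."""

import numpy as np
import pandas as pd
import pytest

from comorbkit.simulate import (
    FamilySimParams,
    PrsSimParams,
    SumstatSimParams,
    TwinSimParams,
    simulate_family_cohort,
    simulate_prs_cohort,
    simulate_sumstats,
    simulate_twin_pairs,
)
from comorbkit.tetrachoric import CellCounts2x2, estimate_tetrachoric, twin_correlations
from comorbkit.twinmodel import CrossTraitCorrelations, VarianceComponents


class TestReproducibility:
    def test_twin_pairs(self):
        p = TwinSimParams(n_mz=500, n_dz=500, seed=42)
        pd.testing.assert_frame_equal(simulate_twin_pairs(p), simulate_twin_pairs(p))

    def test_family_cohort(self):
        p = FamilySimParams(n_families=500, seed=42)
        ped1, phen1 = simulate_family_cohort(p)
        ped2, phen2 = simulate_family_cohort(p)
        pd.testing.assert_frame_equal(ped1, ped2)
        pd.testing.assert_frame_equal(phen1, phen2)

    def test_sumstats(self):
        p = SumstatSimParams(M=1000, seed=42)
        ss1, ld1 = simulate_sumstats(p)
        ss2, ld2 = simulate_sumstats(p)
        pd.testing.assert_frame_equal(ss1, ss2)
        pd.testing.assert_frame_equal(ld1, ld2)

    def test_prs_cohort(self):
        p = PrsSimParams(n=1000, seed=42)
        pd.testing.assert_frame_equal(
            simulate_prs_cohort(p)["cohort"], simulate_prs_cohort(p)["cohort"]
        )

    def test_seed_changes_output(self):
        a = simulate_twin_pairs(TwinSimParams(n_mz=500, n_dz=500, seed=1))
        b = simulate_twin_pairs(TwinSimParams(n_mz=500, n_dz=500, seed=2))
        assert not a.equals(b)


class TestTwinGenerator:
    def test_no_familial_component_gives_zero_correlations(self):
        p = TwinSimParams(
            n_mz=20_000, n_dz=20_000,
            components=VarianceComponents(a2=0.0, e2=1.0), prevalence=0.3, seed=3,
        )
        pairs = simulate_twin_pairs(p)
        for z in ("MZ", "DZ"):
            est = twin_correlations(pairs, "trait1", zygosity=z)
            assert est.r == pytest.approx(0.0, abs=3 * est.se_r)

    def test_additive_sharing_recovered(self):
        p = TwinSimParams(
            n_mz=50_000, n_dz=50_000,
            components=VarianceComponents(a2=0.8, e2=0.2), prevalence=0.2, seed=4,
        )
        pairs = simulate_twin_pairs(p)
        mz = twin_correlations(pairs, "trait1", zygosity="MZ")
        dz = twin_correlations(pairs, "trait1", zygosity="DZ")
        assert mz.r == pytest.approx(0.8, abs=3 * mz.se_r)
        assert dz.r == pytest.approx(0.4, abs=3 * dz.se_r)

    def test_rare_prevalence_realized(self):
        p = TwinSimParams(
            n_mz=100_000, n_dz=100_000,
            components=VarianceComponents(a2=0.75, e2=0.25), prevalence=0.007, seed=5,
        )
        pairs = simulate_twin_pairs(p)
        prev = 0.5 * (pairs["trait1_1"].mean() + pairs["trait1_2"].mean())
        se = np.sqrt(0.007 * 0.993 / (2 * 200_000))
        assert prev == pytest.approx(0.007, abs=4 * se)

    def test_bivariate_cross_structure(self):
        p = TwinSimParams(
            n_mz=50_000, n_dz=50_000,
            components=VarianceComponents(a2=0.6, e2=0.4),
            components2=VarianceComponents(a2=0.5, e2=0.5),
            cross=CrossTraitCorrelations(r_a=0.5, r_e=0.2),
            prevalence=0.25, prevalence2=0.3, seed=6,
        )
        pairs = simulate_twin_pairs(p)
        # cross-twin cross-trait: MZ expects r_a*a1*a2, DZ half of it
        expected_mz = 0.5 * np.sqrt(0.6 * 0.5)
        mz = twin_correlations(pairs, "trait1", "trait2", zygosity="MZ")
        dz = twin_correlations(pairs, "trait1", "trait2", zygosity="DZ")
        assert mz.r == pytest.approx(expected_mz, abs=3 * mz.se_r)
        assert dz.r == pytest.approx(expected_mz / 2, abs=3 * dz.se_r)

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            TwinSimParams(n_mz=10, n_dz=10, components=VarianceComponents(a2=0.9, e2=0.5))


class TestFamilyGenerator:
    def test_null_conditional_or(self):
        ped, phen = simulate_family_cohort(
            FamilySimParams(n_families=30_000, conditional_or=1.0, seed=7)
        )
        d = phen[phen["individual_id"].str.startswith("C")]
        tab = pd.crosstab(d["trait1"], d["trait2"])
        or_hat = (tab.loc[1, 1] * tab.loc[0, 0]) / (tab.loc[1, 0] * tab.loc[0, 1])
        assert np.log(or_hat) == pytest.approx(0.0, abs=0.35)

    def test_prevalences_realized(self):
        ped, phen = simulate_family_cohort(
            FamilySimParams(
                n_families=100_000, prevalence1=0.007, prevalence2=0.18, seed=8
            )
        )
        kids = phen[phen["individual_id"].str.startswith("C")]
        assert kids["trait1"].mean() == pytest.approx(0.007, abs=0.001)
        assert kids["trait2"].mean() == pytest.approx(0.18, abs=0.01)

    def test_liability_variant_kinship_gradient(self):
        """Full sibs share half the additive variance, maternal half sibs a
        quarter: with a2 = 0.75 the implied sib liability correlations are
        0.375 and 0.1875, read back through tetrachoric estimates."""
        from comorbkit.coaggregation import build_relative_pairs

        ped, phen = simulate_family_cohort(
            FamilySimParams(
                n_families=60_000, trait_model="liability", a2=0.75,
                prevalence1=0.3, prevalence2=0.3, p_new_father=0.3, seed=9,
            )
        )
        phen_ix = phen.set_index("individual_id")["trait1"]
        for rel, expected in (("full-sibling", 0.375), ("maternal-half-sibling", 0.1875)):
            pairs = build_relative_pairs(ped, rel)
            # deduplicate ordered pairs (keep one direction)
            mask = pairs["proband_id"] < pairs["relative_id"]
            pairs = pairs[mask]
            x = phen_ix.loc[pairs["proband_id"]].to_numpy()
            y = phen_ix.loc[pairs["relative_id"]].to_numpy()
            est = estimate_tetrachoric(CellCounts2x2.from_binary(x, y))
            assert est.r == pytest.approx(expected, abs=3 * est.se_r + 0.01), rel


class TestSumstatGenerator:
    def test_null_heritability_noiseless_chi2_is_one(self):
        ss, _ = simulate_sumstats(SumstatSimParams(M=2000, h2_obs=0.0, noiseless=True, seed=1))
        assert np.allclose(ss["z"] ** 2, 1.0)

    def test_noiseless_chi2_on_polygenic_line(self):
        p = SumstatSimParams(M=2000, N=50_000, h2_obs=0.2, noiseless=True, seed=2)
        ss, ld = simulate_sumstats(p)
        expected = 1.0 + p.N * p.h2_obs * ld["l2"] / p.M
        assert np.allclose(ss["z"] ** 2, expected)

    def test_zero_rg_cross_products_average_out(self):
        p = SumstatSimParams(M=4000, h2_obs=0.2, rg=0.0, noiseless=True, seed=3)
        ss, _ = simulate_sumstats(p)
        duo_means = (ss["z"] * ss["z2"]).to_numpy().reshape(-1, 2).mean(axis=1)
        assert np.allclose(duo_means, 0.0, atol=1e-10)

    def test_ld_scores_positive(self):
        _, ld = simulate_sumstats(SumstatSimParams(M=2000, seed=4))
        assert (ld["l2"] >= 1.0).all()


class TestPrsGenerator:
    def test_scores_standardized(self):
        c = simulate_prs_cohort(PrsSimParams(n=5000, seed=1))["cohort"]
        assert c["score"].mean() == pytest.approx(0.0, abs=1e-10)
        assert c["score"].std() == pytest.approx(1.0, abs=1e-3)

    def test_dosage_weight_consistency(self):
        from comorbkit.prs import compute_scores

        bundle = simulate_prs_cohort(PrsSimParams(n=300, n_variants=50, seed=2))
        recomputed = compute_scores(bundle["weights"], bundle["dosages"])
        np.testing.assert_allclose(
            recomputed["score"].to_numpy(), bundle["cohort"]["score"].to_numpy(), atol=1e-10
        )

    def test_twin_clustering_structure(self):
        c = simulate_prs_cohort(PrsSimParams(n=1000, twin_pairs=True, seed=3))["cohort"]
        assert c["cluster_id"].value_counts().max() == 2
        assert c["cluster_id"].nunique() == 500
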