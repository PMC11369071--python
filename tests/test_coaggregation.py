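"""Relative-pair construction and familial odds ratios."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from comorbkit.coaggregation import (
    ORResult,
    apply_cohort_filters,
    build_relative_pairs,
    fit_pair_or,
)
from comorbkit.simulate import FamilySimParams, simulate_family_cohort


def brute_force_pairs(ped, relationship):
    """Independent double-loop classification of every ordered pair."""
    rows = ped.set_index("individual_id")[["father_id", "mother_id"]].to_dict("index")
    out = []
    for p, pp in rows.items():
        for r, rr in rows.items():
            if p == r:
                continue
            same_m = pd.notna(pp["mother_id"]) and pp["mother_id"] == rr["mother_id"]
            same_f = pd.notna(pp["father_id"]) and pp["father_id"] == rr["father_id"]
            if relationship == "full-sibling" and same_m and same_f:
                out.append((p, r))
            elif relationship == "maternal-half-sibling" and same_m and not same_f:
                out.append((p, r))
            elif relationship == "paternal-half-sibling" and same_f and not same_m:
                out.append((p, r))
    return sorted(out)


class TestPairConstruction:
    def test_three_full_sibs_give_six_ordered_pairs(self, small_pedigree):
        pairs = build_relative_pairs(small_pedigree, "full-sibling")
        assert len(pairs) == 6
        assert set(pairs["proband_id"]) == {"A1", "A2", "A3"}
        assert pairs["cluster_id"].nunique() == 1

    def test_maternal_half_sibs(self, small_pedigree):
        pairs = build_relative_pairs(small_pedigree, "maternal-half-sibling")
        assert len(pairs) == 2
        assert set(zip(pairs["proband_id"], pairs["relative_id"])) == {
            ("B1", "B2"), ("B2", "B1"),
        }

    def test_paternal_half_sibs(self, small_pedigree):
        pairs = build_relative_pairs(small_pedigree, "paternal-half-sibling")
        assert set(zip(pairs["proband_id"], pairs["relative_id"])) == {
            ("C1", "C2"), ("C2", "C1"),
        }

    def test_parent_pairs_cluster_on_parent(self, small_pedigree):
        pairs = build_relative_pairs(small_pedigree, "parent")
        a1 = pairs[pairs["proband_id"] == "A1"]
        assert set(a1["relative_id"]) == {"F1", "M1"}
        f1 = pairs[pairs["relative_id"] == "F1"]
        assert f1["cluster_id"].nunique() == 1

    def test_self_pairs(self, small_pedigree):
        pairs = build_relative_pairs(small_pedigree, "self")
        assert len(pairs) == len(small_pedigree)
        assert (pairs["proband_id"] == pairs["relative_id"]).all()

    def test_unknown_relationship(self, small_pedigree):
        with pytest.raises(ValueError):
            build_relative_pairs(small_pedigree, "cousin")

    def test_own_parent_rejected(self):
        bad = pd.DataFrame(
            {"individual_id": ["X"], "father_id": ["X"], "mother_id": [None]}
        )
        with pytest.raises(ValueError):
            build_relative_pairs(bad, "self")

    @pytest.mark.parametrize(
        "relationship", ["full-sibling", "maternal-half-sibling", "paternal-half-sibling"]
    )
    def test_matches_brute_force_on_synthetic_pedigree(self, relationship):
        ped, _ = simulate_family_cohort(
            FamilySimParams(n_families=100, p_new_father=0.3, p_shared_father=0.2, seed=13)
        )
        pairs = build_relative_pairs(ped, relationship)
        got = sorted(zip(pairs["proband_id"], pairs["relative_id"]))
        assert got == brute_force_pairs(ped, relationship)


class TestOddsRatios:
    @staticmethod
    def _table_phenotypes():
        """2x2 counts (40, 10, 20, 30) as self-pair data."""
        n11, n10, n01, n00 = 40, 10, 20, 30
        ids = [f"P{i}" for i in range(n11 + n10 + n01 + n00)]
        t1 = [1] * (n11 + n10) + [0] * (n01 + n00)
        t2 = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
        phen = pd.DataFrame({"individual_id": ids, "trait1": t1, "trait2": t2})
        pairs = pd.DataFrame(
            {"proband_id": ids, "relative_id": ids, "cluster_id": ids}
        )
        return pairs, phen

    def test_crude_or_equals_cross_product_ratio(self):
        pairs, phen = self._table_phenotypes()
        res = fit_pair_or(pairs, phen, "trait1", "trait2", adjustment=0)
        assert res.odds_ratio == pytest.approx((40 * 30) / (10 * 20), abs=1e-8)
        assert res.ci_low < res.odds_ratio < res.ci_high

    def test_null_association(self):
        ped, phen = simulate_family_cohort(
            FamilySimParams(n_families=20_000, conditional_or=1.0, seed=14)
        )
        pairs = build_relative_pairs(ped, "self")
        res = fit_pair_or(pairs, phen, "trait1", "trait2", adjustment=0)
        assert res.ci_low < 1.0 < res.ci_high

    def test_constant_exposure_rejected(self):
        pairs, phen = self._table_phenotypes()
        phen["trait1"] = 1
        with pytest.raises(ValueError):
            fit_pair_or(pairs, phen, "trait1", "trait2")

    def test_singleton_clusters_match_heteroskedastic_se(self):
        rng = np.random.default_rng(15)
        n = 800
        x = rng.integers(0, 2, n).astype(float)
        y = (rng.random(n) < 0.2 + 0.2 * x).astype(float)
        phen = pd.DataFrame(
            {"individual_id": [f"i{j}" for j in range(n)], "e": x, "o": y}
        )
        pairs = pd.DataFrame(
            {
                "proband_id": phen["individual_id"],
                "relative_id": phen["individual_id"],
                "cluster_id": phen["individual_id"],
            }
        )
        res = fit_pair_or(pairs, phen, "e", "o", adjustment=0)
        X = pd.DataFrame({"const": 1.0, "exposure": x})
        hc0 = sm.GLM(y, X, family=sm.families.Binomial()).fit(cov_type="HC0")
        k = 2
        factor = np.sqrt(n / (n - 1) * (n - 1) / (n - k))
        assert res.robust_se == pytest.approx(float(hc0.bse["exposure"]) * factor, rel=1e-6)

    def test_attenuation_with_decreasing_relatedness(self):
        """Under a shared liability cause the within-individual association
        exceeds the full-sibling one, which exceeds the half-sibling one."""
        ped, phen = simulate_family_cohort(
            FamilySimParams(
                n_families=80_000, trait_model="liability", a2=0.8,
                prevalence1=0.1, prevalence2=0.1, p_new_father=0.25, seed=16,
            )
        )
        ors = {}
        for rel in ("self", "full-sibling", "maternal-half-sibling"):
            pairs = build_relative_pairs(ped, rel)
            ors[rel] = fit_pair_or(pairs, phen, "trait1", "trait2", adjustment=0).odds_ratio
        assert ors["self"] > ors["full-sibling"] > ors["maternal-half-sibling"]
        assert ors["maternal-half-sibling"] > 0.9  # still positive familiality


class TestFilters:
    def test_birth_year_window(self, small_pedigree):
        ped = small_pedigree.copy()
        ped.loc[ped["individual_id"] == "A1", "birth_year"] = 1950.0
        out = apply_cohort_filters(ped, birth_year_range=(1987, 2014))
        assert "A1" not in set(out["individual_id"])
        # parents with missing birth year are retained
        assert "M1" in set(out["individual_id"])

    def test_exclusion_flags(self, small_pedigree):
        flags = pd.DataFrame({"individual_id": ["A2"], "emigrated": [True]})
        out = apply_cohort_filters(small_pedigree, birth_year_range=None, exclude_flags=flags)
        assert "A2" not in set(out["individual_id"])
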