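import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chromacross.cross_effects import (
    decompose_effects,
    dunn_posthoc,
    litter_size_tests,
    mortality_fraction,
    punnett_offspring,
    replicate_proportion_summary,
    sex_ratio_test,
    viability_chisq,
    weight_contrasts,
)
from chromacross.synthetic_data import (
    CrossDesign,
    EffectParams,
    simulate_conceptus_table,
    simulate_litters,
)

STANDARD_DESIGNS = [
    CrossDesign("WT", "WT", 800),
    CrossDesign("WT", "KO", 800),
    CrossDesign("KO", "WT", 800),
    CrossDesign("KO", "KO", 800),
    CrossDesign("HET", "KO", 1600),
]


@pytest.fixture(scope="module")
def standard_table():
    return simulate_conceptus_table(STANDARD_DESIGNS, EffectParams(seed=11))


class TestPunnett:
    def test_ko_dam_wt_sire_forces_genotypes(self):
        dist = punnett_offspring("KO", "WT")
        assert dist == {("M", "XKO_Y"): 0.5, ("F", "X_XKO"): 0.5}

    def test_het_dam_ko_sire_splits_halves(self):
        dist = punnett_offspring("HET", "KO")
        assert dist[("M", "XY")] == dist[("M", "XKO_Y")] == 0.25
        assert dist[("F", "X_XKO")] == dist[("F", "XKO_XKO")] == 0.25

    def test_wt_cross_yields_no_ko_alleles(self):
        dist = punnett_offspring("WT", "WT")
        assert set(g for _, g in dist) == {"XY", "XX"}

    def test_het_sire_rejected(self):
        with pytest.raises(ValueError, match="hemizygous"):
            punnett_offspring("WT", "HET")

    @given(st.sampled_from(["WT", "HET", "KO"]), st.sampled_from(["WT", "KO"]))
    @settings(max_examples=20, deadline=None)
    def test_distribution_sums_to_one_with_xlinked_support(self, dam, sire):
        dist = punnett_offspring(dam, sire)
        assert sum(dist.values()) == pytest.approx(1.0)
        assert sum(p for (s, _), p in dist.items() if s == "M") == pytest.approx(0.5)
        if sire == "WT":
            # a WT sire contributes a functional X to every daughter
            assert ("F", "XKO_XKO") not in dist


class TestViability:
    def test_identical_to_reference_is_zero(self, standard_table):
        res = viability_chisq(standard_table, ("WT", "WT"), ("WT", "WT"))
        assert res.chisq.statistic == 0.0

    def test_hand_computed_2x2(self):
        # 12 adverse / 125 vs reference 3 / 130
        table = pd.DataFrame({
            "dam_genotype": ["KO"] * 125 + ["WT"] * 130,
            "sire_genotype": ["KO"] * 125 + ["WT"] * 130,
            "outcome": (["resorbed"] * 12 + ["normal"] * 113
                        + ["resorbed"] * 3 + ["normal"] * 127),
        })
        res = viability_chisq(table, ("KO", "KO"))
        e_adv = 125 * 3 / 130
        e_norm = 125 * 127 / 130
        oracle = (12 - e_adv) ** 2 / e_adv + (113 - e_norm) ** 2 / e_norm
        assert res.chisq.statistic == pytest.approx(oracle, abs=1e-9)
        assert res.adverse_fraction == pytest.approx(12 / 125)

    def test_koxko_adverse_about_fourfold(self):
        designs = [CrossDesign("WT", "WT", 10_000), CrossDesign("KO", "KO", 10_000)]
        tab = simulate_conceptus_table(designs, EffectParams(seed=12))
        res = viability_chisq(tab, ("KO", "KO"))
        ratio = res.adverse_fraction / res.reference_fraction
        assert ratio == pytest.approx(9.6 / 2.3, abs=0.9)
        assert res.chisq.pvalue < 1e-6


class TestWeightContrasts:
    def test_identical_groups_give_zero_h(self):
        tab = pd.DataFrame({
            "dam_genotype": ["WT"] * 20, "sire_genotype": ["WT"] * 20,
            "sex": ["M"] * 10 + ["F"] * 10,
            "zygote_genotype": ["XY"] * 10 + ["XX"] * 10,
            "outcome": "normal",
            "fetal_weight_g": list(range(10)) * 2,
            "placental_weight_g": 0.1,
        })
        res = weight_contrasts(tab, by=("sex",))
        assert res.statistic == pytest.approx(0.0, abs=1e-9)

    def test_all_tied_values(self):
        tab = pd.DataFrame({
            "dam_genotype": "WT", "sire_genotype": "WT",
            "sex": ["M"] * 5 + ["F"] * 5, "zygote_genotype": "XY",
            "outcome": "normal", "fetal_weight_g": 0.25,
            "placental_weight_g": 0.1}, index=range(10))
        res = weight_contrasts(tab, by=("sex",))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_h_matches_bruteforce_rank_oracle(self):
        groups = {"a": np.array([1.2, 3.4, 2.2, 5.0]),
                  "b": np.array([2.1, 2.1, 6.7]),
                  "c": np.array([0.3, 4.4, 4.4, 4.4, 8.0])}
        pooled = np.concatenate(list(groups.values()))
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        h = 12 / (n * (n + 1)) * sum(
            len(v) * (ranks[i:i + len(v)].mean() - (n + 1) / 2) ** 2
            for v, i in zip(groups.values(),
                            np.cumsum([0] + [len(v) for v in groups.values()])))
        _, counts = np.unique(pooled, return_counts=True)
        h /= 1 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
        got, _ = stats.kruskal(*groups.values())
        assert got == pytest.approx(h, rel=1e-12)

    def test_kruskal_null_calibration(self):
        rng = np.random.default_rng(13)
        rejections = 0
        n_sim = 4000
        for _ in range(n_sim):
            _, p = stats.kruskal(rng.normal(size=15), rng.normal(size=15),
                                 rng.normal(size=15))
            rejections += p < 0.05
        assert abs(rejections / n_sim - 0.05) < 0.012

    def test_dunn_z_matches_hand_computation(self):
        samples = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([4.0, 5.0, 6.0])}
        out = dunn_posthoc(samples)
        # ranks: a -> 1,2,3 (mean 2); b -> 4,5,6 (mean 5); no ties
        se = np.sqrt(6 * 7 / 12 * (1 / 3 + 1 / 3))
        assert out["z"].iloc[0] == pytest.approx((2 - 5) / se)
        assert out["p_adj"].iloc[0] >= out["p_raw"].iloc[0]

    def test_posthoc_on_simulated_weights(self, standard_table):
        res = weight_contrasts(standard_table)
        assert res.pvalue < 1e-6  # parental deficits separate the crosses
        assert set(res.posthoc.columns) >= {"group1", "group2", "z", "p_adj"}


class TestDecomposeEffects:
    def test_recovers_simulated_deficits(self):
        params = EffectParams(paternal_deficit=0.10, maternal_deficit=0.05,
                              zygotic_deficit=0.0, seed=14)
        designs = [CrossDesign(d, s, 2000) for d, s in
                   [("KO", "WT"), ("KO", "KO"), ("WT", "KO"), ("HET", "KO")]]
        tab = simulate_conceptus_table(designs, params)
        est = decompose_effects(tab, n_boot=300, seed=1,
                                stratify_by_litter=False)
        assert est.paternal.ci_low <= 0.10 <= est.paternal.ci_high
        assert est.maternal.ci_low <= 0.05 <= est.maternal.ci_high
        assert abs(est.zygotic.estimate) < 0.02

    def test_null_gives_zero_effects(self):
        params = EffectParams(paternal_deficit=0, maternal_deficit=0,
                              zygotic_deficit=0, seed=15)
        designs = [CrossDesign(d, s, 1500) for d, s in
                   [("KO", "WT"), ("KO", "KO"), ("WT", "KO"), ("HET", "KO")]]
        est = decompose_effects(simulate_conceptus_table(designs, params),
                                n_boot=200, seed=2, stratify_by_litter=False)
        for e in (est.paternal, est.maternal, est.zygotic):
            assert abs(e.estimate) < 0.025

    def test_invariant_to_global_weight_rescaling(self, standard_table):
        scaled = standard_table.copy()
        scaled["fetal_weight_g"] *= 1000  # grams -> milligrams
        a = decompose_effects(standard_table, n_boot=50, seed=3)
        b = decompose_effects(scaled, n_boot=50, seed=3)
        assert b.paternal.estimate == pytest.approx(a.paternal.estimate)
        assert b.maternal.estimate == pytest.approx(a.maternal.estimate)
        assert b.zygotic.estimate == pytest.approx(a.zygotic.estimate)

    def test_cis_contain_point_estimates(self, standard_table):
        est = decompose_effects(standard_table, n_boot=300, seed=4)
        for e in (est.paternal, est.maternal, est.zygotic, est.combined_parental):
            assert e.ci_low <= e.estimate <= e.ci_high

    def test_missing_cross_named(self, standard_table):
        broken = standard_table[standard_table["dam_genotype"] != "HET"]
        with pytest.raises(ValueError, match="HET x KO"):
            decompose_effects(broken, n_boot=10)


class TestSexRatio:
    def test_even_counts_give_zero(self):
        assert sex_ratio_test(50, 50).statistic == 0.0

    def test_hand_computed_goodness_of_fit(self):
        res = sex_ratio_test(60, 40)
        assert res.statistic == pytest.approx((60 - 50) ** 2 / 50 * 2)

    def test_null_calibration(self):
        rng = np.random.default_rng(16)
        rej = sum(sex_ratio_test(int(m), 400 - int(m)).pvalue < 0.05
                  for m in rng.binomial(400, 0.5, size=3000))
        assert abs(rej / 3000 - 0.05) < 0.015


class TestLitterStats:
    def test_identical_groups_symmetric_u(self):
        sizes = [6.0, 7.0, 8.0, 9.0, 5.0]
        res = litter_size_tests(sizes, sizes)
        assert res["mannwhitney_u"] == len(sizes) ** 2 / 2
        assert res["mannwhitney_p"] == pytest.approx(1.0)

    def test_exact_p_for_separated_small_groups(self):
        res = litter_size_tests([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # complete separation with n=m=3: exact two-sided p = 2/C(6,3) = 0.1
        assert res["mannwhitney_p"] == pytest.approx(0.1)

    def test_shapiro_flags_zero_inflated_litters(self):
        rng = np.random.default_rng(17)
        flagged = 0
        for _ in range(200):
            # KO-like: an excess of single-pup litters among 37
            sizes = np.concatenate([1 + rng.poisson(7, 29), np.ones(8)])
            flagged += stats.shapiro(sizes).pvalue < 0.05
        assert flagged / 200 >= 0.95

    def test_minimum_group_size(self):
        with pytest.raises(ValueError):
            litter_size_tests([5, 6], [7, 8, 9])


class TestMortalityAndProportions:
    def test_fraction_of_flagged_litters(self):
        lit = pd.DataFrame({"sire_genotype": ["WT"] * 4,
                            "any_dead": [True, False, False, True]})
        out = mortality_fraction(lit)
        assert out["mortality_fraction"].iloc[0] == 0.5

    def test_all_alive_is_zero(self):
        lit = simulate_litters({"WT": 50}, dead_prob={"WT": 0.0}, seed=5)
        assert mortality_fraction(lit)["mortality_fraction"].iloc[0] == 0.0

    def test_group_fractions_recovered(self):
        lit = simulate_litters({"WT": 500, "KO": 500},
                               dead_prob={"WT": 0.10, "KO": 0.18}, seed=6)
        out = mortality_fraction(lit).set_index("sire_genotype")
        for g, p in (("WT", 0.10), ("KO", 0.18)):
            se = np.sqrt(p * (1 - p) / 500)
            assert abs(out.loc[g, "mortality_fraction"] - p) < 3 * se

    def test_replicate_percentages(self):
        out = replicate_proportion_summary([50, 60, 70], [100, 100, 100])
        assert out["mean"] == pytest.approx(60.0)
        assert out["sd"] == pytest.approx(10.0)

    def test_single_replicate_has_no_sd(self):
        assert replicate_proportion_summary([5], [10])["sd"] is None

    def test_successes_bounded_by_totals(self):
        with pytest.raises(ValueError):
            replicate_proportion_summary([11], [10])
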