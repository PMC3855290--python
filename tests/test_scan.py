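"""The two-locus statistical core: contrasts, F-tests, thresholds, scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_matrix, random_genotypes
from snpepi.scan import (
    EFFECT_TYPES,
    MonomorphicLocusError,
    TwoLocusModel,
    bonferroni,
    build_pair_design,
    contribution_rate,
    locus_contrasts,
    run_scan,
    single_locus_scan,
)
from snpepi.scan import test_pair as fit_pair
from snpepi.simdata import PlantedEpistasis, SimulationConfig, simulate_cohort


# ---------------------------------------------------------------------------
# contrasts / design

def test_contrasts_at_hwe_half_frequencies_are_classical():
    # genotype frequencies (1/4, 1/2, 1/4), i.e. HWE with p = q = 0.5
    g = np.repeat([0.0, 1.0, 2.0], [10, 20, 10])
    a, d = locus_contrasts(g)
    np.testing.assert_allclose(a, np.repeat([-1.0, 0.0, 1.0], [10, 20, 10]))
    np.testing.assert_allclose(
        d, np.repeat([-0.5, 0.5, -0.5], [10, 20, 10]), atol=1e-12)


def test_two_genotype_classes_leave_dominance_undefined():
    rng = np.random.default_rng(2)
    g1 = rng.choice([0.0, 1.0], size=60)   # two classes only
    g2 = random_genotypes(rng, 60, 0.4)
    design = build_pair_design(g1, g2)
    assert design.d1 is None and design.d2 is not None
    rng = np.random.default_rng(0)
    res = fit_pair(design, rng.normal(size=60))
    assert not res.per_effect["DA"]["testable"]
    assert not res.per_effect["DD"]["testable"]
    assert res.per_effect["AA"]["testable"]
    assert res.per_effect["AD"]["testable"]


def test_monomorphic_locus_rejected():
    with pytest.raises(MonomorphicLocusError):
        build_pair_design(np.zeros(20), np.tile([0.0, 1], 10))


@pytest.mark.parametrize("seed", range(10))
def test_contrast_orthogonality_under_random_frequencies(seed):
    rng = np.random.default_rng(seed)
    g = random_genotypes(rng, 200, rng.uniform(0.15, 0.5))
    design = build_pair_design(g, random_genotypes(rng, 200, 0.4))
    for name, value in design.orthogonality_residuals().items():
        assert abs(value) < 1e-10, name


def test_complete_case_within_pair():
    g1 = np.array([0.0, 1, 2, np.nan, 1, 0, 2, 1])
    g2 = np.array([2.0, 1, 0, 1, np.nan, 0, 1, 2])
    design = build_pair_design(g1, g2)
    assert design.n_used == 6
    assert design.mask.tolist() == [True, True, True, False, False,
                                    True, True, True]


# ---------------------------------------------------------------------------
# single-pair tests

def test_purely_additive_surface_gives_null_interaction():
    rng = np.random.default_rng(1)
    g1 = random_genotypes(rng, 90, 0.5)
    g2 = random_genotypes(rng, 90, 0.4)
    y = 1.5 + 2.0 * g1 - 0.7 * g2          # no interaction, no noise
    res = fit_pair(build_pair_design(g1, g2), y)
    for e in EFFECT_TYPES:
        assert res.per_effect[e]["ss"] == pytest.approx(0.0, abs=1e-16)
    assert res.p_overall == pytest.approx(1.0)


def _balanced_design(r=7, seed=3):
    """Balanced 3x3 layout, r individuals per genotype cell."""
    g1 = np.repeat([0.0, 1, 2], 3 * r)
    g2 = np.tile(np.repeat([0.0, 1, 2], r), 3)
    y = np.random.default_rng(seed).normal(size=9 * r)
    return g1, g2, y, r


def test_aa_equals_linear_by_linear_anova_contrast():
    g1, g2, y, r = _balanced_design()
    res = fit_pair(build_pair_design(g1, g2), y)
    # classical orthogonal-polynomial contrast on the 3x3 cell totals
    totals = np.array([[y[(g1 == i) & (g2 == j)].sum() for j in range(3)]
                       for i in range(3)])
    w = np.outer([-1, 0, 1], [-1, 0, 1])
    ss_contrast = (w * totals).sum() ** 2 / (r * (w ** 2).sum())
    assert res.per_effect["AA"]["ss"] == pytest.approx(ss_contrast, rel=1e-10)


def test_effect_ss_sum_to_overall_in_balanced_orthogonal_case():
    g1, g2, y, _ = _balanced_design(r=6, seed=9)
    res = fit_pair(build_pair_design(g1, g2), y)
    total = sum(res.per_effect[e]["ss"] for e in EFFECT_TYPES)
    assert total == pytest.approx(res.ss_overall, rel=1e-8)


def test_matches_statsmodels_model_comparison_oracle():
    import statsmodels.api as sm

    rng = np.random.default_rng(99)
    checked = 0
    while checked < 30:
        n = int(rng.integers(50, 90))
        g1 = random_genotypes(rng, n, rng.uniform(0.25, 0.5))
        g2 = random_genotypes(rng, n, rng.uniform(0.25, 0.5))
        fam = rng.choice(["u", "v", "w"], size=n)
        y = rng.normal(size=n) + 0.4 * g1 * g2
        design = build_pair_design(g1, g2, fam)
        res = fit_pair(design, y)
        if not all(res.per_effect[e]["testable"] for e in EFFECT_TYPES):
            continue
        # oracle: explicit OLS fits and model-comparison F statistics
        base = pd.get_dummies(pd.Series(fam), drop_first=True,
                              dtype=float).to_numpy()
        base = np.column_stack([np.ones(n), base])
        a1, d1 = design.a1, design.d1
        a2, d2 = design.a2, design.d2
        inter = {"AA": a1 * a2, "AD": a1 * d2, "DA": d1 * a2, "DD": d1 * d2}
        X_main = np.column_stack([base, a1, d1, a2, d2])
        X_full = np.column_stack([X_main] + [inter[e] for e in EFFECT_TYPES])
        fit_full = sm.OLS(y, X_full).fit()
        fit_main = sm.OLS(y, X_main).fit()
        f_overall, p_overall, df = fit_full.compare_f_test(fit_main)
        assert res.f_overall == pytest.approx(f_overall, rel=1e-8)
        assert res.p_overall == pytest.approx(p_overall, rel=1e-8)
        for e in EFFECT_TYPES:
            X_red = np.column_stack(
                [X_main] + [inter[f] for f in EFFECT_TYPES if f != e])
            fit_red = sm.OLS(y, X_red).fit()
            ss = fit_red.ssr - fit_full.ssr
            F = ss / (fit_full.ssr / fit_full.df_resid)
            assert res.per_effect[e]["ss"] == pytest.approx(ss, rel=1e-8)
            assert res.per_effect[e]["F"] == pytest.approx(F, rel=1e-8)
        checked += 1


def test_planted_aa_effect_has_smallest_p_value_among_effects():
    hits = 0
    for seed in range(100):
        cfg = SimulationConfig(
            n_individuals=500, n_families=5, family_variance=0.1,
            residual_variance=1.0, n_snps=6, maf_law=(0.3, 0.5),
            seed=20_000 + seed,
            planted_effects=[PlantedEpistasis("snp00002", "snp00005",
                                              "AA", 0.35)])
        gm, pheno, _ = simulate_cohort(cfg)
        design = build_pair_design(gm.column("snp00002"),
                                   gm.column("snp00005"),
                                   pheno["family"].to_numpy())
        res = fit_pair(design, pheno["afw"].to_numpy())
        ps = {e: res.per_effect[e]["p"] for e in EFFECT_TYPES
              if res.per_effect[e]["testable"]}
        if min(ps, key=ps.get) == "AA":
            hits += 1
    assert hits >= 90


def test_results_invariant_to_individual_ordering():
    rng = np.random.default_rng(14)
    n = 120
    g1 = random_genotypes(rng, n, 0.4)
    g2 = random_genotypes(rng, n, 0.3)
    fam = rng.choice(["a", "b", "c", "d"], size=n)
    y = rng.normal(size=n) + 0.5 * g1 * g2
    res = fit_pair(build_pair_design(g1, g2, fam), y)
    perm = rng.permutation(n)
    res_p = fit_pair(build_pair_design(g1[perm], g2[perm], fam[perm]),
                      y[perm])
    assert res.f_overall == pytest.approx(res_p.f_overall, rel=1e-10)
    for e in EFFECT_TYPES:
        assert res.per_effect[e]["ss"] == pytest.approx(
            res_p.per_effect[e]["ss"], rel=1e-10)


def test_swapping_loci_exchanges_ad_and_da():
    rng = np.random.default_rng(21)
    n = 150
    g1 = random_genotypes(rng, n, 0.45)
    g2 = random_genotypes(rng, n, 0.3)
    y = rng.normal(size=n) + 0.6 * g1 * (g2 == 1)
    res = fit_pair(build_pair_design(g1, g2), y)
    res_sw = fit_pair(build_pair_design(g2, g1), y)
    assert res.per_effect["AD"]["F"] == pytest.approx(
        res_sw.per_effect["DA"]["F"], rel=1e-10)
    assert res.per_effect["DA"]["F"] == pytest.approx(
        res_sw.per_effect["AD"]["F"], rel=1e-10)
    assert res.per_effect["AA"]["F"] == pytest.approx(
        res_sw.per_effect["AA"]["F"], rel=1e-10)
    assert res.per_effect["DD"]["F"] == pytest.approx(
        res_sw.per_effect["DD"]["F"], rel=1e-10)


def test_random_family_mode_agrees_with_fixed_on_balanced_families():
    rng = np.random.default_rng(30)
    n = 240
    g1 = random_genotypes(rng, n, 0.4)
    g2 = random_genotypes(rng, n, 0.4)
    fam = np.repeat(np.arange(6), 40)
    fam_eff = rng.normal(0, 0.6, size=6)
    y = fam_eff[fam] + 1.2 * g1 * g2 + rng.normal(size=n)
    design = build_pair_design(g1, g2, fam)
    res_fixed = fit_pair(design, y, family_mode="fixed")
    res_random = fit_pair(design, y, family_mode="random")
    # the two family treatments are different estimators; they must agree
    # on which effect carries the signal and roughly on its magnitude
    assert res_random.per_effect["AA"]["p"] < 1e-4
    ratio = res_random.per_effect["AA"]["F"] / res_fixed.per_effect["AA"]["F"]
    assert 0.7 < ratio < 1.4


# ---------------------------------------------------------------------------
# threshold arithmetic and contribution rates

def test_bonferroni_for_the_full_panel():
    n_tests, threshold = bonferroni(45_611, alpha=0.05, tests_per_pair=4)
    assert n_tests == 4 * 45_611 * 45_610 // 2
    assert n_tests == pytest.approx(4.16e9, rel=2e-3)
    assert threshold == pytest.approx(1.20e-11, rel=2e-3)


def test_bonferroni_single_test():
    assert bonferroni(2, tests_per_pair=1) == (1, 0.05)


def test_bonferroni_small_panel():
    n_tests, threshold = bonferroni(100, tests_per_pair=4)
    assert n_tests == 19_800
    assert threshold == pytest.approx(0.05 / 19_800)


def test_contribution_rate_bounds():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    tss = ((y - y.mean()) ** 2).sum()
    assert contribution_rate(0.0, y) == 0.0
    assert contribution_rate(tss, y) == pytest.approx(100.0)
    with pytest.raises(ValueError):
        contribution_rate(1.0, np.full(5, 2.0))


# ---------------------------------------------------------------------------
# scans

def test_scan_recovers_a_single_planted_pair():
    cfg = SimulationConfig(
        n_individuals=400, n_families=4, family_variance=0.1,
        residual_variance=0.3, n_snps=30, maf_law=(0.3, 0.5), seed=77,
        planted_effects=[PlantedEpistasis("snp00008", "snp00021",
                                          "AA", 1.2)])
    gm, pheno, _ = simulate_cohort(cfg)
    out = run_scan(gm, pheno["afw"].to_numpy(),
                   pheno["family"].to_numpy(), threshold=1e-10)
    assert len(out) == 1
    row = out.iloc[0]
    assert {row["snp1"], row["snp2"]} == {"snp00008", "snp00021"}
    assert row["effect"] == "AA"


def test_scan_controls_familywise_error_on_null_phenotype():
    cfg = SimulationConfig(n_individuals=300, n_families=4, n_snps=60,
                           maf_law=(0.2, 0.5), seed=51)
    gm, pheno, _ = simulate_cohort(cfg)
    out = run_scan(gm, pheno["afw"].to_numpy(), pheno["family"].to_numpy())
    assert len(out) == 0


def test_scan_rejects_empty_input():
    gm = make_matrix(np.empty((0, 0)))
    with pytest.raises(ValueError, match="empty"):
        run_scan(gm, np.array([]), threshold=0.05)


def test_scan_restrictions_and_ordering():
    cfg = SimulationConfig(n_individuals=200, n_families=2, n_snps=20,
                           n_chromosomes=2, maf_law=(0.3, 0.5), seed=15)
    gm, pheno, _ = simulate_cohort(cfg)
    y = pheno["afw"].to_numpy()
    out = run_scan(gm, y, threshold=1.0, chrom_pairs=[("1", "2")],
                   max_pairs=40)
    assert len(out) > 0
    assert set(zip(out["chrom1"], out["chrom2"])) == {("1", "2")}
    key = list(zip(out["chrom1"], out["pos1"], out["chrom2"], out["pos2"],
                   out["effect"]))
    assert key == sorted(key)


def test_single_locus_scan_skips_monomorphic_and_recovers_additive():
    rng = np.random.default_rng(8)
    n = 800
    mono = np.zeros(n)
    causal = random_genotypes(rng, n, 0.5)
    neutral = random_genotypes(rng, n, 0.3)
    gm = make_matrix(np.column_stack([mono, causal, neutral]))
    target = 1.5
    beta = np.sqrt((target / 100) / (1 - target / 100) / 0.5)
    cs = []
    for seed in range(20):
        r = np.random.default_rng(seed)
        y = beta * (causal - causal.mean()) + r.normal(size=n)
        out = single_locus_scan(gm, y)
        assert set(out["snp"]) == {"s2", "s3"}
        cs.append(out.set_index("snp").at["s2", "c"])
    assert abs(np.mean(cs) - target) < 0.4


def test_single_locus_null_p_values_are_uniform():
    cfg = SimulationConfig(n_individuals=500, n_families=2, n_snps=2_000,
                           maf_law=(0.1, 0.5), seed=33)
    gm, pheno, _ = simulate_cohort(cfg)
    out = single_locus_scan(gm, pheno["afw"].to_numpy())
    stat, p = stats.kstest(out["P"], "uniform")
    assert p > 0.01
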