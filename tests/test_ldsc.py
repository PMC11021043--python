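"""LD scores and the heritability / genetic-correlation regressions."""

import numpy as np
import pytest

from pleiokit.ldsc import (
    CrossTraitLDSC,
    StratifiedLDSC,
    UnivariateLDSC,
    compute_ld_scores,
    estimate_h2,
    observed_to_liability,
    stratified_h2,
)
from pleiokit.mixture import MixtureParams
from pleiokit.simulate import (
    SimConfig,
    draw_effects,
    draw_effects_with_enrichment,
    make_annotations,
    simulate_genotypes,
    simulate_sumstats,
    simulate_sumstats_pair,
)
from conftest import make_config


class TestLDScores:
    def test_no_ld_gives_self_term_only(self):
        cfg = make_config(m_snps=300, n_ref=8_000, rho=0.0, block_size=10)
        ld = compute_ld_scores(simulate_genotypes(cfg), window_snps=50)
        assert abs(ld.total.mean() - 1.0) < 0.02

    def test_matches_bruteforce_with_full_window(self):
        cfg = make_config(m_snps=200, n_ref=500, rho=0.6, block_size=40, n_chrom=1)
        panel = simulate_genotypes(cfg)
        ld = compute_ld_scores(panel, window_snps=200)
        X, n = panel.genotypes, panel.n_ref
        acc = np.zeros(200)
        for j in range(200):  # O(m^2) double loop oracle
            for k in range(200):
                r = float(X[:, j] @ X[:, k]) / n
                acc[j] += r * r - (1 - r * r) / (n - 2)
        assert np.allclose(ld.total, acc, atol=1e-10)

    def test_ar1_closed_form(self):
        cfg = make_config(m_snps=400, n_ref=4_000, rho=0.5, block_size=400,
                          n_chrom=1)
        ld = compute_ld_scores(simulate_genotypes(cfg), window_snps=400)
        interior = ld.total[30:-30]
        assert abs(interior.mean() - 5.0 / 3.0) < 0.03

    def test_windows_do_not_cross_chromosomes(self):
        cfg = make_config(m_snps=100, n_ref=2_000, rho=0.9, block_size=50, n_chrom=2)
        ld = compute_ld_scores(simulate_genotypes(cfg), window_snps=100)
        # last SNP of chr1 must not pick up its chr2 neighbours
        assert ld.total[49] < ld.total[25]

    def test_category_scores_sum_to_total(self, small_panel):
        m = small_panel.m_snps
        rng = np.random.default_rng(1)
        half = rng.random(m) < 0.5
        A = np.column_stack([half, ~half]).astype(float)  # partition
        ld = compute_ld_scores(small_panel, window_snps=30, annotations=A)
        assert np.allclose(ld.categories.sum(axis=1), ld.total, atol=1e-10)

    def test_small_panel_rejected(self, small_panel):
        cfg = make_config(n_ref=2)
        with pytest.raises(ValueError):
            compute_ld_scores(simulate_genotypes(cfg))


class TestUnivariate:
    def test_null_line(self):
        ld = np.linspace(1, 3, 500)
        est = estimate_h2(np.ones(500), ld, 10_000, n_blocks=20)
        assert est.estimate == pytest.approx(0.0, abs=1e-10)
        assert est.intercept == pytest.approx(1.0, abs=1e-10)

    def test_recovers_h2_in_simulation(self):
        m, n = 8_000, 30_000
        mix = MixtureParams.from_h2(0.3, 0.3, m, pi12=0.05, rho12=0.0)
        cfg = make_config(m_snps=m, n_ref=800, block_size=25, rho=0.1,
                          rho_max=0.9, mixture=mix, seed=21)
        panel = simulate_genotypes(cfg)
        b1, _ = draw_effects(cfg)
        ss = simulate_sumstats(panel, b1, n, seed=21)
        ld = compute_ld_scores(panel, window_snps=50)
        est = estimate_h2(ss["Z"].to_numpy() ** 2, ld, n, n_blocks=50)
        assert est.se > 0
        assert abs(est.estimate - 0.3) < 3 * est.se

    def test_constrained_and_free_agree_without_confounding(self):
        m, n = 8_000, 30_000
        mix = MixtureParams.from_h2(0.3, 0.3, m, pi12=0.05, rho12=0.0)
        cfg = make_config(m_snps=m, n_ref=800, block_size=25, rho=0.1,
                          rho_max=0.9, mixture=mix, seed=22)
        panel = simulate_genotypes(cfg)
        b1, _ = draw_effects(cfg)
        ss = simulate_sumstats(panel, b1, n, seed=22)
        ld = compute_ld_scores(panel, window_snps=50)
        free = estimate_h2(ss["Z"].to_numpy() ** 2, ld, n, n_blocks=50)
        con = estimate_h2(ss["Z"].to_numpy() ** 2, ld, n, n_blocks=50,
                          constrain_intercept=True)
        assert abs(free.estimate - con.estimate) < 2 * free.se

    def test_scale_consistency(self):
        # generating the same excess under doubled N doubles chi2-1;
        # the estimate must be unchanged
        rng = np.random.default_rng(3)
        ld = np.linspace(1, 4, 1_000)
        n = 10_000
        chi2 = 1.0 + 0.2 * n * ld / 1_000 + rng.normal(0, 0.5, 1_000)
        chi2b = 1.0 + 2.0 * (chi2 - 1.0)
        a = UnivariateLDSC(n_blocks=20, two_step=False).fit(ld, chi2, n)
        b = UnivariateLDSC(n_blocks=20, two_step=False).fit(ld, chi2b, 2 * n)
        assert a.h2_ == pytest.approx(b.h2_, rel=1e-10)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        ld = rng.uniform(1, 5, 800)
        chi2 = 1 + 0.1 * ld + rng.normal(0, 0.3, 800)
        a = UnivariateLDSC(n_blocks=10).fit(ld, chi2, 5_000)
        perm = rng.permutation(800)
        b = UnivariateLDSC(n_blocks=10).fit(ld[perm], chi2[perm], 5_000)
        assert a.h2_ == pytest.approx(b.h2_, abs=1e-8)

    def test_fewer_snps_than_blocks_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            UnivariateLDSC(n_blocks=200).fit(np.ones(50), np.ones(50), 1_000)


class TestLiabilityScale:
    def test_closed_form_value(self):
        # K = P = 0.5: multiplier K^2(1-K)^2 / (P(1-P) phi(0)^2) = pi/2
        assert observed_to_liability(1.0, 0.5, 0.5) == pytest.approx(np.pi / 2, rel=1e-6)
        assert observed_to_liability(1.0, 0.5, 0.5) == pytest.approx(1.571, abs=1e-3)

    def test_zero_maps_to_zero(self):
        assert observed_to_liability(0.0, 0.01, 0.4) == 0.0

    def test_linear_in_h2(self):
        a = observed_to_liability(0.1, 0.02, 0.3)
        b = observed_to_liability(0.2, 0.02, 0.3)
        assert b == pytest.approx(2 * a)

    @pytest.mark.parametrize("K,P", [(0.0, 0.5), (1.0, 0.5), (0.5, 0.0)])
    def test_invalid_prevalence(self, K, P):
        with pytest.raises(ValueError):
            observed_to_liability(0.1, K, P)


@pytest.fixture(scope="module")
def sim():
    m, n = 8_000, 30_000
    mix = MixtureParams.from_h2(0.3, 0.3, m, pi12=0.05, rho12=0.5)
    cfg = make_config(m_snps=m, n_ref=800, block_size=25, rho=0.1,
                      rho_max=0.9, mixture=mix, seed=31)
    panel = simulate_genotypes(cfg)
    b1, b2 = draw_effects(cfg)
    s1, s2 = simulate_sumstats_pair(panel, b1, b2, n, n, 0.0, seed=31)
    ld = compute_ld_scores(panel, window_snps=50)
    return ld.total, s1["Z"].to_numpy(), s2["Z"].to_numpy(), n


class TestCrossTrait:
    def test_self_pairing_gives_rg_one(self, sim):
        ld, z1, _, n = sim
        model = CrossTraitLDSC(n_blocks=50).fit(ld, z1, z1, n, n)
        assert model.rg_ == pytest.approx(1.0, abs=1e-12)

    def test_recovers_shared_component_rg(self, sim):
        ld, z1, z2, n = sim
        model = CrossTraitLDSC(n_blocks=50).fit(ld, z1, z2, n, n)
        assert model.rg_se_ > 0
        assert abs(model.rg_ - 0.5) < 3 * model.rg_se_

    def test_disjoint_causals_give_null_rg(self):
        m, n = 8_000, 30_000
        mix = MixtureParams(pi0=0.9, pi1=0.05, pi2=0.05, pi12=0.0,
                            sigma1_sq=0.3 / (m * 0.05), sigma2_sq=0.3 / (m * 0.05),
                            rho12=0.0)
        cfg = make_config(m_snps=m, n_ref=800, block_size=25, rho=0.1,
                          rho_max=0.9, mixture=mix, seed=32)
        panel = simulate_genotypes(cfg)
        b1, b2 = draw_effects(cfg)
        s1, s2 = simulate_sumstats_pair(panel, b1, b2, n, n, 0.0, seed=32)
        ld = compute_ld_scores(panel, window_snps=50)
        model = CrossTraitLDSC(n_blocks=50).fit(
            ld.total, s1["Z"].to_numpy(), s2["Z"].to_numpy(), n, n
        )
        assert abs(model.rg_) < 3 * model.rg_se_

    def test_sample_overlap_absorbed_by_intercept(self):
        m, n = 6_000, 20_000
        mix = MixtureParams.from_h2(0.3, 0.3, m, pi12=0.05, rho12=0.0)
        cfg = make_config(m_snps=m, n_ref=600, block_size=25, rho=0.1,
                          rho_max=0.9, mixture=mix, seed=33)
        panel = simulate_genotypes(cfg)
        b1, b2 = draw_effects(cfg)
        s1, s2 = simulate_sumstats_pair(panel, b1, b2, n, n, 0.7, seed=33)
        ld = compute_ld_scores(panel, window_snps=50)
        model = CrossTraitLDSC(n_blocks=50).fit(
            ld.total, s1["Z"].to_numpy(), s2["Z"].to_numpy(), n, n
        )
        # intercept estimates the null cross-trait correlation (the overlap)
        assert abs(model.cross_intercept_ - 0.7) < 4 * model.cross_intercept_se_

    def test_negative_h2_flags_rg_undefined(self):
        rng = np.random.default_rng(5)
        ld = rng.uniform(1, 4, 1_000)
        # chi2 decreasing in ld -> negative slope
        z1 = np.sqrt(np.clip(2.0 - 0.3 * ld, 0.05, None)) * rng.choice([-1, 1], 1_000)
        z2 = rng.standard_normal(1_000)
        with pytest.warns(UserWarning, match="undefined"):
            model = CrossTraitLDSC(n_blocks=10).fit(ld, z1, z2, 50_000, 50_000)
        assert not model.rg_defined_
        assert np.isnan(model.rg_)


class TestStratified:
    def test_single_category_collapses_to_univariate(self, small_panel):
        rng = np.random.default_rng(6)
        m = small_panel.m_snps
        ld = compute_ld_scores(small_panel, window_snps=20,
                               annotations=np.ones((m, 1)))
        chi2 = 1 + 0.05 * ld.total + rng.normal(0, 0.2, m)
        uni = UnivariateLDSC(n_blocks=10).fit(ld.total, chi2, 5_000)
        strat = StratifiedLDSC(n_blocks=10).fit(ld, chi2, 5_000, np.ones((m, 1)))
        assert strat.h2_total_ == pytest.approx(uni.h2_, rel=1e-8)
        assert strat.intercept_ == pytest.approx(uni.intercept_, rel=1e-8)

    def test_zero_snp_category_rejected(self, small_panel):
        m = small_panel.m_snps
        A = np.column_stack([np.ones(m), np.zeros(m)])
        ld = compute_ld_scores(small_panel, window_snps=20, annotations=A)
        with pytest.raises(ValueError, match="zero SNPs"):
            StratifiedLDSC(n_blocks=10).fit(ld, np.ones(m), 5_000, A)

    def test_enriched_category_detected(self):
        m, n = 8_000, 30_000
        enrich = []
        zs = []
        for rep in range(5):
            mix = MixtureParams.from_h2(0.3, 0.3, m, pi12=0.1, rho12=0.0)
            cfg = make_config(m_snps=m, n_ref=600, block_size=25, rho=0.1,
                              rho_max=0.9, mixture=mix, seed=60 + rep)
            panel = simulate_genotypes(cfg)
            ann = make_annotations(m, 10, category_fraction=0.1, seed=60 + rep)
            b1, _ = draw_effects_with_enrichment(cfg, ann, "cat3", 5.0)
            ss = simulate_sumstats(panel, b1, n, seed=60 + rep)
            ld = compute_ld_scores(panel, window_snps=50, annotations=ann)
            res = stratified_h2(ss["Z"].to_numpy() ** 2, ld, n, ann, n_blocks=40)
            k = res.category_names.index("cat3")
            others = [i for i in range(1, len(res.category_names)) if i != k]
            enrich.append(res.enrichment[k] - max(res.enrichment[others]))
            zs.append(res.tau_z[k])
        # the enriched category tops the ranking and its coefficient is positive
        assert np.mean([e > 0 for e in enrich]) >= 0.8
        assert np.mean(zs) > 1.0
        assert np.mean([res.enrichment[k] > 1.0]) == 1.0
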