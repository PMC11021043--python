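"""Adaptive SPU statistics, Monte-Carlo calibration, pruning and gene mapping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.stats import rankdata

from pleiokit._rng import substream
from pleiokit.genetest import (
    aspus_test,
    estimate_null_trait_correlation,
    gene_scan,
    map_snps_to_genes,
    mtaspusset_test,
    mtspusset_stat,
    pleiotropic_genes,
    prune_snps,
    spus_stat,
)
from pleiokit.simulate import make_gene_map, simulate_genotypes
from conftest import make_config


def ar1(d, rho):
    return rho ** np.abs(np.subtract.outer(np.arange(d), np.arange(d)))


class TestStatistics:
    @pytest.mark.parametrize(
        "z,g,expected",
        [
            ([1, 2, 3], 1, 6.0),
            ([3, 4], 2, 5.0),
            ([2, 2, 2, 2], 8, 2 ** 1.25),
            ([-1, -2, -3], 1, -6.0),
        ],
    )
    def test_spus_values(self, z, g, expected):
        assert spus_stat(z, g) == pytest.approx(expected)

    def test_mtspusset_hand_value(self):
        # (sqrt(5))^2 + 5^2 = 30
        assert mtspusset_stat([[1, 2], [3, 4]], 2, 2) == pytest.approx(30.0)

    def test_single_trait_collapse(self, rng):
        z = rng.standard_normal(6)
        for g1 in (1, 2, 4, 8):
            assert mtspusset_stat(z[None, :], g1, 1) == pytest.approx(spus_stat(z, g1))

    def test_all_zero(self):
        assert mtspusset_stat(np.zeros((2, 4)), 2, 2) == 0.0

    def test_even_gamma_sign_invariant(self, rng):
        z = rng.standard_normal(8)
        for g in (2, 4, 8):
            assert spus_stat(z, g) == pytest.approx(spus_stat(-z, g))

    def test_gamma_one_is_burden(self, rng):
        z = rng.standard_normal(8)
        assert spus_stat(z, 1) == pytest.approx(z.sum())

    def test_bruteforce_oracle_random_matrices(self, rng):
        for _ in range(100):
            m = int(rng.integers(1, 4))
            d = int(rng.integers(1, 6))
            Z = rng.normal(0, 2, size=(m, d))
            for g1 in (1, 2, 4, 8):
                s = sum(float(v) ** g1 for v in Z[0])
                assert spus_stat(Z[0], g1) == pytest.approx(
                    np.sign(s) * abs(s) ** (1 / g1), abs=1e-9
                )
                for g2 in (1, 2, 4, 8):
                    tot = 0.0
                    for b in range(m):
                        sb = sum(float(v) ** g1 for v in Z[b])
                        rb = np.sign(sb) * abs(sb) ** (1 / g1)
                        tot += np.sign(rb) * abs(rb) ** g2
                    assert mtspusset_stat(Z, g1, g2) == pytest.approx(tot, abs=1e-8)


class TestAdaptiveTests:
    def test_zero_vector_gives_p_one(self):
        r = aspus_test(np.zeros(5), np.eye(5), B=500, seed=1, escalate=False)
        assert r["p"] > 0.95
        assert all(p > 0.95 for p in r["component_p"].values())

    def test_single_snp_collapses_to_normal_tail(self):
        r = aspus_test(np.array([2.0]), np.eye(1), B=4_000, seed=2, escalate=False)
        expected = 2 * stats.norm.sf(2.0)
        mc_se = np.sqrt(expected * (1 - expected) / 4_000)
        assert abs(r["p"] - expected) < 4 * mc_se

    def test_exhaustive_rank_oracle_d1(self):
        # with d=1 every statistic is a monotone transform of |z|, so the
        # adaptive p equals the rank of |z| among the null draws
        z = np.array([1.3])
        B = 300
        r = aspus_test(z, np.eye(1), B=B, seed=5, escalate=False)
        L = np.linalg.cholesky(np.eye(1) + 1e-6 * np.eye(1))
        draws = (substream(5, f"aspus:B={B}").standard_normal((B, 1)) @ L.T).ravel()
        expected = (1 + np.sum(np.abs(draws) >= abs(z[0]))) / (B + 1)
        assert r["p"] == pytest.approx(expected)

    def test_adaptive_p_floor(self):
        r = aspus_test(np.full(4, 50.0), ar1(4, 0.3), B=200, seed=3, escalate=False)
        assert r["p"] == pytest.approx(1 / 201)

    def test_escalation_refines_small_p(self):
        r = aspus_test(np.full(4, 8.0), ar1(4, 0.3), B=1_000, seed=3,
                       escalate=True, b_cap=10_000)
        assert r["B"] == 10_000
        assert r["p"] <= 1e-3

    def test_doubling_B_is_stable(self):
        z = np.array([1.0, -2.0, 0.5, 1.5])
        R = ar1(4, 0.5)
        p1 = aspus_test(z, R, B=2_000, seed=7, escalate=False)["p"]
        p2 = aspus_test(z, R, B=4_000, seed=7, escalate=False)["p"]
        mc = np.sqrt(p1 * (1 - p1) / 2_000)
        assert abs(p1 - p2) < 3 * mc + 1e-3

    def test_mt_reduces_to_single_trait(self):
        z = np.array([1.7, -0.4, 0.9])
        R = ar1(3, 0.4)
        pa = aspus_test(z, R, B=2_000, seed=11, escalate=False)["p"]
        pm = mtaspusset_test(z[None, :], R, np.eye(1), B=2_000, seed=11,
                             escalate=False)["p"]
        assert pm == pytest.approx(pa, abs=5e-3)

    def test_identical_traits_boost_weak_signal(self, rng):
        R = ar1(6, 0.4)
        V = np.ones((2, 2))
        wins = 0
        for rep in range(10):
            z = np.linalg.cholesky(R) @ rng.standard_normal(6)
            z[0] += 2.5
            Z = np.vstack([z, z])
            pm = mtaspusset_test(Z, R, V, B=500, seed=100 + rep, escalate=False)["p"]
            pa = aspus_test(z, R, B=500, seed=200 + rep, escalate=False)["p"]
            wins += pm <= pa
        assert wins >= 6

    def test_requires_minimum_B(self):
        with pytest.raises(ValueError):
            aspus_test(np.zeros(3), np.eye(3), B=50)

    def test_non_psd_matrix_rejected(self):
        R = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            aspus_test(np.zeros(2), R, B=200)

    def test_quick_calibration(self):
        d = 10
        R = ar1(d, 0.5)
        L = np.linalg.cholesky(R)
        rng = np.random.default_rng(9)
        hits = 0
        n_genes = 300
        for g in range(n_genes):
            z = L @ rng.standard_normal(d)
            hits += aspus_test(z, R, B=400, seed=g, escalate=False)["p"] < 0.05
        assert 0.02 < hits / n_genes < 0.09


class TestPruning:
    def test_independent_all_kept(self):
        kept = prune_snps(np.eye(20), r2_threshold=0.5)
        assert len(kept) == 20

    def test_duplicate_column_drops_one(self):
        R = np.eye(3)
        R[0, 1] = R[1, 0] = 1.0
        kept = prune_snps(R, r2_threshold=0.5)
        assert list(kept) == [0, 2]

    def test_matches_greedy_oracle(self):
        R = ar1(10, 0.95)
        kept = prune_snps(R, r2_threshold=0.5, window=100)
        # brute-force greedy oracle
        oracle = []
        for j in range(10):
            if all(R[j, k] ** 2 <= 0.5 for k in oracle):
                oracle.append(j)
        assert list(kept) == oracle

    def test_panel_input(self, small_panel):
        kept = prune_snps(small_panel, r2_threshold=0.2, window=20)
        X = small_panel.genotypes
        n = small_panel.n_ref
        # no kept pair within the window exceeds the threshold
        for i, j in zip(kept[:-1], kept[1:]):
            if j - i <= 20:
                r = float(X[:, i] @ X[:, j]) / n
                assert r * r <= 0.2 + 1e-12


class TestGeneMapping:
    def test_bed_half_open_convention(self):
        gm = pd.DataFrame({"chrom": [1], "start": [1000], "end": [2000],
                           "name": ["g1"]})
        pos = np.array([1000, 1001, 2000, 2001])  # 1-based
        chrom = np.ones(4)
        out = map_snps_to_genes(gm, pos, chrom)
        # 1-based 1001..2000 <-> 0-based [1000, 2000)
        assert list(out["g1"]) == [1, 2]

    def test_nonoverlapping_genes_unique_assignment(self):
        gm = make_gene_map(m_snps=60, n_genes=6, gene_span=5, seed=0)
        pos = np.arange(60) * 1_000 + 1
        chrom = np.ones(60)
        out = map_snps_to_genes(gm[["chrom", "start", "end", "name"]], pos, chrom)
        all_snps = np.concatenate(list(out.values()))
        assert len(all_snps) == len(set(all_snps))

    def test_hand_enumeration(self):
        gm = pd.DataFrame({
            "chrom": [1, 1, 1],
            "start": [0, 3_000, 7_000],
            "end": [2_000, 5_000, 9_000],
            "name": ["a", "b", "c"],
        })
        pos = np.arange(10) * 1_000 + 1  # 1, 1001, ..., 9001
        out = map_snps_to_genes(gm, pos, np.ones(10))
        assert list(out["a"]) == [0, 1]
        assert list(out["b"]) == [3, 4]
        assert list(out["c"]) == [7, 8]


class TestTraitCorrelation:
    def test_independent_traits(self, rng):
        z1 = rng.standard_normal(5_000)
        z2 = rng.standard_normal(5_000)
        p1 = 2 * stats.norm.sf(np.abs(z1))
        p2 = 2 * stats.norm.sf(np.abs(z2))
        V = estimate_null_trait_correlation(z1, z2, p1, p2)
        assert abs(V[0, 1]) < 0.05
        assert V[0, 0] == V[1, 1] == 1.0
        assert V[0, 1] == V[1, 0]

    def test_identical_traits(self, rng):
        z = rng.standard_normal(1_000)
        p = 2 * stats.norm.sf(np.abs(z))
        V = estimate_null_trait_correlation(z, z, p, p)
        assert V[0, 1] == pytest.approx(0.999)


class TestPleiotropicRule:
    def toy(self):
        return pd.DataFrame({
            "gene": ["g1", "g2", "g3", "g4", "g5"],
            "aspus_p_1": [1e-4, 0.5, 1e-4, 0.5, 1e-4],
            "aspus_p_2": [0.5, 1e-4, 0.5, 0.5, 1e-4],
            "mtaspusset_p": [1e-4, 1e-4, 0.5, 1e-4, 1e-4],
        })

    def test_manual_application(self):
        out = pleiotropic_genes(self.toy(), alpha_gene=0.01)
        # rule: MT significant AND (trait1 or trait2 significant)
        assert list(out["gene"]) == ["g1", "g2", "g5"]

    def test_joint_only_excluded(self):
        out = pleiotropic_genes(self.toy(), alpha_gene=0.01)
        assert "g4" not in set(out["gene"])

    def test_subset_of_joint_significant(self):
        df = self.toy()
        out = pleiotropic_genes(df, alpha_gene=0.01)
        assert len(out) <= (df["mtaspusset_p"] < 0.01).sum()

    def test_default_alpha_is_bonferroni(self):
        out = pleiotropic_genes(self.toy())
        assert out.attrs["alpha_gene"] == pytest.approx(0.05 / 5)


class TestGeneScan:
    def test_deterministic_and_scan_order_free(self):
        cfg = make_config(m_snps=200, n_ref=300, block_size=10, seed=13)
        panel = simulate_genotypes(cfg)
        rng = np.random.default_rng(2)
        z1 = rng.standard_normal(200)
        z2 = rng.standard_normal(200)
        p1 = 2 * stats.norm.sf(np.abs(z1))
        p2 = 2 * stats.norm.sf(np.abs(z2))
        gm = make_gene_map(200, 8, 10, seed=1, panel=panel)
        a = gene_scan(z1, z2, p1, p2, panel, gm, B=200, seed=4, escalate=False)
        b = gene_scan(z1, z2, p1, p2, panel, gm, B=200, seed=4, escalate=False)
        assert a.equals(b)
        # per-gene results identical when scanning a sub-map (substreams keyed by gene)
        c = gene_scan(z1, z2, p1, p2, panel, gm.iloc[3:5], B=200, seed=4,
                      escalate=False)
        merged = a.merge(c, on="gene", suffixes=("", "_sub"))
        assert np.allclose(merged["mtaspusset_p"], merged["mtaspusset_p_sub"])
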