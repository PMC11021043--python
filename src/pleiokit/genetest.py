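"""Gene-based adaptive sum-of-powered-score tests on summary statistics.

For a gene with d SNPs and Z-score vector z, the sum-of-powered-score
statistic with power gamma1 is

    SPUs(gamma1; z) = sign(s) * |s|^(1/gamma1),   s = sum_j z_j^gamma1

(the signed-root convention keeps the statistic sign-equivariant when the
powered sum is negative).  Small powers behave like a burden test; large
powers approach the max statistic.  The multi-trait extension combines the
per-trait statistics with a second power:

    MTSPUsSet(gamma1, gamma2; Z) = sum_b SPUs(gamma1; Z_b)^gamma2.

Because no single power is best for every (sparsity, direction) pattern,
the adaptive tests take the minimum p-value over a power grid
(Gamma1 = Gamma2 = {1,2,4,8}) and recalibrate that minimum against the same
Monte-Carlo null: draws from N(0, R) for one trait, or V^{1/2} G R^{1/2}
for m traits (R the gene's LD correlation, V the null trait correlation).
All comparisons are two-sided on |T|; the smallest attainable p is 1/(B+1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._rng import substream
from .simulate import GenotypePanel

__all__ = [
    "spus_stat",
    "mtspusset_stat",
    "aspus_test",
    "mtaspusset_test",
    "prune_snps",
    "map_snps_to_genes",
    "estimate_null_trait_correlation",
    "gene_scan",
    "pleiotropic_genes",
]

DEFAULT_GAMMAS = (1, 2, 4, 8)


def _signed_power(x, g: float):
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.abs(x) ** g


def spus_stat(z, gamma1: float) -> float:
    """SPUs statistic: signed gamma1-th root of the powered sum of Z-scores."""
    z = np.asarray(z, dtype=float)
    s = np.sum(_signed_power(z, gamma1) if gamma1 % 2 else np.abs(z) ** gamma1)
    # even powers give a non-negative sum; odd powers keep each term's sign,
    # identical to plain z**gamma1 for integer gamma1
    return float(np.sign(s) * np.abs(s) ** (1.0 / gamma1))


def mtspusset_stat(Z, gamma1: float, gamma2: float) -> float:
    """Multi-trait statistic: powered sum over traits of per-trait SPUs values."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    per_trait = np.array([spus_stat(row, gamma1) for row in Z])
    return float(np.sum(_signed_power(per_trait, gamma2)))


def _chol_psd(R: np.ndarray, ridge: float = 1e-6) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    try:
        return np.linalg.cholesky(R + ridge * np.eye(len(R)))
    except np.linalg.LinAlgError as e:
        raise ValueError("correlation matrix is not PSD after ridge adjustment") from e


def _null_spus_matrix(draws: np.ndarray, gammas) -> np.ndarray:
    """(B, len(gammas)) SPUs statistics of null draws (B, d)."""
    out = np.empty((draws.shape[0], len(gammas)))
    for k, g in enumerate(gammas):
        s = (draws**g).sum(axis=1)
        out[:, k] = np.sign(s) * np.abs(s) ** (1.0 / g)
    return out


def _adaptive_p(T_null_abs: np.ndarray, T_obs_abs: np.ndarray):
    """Min-p recalibration shared by aSPUs and MTaSPUsSet.

    T_null_abs : (B, K) |statistics| of the null draws.
    T_obs_abs : (K,) observed |statistics|.
    Returns (adaptive_p, component_p array).
    """
    B, K = T_null_abs.shape
    comp_p = (1.0 + (T_null_abs >= T_obs_abs[None, :]).sum(axis=0)) / (B + 1.0)
    # leave-one-out null p's: rank of each null |T| among all B (ties -> max rank)
    null_p = np.empty_like(T_null_abs)
    for k in range(K):
        null_p[:, k] = rankdata(-T_null_abs[:, k], method="max") / B
    min_null = null_p.min(axis=1)
    min_obs = comp_p.min()
    adaptive = (1.0 + (min_null <= min_obs).sum()) / (B + 1.0)
    return float(adaptive), comp_p


def aspus_test(
    z,
    R,
    gammas=DEFAULT_GAMMAS,
    B: int = 10_000,
    seed: int = 0,
    escalate: bool = True,
    b_cap: int = 1_000_000,
) -> dict:
    """Single-trait adaptive SPUs test with a Monte-Carlo N(0, R) null.

    Returns a dict with the adaptive p, per-gamma component p's and the
    number of null draws used.  When escalate is set, an adaptive p below
    50/B triggers a rerun with 10x the draws (capped), so small p-values
    are resolved with adequate resolution.
    """
    z = np.asarray(z, dtype=float)
    if B < 100:
        raise ValueError("B must be at least 100")
    L = _chol_psd(R)
    if len(z) != L.shape[0]:
        raise ValueError("z and R dimensions disagree")
    T_obs = np.abs([spus_stat(z, g) for g in gammas])

    b = B
    while True:
        rng = substream(seed, f"aspus:B={b}")
        draws = rng.standard_normal((b, len(z))) @ L.T
        T_null = np.abs(_null_spus_matrix(draws, gammas))
        adaptive, comp = _adaptive_p(T_null, T_obs)
        if not escalate or adaptive >= 50.0 / b or b * 10 > b_cap:
            break
        b *= 10
    return {
        "p": adaptive,
        "component_p": dict(zip(gammas, comp)),
        "B": b,
    }


def mtaspusset_test(
    Z,
    R,
    V,
    gammas1=DEFAULT_GAMMAS,
    gammas2=DEFAULT_GAMMAS,
    B: int = 10_000,
    seed: int = 0,
    escalate: bool = True,
    b_cap: int = 1_000_000,
) -> dict:
    """Multi-trait adaptive test over the (gamma1, gamma2) grid.

    Null draws are Z(b) = V^{1/2} G R^{1/2} with G iid standard normal, so
    rows share the traits' null correlation V and columns the gene's LD R.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    mtraits, d = Z.shape
    if B < 100:
        raise ValueError("B must be at least 100")
    Lr = _chol_psd(R)
    Lv = _chol_psd(V)
    if Lv.shape[0] != mtraits or Lr.shape[0] != d:
        raise ValueError("Z, R, V dimensions disagree")

    grid = [(g1, g2) for g1 in gammas1 for g2 in gammas2]
    T_obs = np.abs([mtspusset_stat(Z, g1, g2) for g1, g2 in grid])

    b = B
    while True:
        rng = substream(seed, f"mtaspusset:B={b}")
        G = rng.standard_normal((b, mtraits, d))
        null_Z = np.einsum("ij,bjd->bid", Lv, G @ Lr.T)
        T_null = np.empty((b, len(grid)))
        for k, (g1, g2) in enumerate(grid):
            s = (null_Z**g1).sum(axis=2)
            root = np.sign(s) * np.abs(s) ** (1.0 / g1)
            T_null[:, k] = _signed_power(root, g2).sum(axis=1)
        adaptive, comp = _adaptive_p(np.abs(T_null), T_obs)
        if not escalate or adaptive >= 50.0 / b or b * 10 > b_cap:
            break
        b *= 10
    return {
        "p": adaptive,
        "component_p": dict(zip(grid, comp)),
        "B": b,
    }


def prune_snps(ref, r2_threshold: float = 0.5, window: int = 100) -> np.ndarray:
    """Greedy left-to-right LD pruning; returns indices of kept SNPs.

    Scanning SNPs in order, a SNP is dropped when its squared correlation
    with any already-kept SNP within `window` positions exceeds the
    threshold.  Deterministic: always keeps the earlier SNP of a pair.
    `ref` is either a square correlation matrix or a GenotypePanel.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must be in (0, 1]")
    if isinstance(ref, GenotypePanel):
        X = ref.genotypes
        n, m = X.shape

        def r2(j, k):
            return (float(X[:, j] @ X[:, k]) / n) ** 2

    else:
        R = np.asarray(ref, dtype=float)
        m = R.shape[0]

        def r2(j, k):
            return float(R[j, k]) ** 2

    kept: list[int] = []
    for j in range(m):
        ok = True
        for k in reversed(kept):
            if j - k > window:
                break
            if r2(j, k) > r2_threshold:
                ok = False
                break
        if ok:
            kept.append(j)
    return np.asarray(kept, dtype=int)


def map_snps_to_genes(gene_map: pd.DataFrame, positions, chrom, snp_indices=None) -> dict:
    """Assign SNPs to genes by position (BED half-open intervals).

    A SNP at 1-based position p belongs to a gene iff start <= p-1 < end on
    the same chromosome.  Genes with no SNPs are omitted.  Returns a dict
    gene name -> array of SNP indices (into the supplied positions).
    """
    positions = np.asarray(positions)
    chrom = np.asarray(chrom)
    idx = (
        np.asarray(snp_indices, dtype=int)
        if snp_indices is not None
        else np.arange(len(positions))
    )
    out: dict[str, np.ndarray] = {}
    for _, g in gene_map.iterrows():
        mask = (
            (chrom[idx] == g["chrom"])
            & (positions[idx] - 1 >= g["start"])
            & (positions[idx] - 1 < g["end"])
        )
        hit = idx[mask]
        if len(hit):
            out[str(g["name"])] = hit
    return out


def estimate_null_trait_correlation(z1, z2, p1, p2, p_cut: float = 0.05) -> np.ndarray:
    """Null cross-trait Z correlation from nominally non-significant SNPs.

    Correlates the two traits' Z-scores over SNPs with both p > p_cut (an
    effectively null subset), yielding the 2x2 trait correlation V the
    multi-trait Monte-Carlo null requires.  Sample overlap shows up here.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    mask = (np.asarray(p1) > p_cut) & (np.asarray(p2) > p_cut)
    if mask.sum() < 10:
        warnings.warn("fewer than 10 null SNPs; defaulting V to identity")
        return np.eye(2)
    r = float(np.corrcoef(z1[mask], z2[mask])[0, 1])
    r = float(np.clip(r, -0.999, 0.999))
    return np.array([[1.0, r], [r, 1.0]])


def gene_scan(
    z1,
    z2,
    p1,
    p2,
    panel: GenotypePanel,
    gene_map: pd.DataFrame,
    snp_indices=None,
    B: int = 10_000,
    seed: int = 0,
    gammas=DEFAULT_GAMMAS,
    ridge: float = 1e-6,
    escalate: bool = True,
) -> pd.DataFrame:
    """Run aSPUs (each trait) and MTaSPUsSet (jointly) for every gene.

    Per-gene LD comes from the reference panel restricted to the gene's
    SNPs; the per-gene RNG substream is keyed by gene id so results do not
    depend on scan order.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    V = estimate_null_trait_correlation(z1, z2, p1, p2)
    assign = map_snps_to_genes(gene_map, panel.positions, panel.chrom, snp_indices)
    n = panel.n_ref
    rows = []
    for gene, idx in assign.items():
        X = panel.genotypes[:, idx]
        R = (X.T @ X) / n
        np.fill_diagonal(R, 1.0)
        gene_seed = substream(seed, f"gene:{gene}").integers(2**31)
        Zmat = np.vstack([z1[idx], z2[idx]])
        r1 = aspus_test(Zmat[0], R, gammas=gammas, B=B, seed=gene_seed, escalate=escalate)
        r2_ = aspus_test(Zmat[1], R, gammas=gammas, B=B, seed=gene_seed + 1, escalate=escalate)
        rmt = mtaspusset_test(
            Zmat, R, V, gammas1=gammas, gammas2=gammas, B=B, seed=gene_seed + 2,
            escalate=escalate,
        )
        rows.append(
            {
                "gene": gene,
                "d": len(idx),
                "aspus_p_1": r1["p"],
                "aspus_p_2": r2_["p"],
                "mtaspusset_p": rmt["p"],
                "B": rmt["B"],
            }
        )
    return pd.DataFrame(rows)


def pleiotropic_genes(results: pd.DataFrame, alpha_gene: float | None = None) -> pd.DataFrame:
    """Pleiotropic genes: significant jointly AND in at least one single trait.

    A gene qualifies iff its MTaSPUsSet p is below the gene-level threshold
    and its aSPUs p for at least one trait is also below it.  The default
    threshold is the Bonferroni-corrected 0.05 / (number of genes tested).
    """
    if len(results) == 0:
        return results.iloc[0:0]
    alpha = alpha_gene if alpha_gene is not None else 0.05 / len(results)
    joint = results["mtaspusset_p"] < alpha
    single = (results["aspus_p_1"] < alpha) | (results["aspus_p_2"] < alpha)
    out = results[joint & single].copy()
    out.attrs["alpha_gene"] = alpha
    return out
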