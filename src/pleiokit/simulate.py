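"""Synthetic GWAS data with known genetic architecture.

Generates the full chain the downstream analyses assume: LD-blocked
standardized genotypes (block-diagonal AR(1) correlation), per-SNP effect
sizes from the four-component bivariate causal mixture, GWAS Z-scores with
LD-proportional chi-square inflation and configurable sample overlap, plus
gene maps and functional annotation matrices.  Everything is deterministic
given the master seed via named substreams.

Z-scores are generated from the standard summary-statistics model

    Z = sqrt(n) * R * beta + eps,   eps ~ N(0, R),

with R the within-block LD correlation, so that LDSC, the mixture model and
the local quadratic-form estimators all see data obeying their own generative
assumptions with known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from ._rng import substream
from .mixture import MixtureParams

__all__ = [
    "SimConfig",
    "GenotypePanel",
    "simulate_genotypes",
    "draw_effects",
    "draw_effects_with_enrichment",
    "simulate_sumstats",
    "simulate_sumstats_pair",
    "make_gene_map",
    "make_annotations",
    "realized_h2",
    "ar1_ld_score",
    "write_sumstats",
    "write_gene_map",
    "write_annotations",
]

SNP_SPACING_BP = 1_000  # synthetic SNPs sit on a 1 kb grid within each chromosome


@dataclass
class SimConfig:
    """Configuration of one synthetic two-trait GWAS study.

    m_snps : total number of SNPs.
    n1, n2 : GWAS sample sizes for the two traits.
    n_ref : reference-panel size (individuals).
    block_size : SNPs per LD block.
    rho : adjacent-SNP AR(1) correlation within a block, 0 <= rho < 1.
    rho_max : when set, each block draws its own AR(1) coefficient
        uniformly from [rho, rho_max] — heterogeneous local LD, as in real
        genomes, which is what gives LD score regression its leverage.
        When None every block uses `rho` (closed-form oracle mode).
    mixture : effect-size mixture parameters.
    sample_overlap : fraction of individuals shared between the two GWAS.
    n_chrom : number of chromosome labels (blocks never cross them).
    seed : master seed; all operations draw from named substreams of it.
    """

    m_snps: int
    n1: int
    n2: int
    n_ref: int
    block_size: int
    rho: float
    mixture: MixtureParams
    sample_overlap: float = 0.0
    n_chrom: int = 1
    seed: int = 0
    rho_max: float | None = None

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be positive")
        if self.block_size < 1 or self.block_size > self.m_snps:
            raise ValueError("block_size must be in [1, m_snps]")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must satisfy 0 <= rho < 1")
        if self.rho_max is not None and not self.rho <= self.rho_max < 1:
            raise ValueError("rho_max must satisfy rho <= rho_max < 1")
        if not 0 <= self.sample_overlap <= 1:
            raise ValueError("sample_overlap must be in [0, 1]")
        if self.n_chrom < 1 or self.n_chrom > self.m_snps:
            raise ValueError("n_chrom must be in [1, m_snps]")
        # MixtureParams validates itself in its own __post_init__

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["mixture"] = MixtureParams(**d["mixture"])
        return cls(**d)


@dataclass
class GenotypePanel:
    """Standardized reference genotypes with LD-block bookkeeping.

    genotypes : (n_ref, m) matrix, each column mean 0 / variance 1.
    positions : 1-based bp positions (restarting on each chromosome).
    chrom : per-SNP chromosome labels.
    block_index : per-SNP LD-block id; blocks are contiguous and never
        cross a chromosome boundary.
    rho : the AR(1) parameter used to generate the panel (kept for
        closed-form oracles); block_rho holds the per-block coefficients
        when LD is heterogeneous.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    block_index: np.ndarray
    rho: float = 0.0
    snp_ids: np.ndarray = field(default=None)
    block_rho: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.snp_ids is None:
            self.snp_ids = np.array([f"rs{i + 1}" for i in range(self.m_snps)])

    @property
    def n_ref(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m_snps(self) -> int:
        return self.genotypes.shape[1]

    def block_slices(self) -> list[slice]:
        idx = self.block_index
        bounds = np.flatnonzero(np.diff(idx)) + 1
        starts = np.concatenate([[0], bounds])
        stops = np.concatenate([bounds, [len(idx)]])
        return [slice(a, b) for a, b in zip(starts, stops)]

    def block_correlations(self, ridge: float = 1e-6) -> list[np.ndarray]:
        """Empirical within-block correlation matrices, ridge-stabilised."""
        out = []
        n = self.n_ref
        for sl in self.block_slices():
            X = self.genotypes[:, sl]
            R = (X.T @ X) / n
            np.fill_diagonal(R, 1.0 + ridge)
            out.append(R)
        return out


def _layout(m_snps: int, block_size: int, n_chrom: int):
    """Chromosome labels, positions and block ids for m SNPs."""
    per_chrom = np.full(n_chrom, m_snps // n_chrom)
    per_chrom[: m_snps % n_chrom] += 1
    chrom = np.repeat(np.arange(1, n_chrom + 1), per_chrom)
    positions = np.concatenate(
        [np.arange(c) * SNP_SPACING_BP + 1 for c in per_chrom]
    )
    block = np.empty(m_snps, dtype=int)
    b = 0
    start = 0
    for c in per_chrom:
        for off in range(0, c, block_size):
            stop = min(off + block_size, c)
            block[start + off : start + stop] = b
            b += 1
        start += c
    return chrom, positions, block


def simulate_genotypes(cfg: SimConfig) -> GenotypePanel:
    """Draw a standardized reference panel with block-diagonal AR(1) LD.

    Within a block the population correlation of SNPs i and j is
    rho^|i-j|; across blocks it is zero.  Columns are empirically
    standardized to mean 0, variance 1.
    """
    rng = substream(cfg.seed, "genotypes")
    chrom, positions, block = _layout(cfg.m_snps, cfg.block_size, cfg.n_chrom)
    n_blocks = int(block[-1]) + 1
    if cfg.rho_max is None:
        block_rho = np.full(n_blocks, cfg.rho)
    else:
        block_rho = substream(cfg.seed, "block_rho").uniform(
            cfg.rho, cfg.rho_max, size=n_blocks
        )
    X = rng.standard_normal((cfg.n_ref, cfg.m_snps))
    if block_rho.max() > 0:
        # AR(1) recursion along columns, restarted at block boundaries
        for j in range(1, cfg.m_snps):
            if block[j] == block[j - 1]:
                r = block_rho[block[j]]
                X[:, j] = r * X[:, j - 1] + np.sqrt(1.0 - r * r) * X[:, j]
    X -= X.mean(axis=0)
    X /= X.std(axis=0)
    return GenotypePanel(
        genotypes=X, positions=positions, chrom=chrom, block_index=block,
        rho=cfg.rho, block_rho=block_rho,
    )


def draw_effects(cfg: SimConfig, return_labels: bool = False):
    """Draw per-SNP effect sizes for both traits from the causal mixture.

    Each SNP independently lands in one of the four components with
    probabilities (pi0, pi1, pi2, pi12); within the shared component the two
    effects are bivariate normal with correlation rho12.
    """
    rng = substream(cfg.seed, "effects")
    mx = cfg.mixture
    m = cfg.m_snps
    labels = rng.choice(4, size=m, p=mx.proportions)
    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    s1 = np.sqrt(mx.sigma1_sq)
    s2 = np.sqrt(mx.sigma2_sq)

    only1 = labels == 1
    only2 = labels == 2
    both = labels == 3
    beta1[only1] = rng.standard_normal(only1.sum()) * s1
    beta2[only2] = rng.standard_normal(only2.sum()) * s2
    nb = int(both.sum())
    if nb:
        g = rng.standard_normal((nb, 2))
        r = mx.rho12
        beta1[both] = s1 * g[:, 0]
        beta2[both] = s2 * (r * g[:, 0] + np.sqrt(max(1.0 - r * r, 0.0)) * g[:, 1])
    if return_labels:
        return beta1, beta2, labels
    return beta1, beta2


def draw_effects_with_enrichment(
    cfg: SimConfig, annotations: pd.DataFrame, category: str, factor: float
):
    """Like draw_effects, but inflate effect variance by `factor` inside one category.

    Used to build stratified-regression test cases with a known enriched
    annotation; factor=1 recovers the uniform architecture exactly.
    """
    beta1, beta2 = draw_effects(cfg)
    if category not in annotations.columns:
        raise KeyError(f"annotation category {category!r} not found")
    mask = annotations[category].to_numpy().astype(bool)
    scale = np.where(mask, np.sqrt(factor), 1.0)
    return beta1 * scale, beta2 * scale


def _block_chols(panel: GenotypePanel, ridge: float = 1e-6):
    chols = []
    Rs = panel.block_correlations(ridge=ridge)
    for R in Rs:
        chols.append(np.linalg.cholesky(R))
    return Rs, chols


def _sumstats_frame(panel: GenotypePanel, z: np.ndarray, n: int) -> pd.DataFrame:
    from scipy import stats as _st

    return pd.DataFrame(
        {
            "SNP": panel.snp_ids,
            "CHR": panel.chrom,
            "BP": panel.positions,
            "A1": "A",
            "A2": "G",
            "Z": z,
            "P": 2.0 * _st.norm.sf(np.abs(z)),
            "N": n,
        }
    )


def simulate_sumstats(
    panel: GenotypePanel, beta: np.ndarray, n: int, seed: int = 0
) -> pd.DataFrame:
    """GWAS summary statistics for one trait: Z = sqrt(n) R beta + eps, eps ~ N(0, R)."""
    if n <= 0:
        raise ValueError("sample size must be positive")
    beta = np.asarray(beta, dtype=float)
    if len(beta) != panel.m_snps:
        raise ValueError("beta length must equal the panel's SNP count")
    rng = substream(seed, "sumstats")
    z = np.empty(panel.m_snps)
    Rs, chols = _block_chols(panel)
    for sl, R, L in zip(panel.block_slices(), Rs, chols):
        mean = np.sqrt(n) * (R @ beta[sl])
        z[sl] = mean + L @ rng.standard_normal(sl.stop - sl.start)
    return _sumstats_frame(panel, z, n)


def simulate_sumstats_pair(
    panel: GenotypePanel,
    beta1: np.ndarray,
    beta2: np.ndarray,
    n1: int,
    n2: int,
    sample_overlap: float = 0.0,
    seed: int = 0,
):
    """Summary statistics for both traits with correlated null noise.

    Sample overlap is modelled by sharing a fraction of the noise component:
    eps_t = sqrt(f)*eps_shared + sqrt(1-f)*eps_own, which makes the null
    cross-trait Z correlation equal to the overlap fraction f (the quantity
    the cross-trait LDSC intercept absorbs).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    if not 0 <= sample_overlap <= 1:
        raise ValueError("sample_overlap must be in [0, 1]")
    rng = substream(seed, "sumstats_pair")
    f = sample_overlap
    z1 = np.empty(panel.m_snps)
    z2 = np.empty(panel.m_snps)
    Rs, chols = _block_chols(panel)
    for sl, R, L in zip(panel.block_slices(), Rs, chols):
        d = sl.stop - sl.start
        shared = L @ rng.standard_normal(d)
        own1 = L @ rng.standard_normal(d)
        own2 = L @ rng.standard_normal(d)
        e1 = np.sqrt(f) * shared + np.sqrt(1 - f) * own1
        e2 = np.sqrt(f) * shared + np.sqrt(1 - f) * own2
        z1[sl] = np.sqrt(n1) * (R @ beta1[sl]) + e1
        z2[sl] = np.sqrt(n2) * (R @ beta2[sl]) + e2
    return _sumstats_frame(panel, z1, n1), _sumstats_frame(panel, z2, n2)


def realized_h2(panel: GenotypePanel, beta: np.ndarray) -> float:
    """Variance explained by the genetic term, h2 = beta' R beta, summed over blocks."""
    beta = np.asarray(beta, dtype=float)
    total = 0.0
    for sl, R in zip(panel.block_slices(), panel.block_correlations(ridge=0.0)):
        b = beta[sl]
        total += float(b @ R @ b)
    return total


def ar1_ld_score(rho: float) -> float:
    """Population LD score of an interior SNP in an infinite AR(1) block.

    l = 1 + 2 * sum_{d>=1} rho^(2d) = 1 + 2*rho^2/(1 - rho^2).
    """
    return 1.0 + 2.0 * rho**2 / (1.0 - rho**2)


def make_gene_map(
    m_snps: int,
    n_genes: int,
    gene_span: int,
    seed: int = 0,
    panel: GenotypePanel | None = None,
) -> pd.DataFrame:
    """Non-overlapping gene intervals (BED convention) over the SNP grid.

    Genes are placed on an even stride with seeded jitter; every gene spans
    `gene_span` SNPs (clipped at chromosome ends) and contains at least one
    SNP.  Returns a BED-like frame (chrom, start, end, name) in 0-based
    half-open coordinates, plus the SNP index range per gene.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes > m_snps:
        raise ValueError("cannot place more genes than SNPs")
    if gene_span < 1:
        raise ValueError("gene_span must be >= 1")
    if panel is None:
        chrom, positions, _ = _layout(m_snps, m_snps, 1)
    else:
        if panel.m_snps != m_snps:
            raise ValueError("panel SNP count does not match m_snps")
        chrom, positions = panel.chrom, panel.positions

    rng = substream(seed, "gene_map")
    stride = m_snps // n_genes
    span = min(gene_span, stride)
    rows = []
    for g in range(n_genes):
        lo = g * stride
        hi = min(lo + stride, m_snps)
        jitter_max = max(hi - lo - span, 0)
        start_idx = lo + int(rng.integers(0, jitter_max + 1))
        stop_idx = min(start_idx + span, m_snps)  # exclusive
        # clip at chromosome boundaries: keep the gene on its first chromosome
        c = chrom[start_idx]
        while stop_idx > start_idx + 1 and chrom[stop_idx - 1] != c:
            stop_idx -= 1
        rows.append(
            {
                "chrom": c,
                "start": int(positions[start_idx] - 1),  # BED 0-based
                "end": int(positions[stop_idx - 1]),  # half-open
                "name": f"gene{g + 1}",
                "snp_start": start_idx,
                "snp_stop": stop_idx,
            }
        )
    return pd.DataFrame(rows)


def make_annotations(
    m_snps: int,
    n_categories: int,
    category_fraction: float = 0.1,
    seed: int = 0,
    snp_ids=None,
) -> pd.DataFrame:
    """Binary functional-annotation matrix; the first column is the all-ones base.

    Each non-base category marks an independent random `category_fraction`
    of SNPs.  Effect-variance enrichment inside a category is applied when
    drawing effects (see draw_effects_with_enrichment), not here.
    """
    if n_categories < 1:
        raise ValueError("n_categories must be >= 1")
    if not 0 < category_fraction <= 1:
        raise ValueError("category_fraction must be in (0, 1]")
    rng = substream(seed, "annotations")
    if snp_ids is None:
        snp_ids = [f"rs{i + 1}" for i in range(m_snps)]
    data = {"SNP": snp_ids, "base": np.ones(m_snps, dtype=int)}
    for c in range(1, n_categories):
        data[f"cat{c}"] = (rng.random(m_snps) < category_fraction).astype(int)
    df = pd.DataFrame(data)
    empty = [c for c in df.columns[1:] if df[c].sum() == 0]
    if empty:
        warnings.warn(f"annotation categories with zero SNPs: {empty}")
    return df


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write LDSC-dialect summary statistics (SNP CHR BP A1 A2 Z P N, tab-separated)."""
    df.to_csv(path, sep="\t", index=False)


def write_gene_map(gene_map: pd.DataFrame, path) -> None:
    """Write the gene map as 4-column BED (0-based half-open)."""
    gene_map[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def write_annotations(annot: pd.DataFrame, path) -> None:
    annot.to_csv(path, sep="\t", index=False)
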