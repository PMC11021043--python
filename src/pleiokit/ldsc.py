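"""LD score regression: SNP heritability, genetic correlation, and partitioned h2.

The regression exploits that under a polygenic model the expected GWAS
chi-square of SNP j grows linearly in its LD score l_j (the summed squared
correlation with neighbouring SNPs):

    E[chi2_j] = N * h2 * l_j / M + N*a + 1,

so the slope of chi2 on N*l/M estimates h2 while the intercept captures
confounding (population stratification, cryptic relatedness).  The
cross-trait analogue regresses z1*z2 on sqrt(N1*N2)*l/M; its slope is the
genetic covariance and its intercept absorbs sample overlap.  Standard
errors come from a block jackknife over contiguous SNP blocks.

Estimators follow the scikit-learn convention (fit() + trailing-underscore
attributes); thin functional wrappers return EstimateWithSE records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .simulate import GenotypePanel

__all__ = [
    "LDScores",
    "EstimateWithSE",
    "StratifiedResult",
    "compute_ld_scores",
    "UnivariateLDSC",
    "CrossTraitLDSC",
    "StratifiedLDSC",
    "estimate_h2",
    "estimate_rg",
    "stratified_h2",
    "observed_to_liability",
]


@dataclass
class LDScores:
    """Per-SNP LD scores; optionally one column per annotation category.

    total : (m,) summed adjusted r^2 within the window (self term included).
    categories : optional (m, C) per-category scores; sums to `total`
        across categories when the categories partition the SNPs.
    """

    total: np.ndarray
    window_snps: int
    categories: np.ndarray | None = None
    category_names: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.total)


@dataclass
class EstimateWithSE:
    """Point estimate with block-jackknife SE and a Wald p-value."""

    estimate: float
    se: float
    n_blocks: int
    p: float
    scale: str = "observed"
    intercept: float | None = None
    intercept_se: float | None = None


@dataclass
class StratifiedResult:
    """Partitioned-heritability output: per-category coefficients and enrichment."""

    category_names: list
    tau: np.ndarray
    tau_se: np.ndarray
    tau_z: np.ndarray
    h2_category: np.ndarray
    h2_total: float
    snp_fraction: np.ndarray
    h2_fraction: np.ndarray
    enrichment: np.ndarray
    enrichment_se: np.ndarray
    n_blocks: int


def compute_ld_scores(
    panel: GenotypePanel,
    window_snps: int = 100,
    annotations=None,
) -> LDScores:
    """LD scores from a standardized reference panel.

    l_j = sum over SNPs k within `window_snps` (same chromosome) of the
    bias-adjusted squared correlation r2_adj = r^2 - (1 - r^2)/(n_ref - 2).
    The self term contributes exactly 1.  With an annotation matrix,
    per-category scores restrict the inner sum to category members.
    """
    X = panel.genotypes
    n, m = X.shape
    if n < 3:
        raise ValueError("reference panel needs at least 3 individuals")
    if window_snps < 0:
        raise ValueError("window_snps must be non-negative")

    A = None
    names: list = []
    if annotations is not None:
        if hasattr(annotations, "columns"):
            names = [c for c in annotations.columns if c != "SNP"]
            A = annotations[names].to_numpy(dtype=float)
        else:
            A = np.asarray(annotations, dtype=float)
            names = [f"cat{i}" for i in range(A.shape[1])]
        if A.shape[0] != m:
            raise ValueError("annotation rows must match SNP count")

    total = np.zeros(m)
    cat = np.zeros((m, A.shape[1])) if A is not None else None
    chunk = max(256, window_snps)
    idx = np.arange(m)
    for c0 in range(0, m, chunk):
        c1 = min(c0 + chunk, m)
        lo = max(0, c0 - window_snps)
        hi = min(m, c1 + window_snps)
        r = (X[:, c0:c1].T @ X[:, lo:hi]) / n
        r2 = r * r
        r2adj = r2 - (1.0 - r2) / (n - 2)
        dist_ok = np.abs(idx[c0:c1, None] - idx[None, lo:hi]) <= window_snps
        same_chrom = panel.chrom[c0:c1, None] == panel.chrom[None, lo:hi]
        mask = dist_ok & same_chrom
        r2adj = np.where(mask, r2adj, 0.0)
        total[c0:c1] = r2adj.sum(axis=1)
        if cat is not None:
            cat[c0:c1] = r2adj @ A[lo:hi]
    return LDScores(total=total, window_snps=window_snps, categories=cat, category_names=names)


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return coef


def _block_bounds(m: int, n_blocks: int) -> np.ndarray:
    return np.linspace(0, m, n_blocks + 1).astype(int)


def _jackknife(est_fn, m: int, n_blocks: int):
    """Delete-one-block jackknife of a (possibly vector-valued) estimator."""
    bounds = _block_bounds(m, n_blocks)
    full = np.atleast_1d(np.asarray(est_fn(np.ones(m, dtype=bool)), dtype=float))
    reps = np.empty((n_blocks, len(full)))
    for i in range(n_blocks):
        keep = np.ones(m, dtype=bool)
        keep[bounds[i] : bounds[i + 1]] = False
        reps[i] = np.atleast_1d(est_fn(keep))
    mean = reps.mean(axis=0)
    se = np.sqrt((n_blocks - 1) / n_blocks * np.sum((reps - mean) ** 2, axis=0))
    return full, se, reps


class UnivariateLDSC(BaseEstimator):
    """Single-trait LD score regression for SNP heritability.

    Parameters
    ----------
    n_blocks : jackknife blocks (contiguous SNP chunks).
    constrain_intercept : fix the intercept at 1 (no confounding).
    M : number of SNPs the heritability refers to; defaults to the number
        of regression SNPs.
    two_step : use heteroskedasticity weights re-derived from a first pass.

    Attributes
    ----------
    h2_, h2_se_, h2_p_ : slope estimate on the observed scale.
    intercept_, intercept_se_ : regression intercept (1 + confounding).
    """

    def __init__(
        self,
        n_blocks: int = 200,
        constrain_intercept: bool = False,
        M: int | None = None,
        two_step: bool = True,
    ):
        self.n_blocks = n_blocks
        self.constrain_intercept = constrain_intercept
        self.M = M
        self.two_step = two_step

    def _design(self, x: np.ndarray):
        if self.constrain_intercept:
            return x[:, None]
        return np.column_stack([x, np.ones_like(x)])

    def fit(self, ld, chisq, N):
        ld = np.asarray(ld, dtype=float)
        y = np.asarray(chisq, dtype=float)
        m = len(ld)
        if len(y) != m:
            raise ValueError("ld and chisq must have equal length")
        if m < self.n_blocks:
            raise ValueError(
                f"{m} SNPs is fewer than {self.n_blocks} jackknife blocks; "
                "reduce n_blocks"
            )
        M = self.M if self.M is not None else m
        x = np.asarray(N, dtype=float) * ld / M
        if self.constrain_intercept:
            y = y - 1.0

        lw = np.maximum(ld, 1.0)
        w = 1.0 / lw
        X = self._design(x)
        coef0 = _wls(X, y, w)
        if self.two_step:
            slope0 = max(coef0[0], 0.0)
            i0 = coef0[1] if not self.constrain_intercept else 1.0
            a = 1.0 + slope0 * x
            c = slope0 * x + i0
            w = 1.0 / (lw * (a * a + c * c))
        self.weights_ = w

        def est(keep):
            return _wls(X[keep], y[keep], w[keep])

        full, se, reps = _jackknife(est, m, self.n_blocks)
        self.h2_ = float(full[0])
        self.h2_se_ = float(se[0])
        self.h2_p_ = _wald_p(self.h2_, self.h2_se_)
        if self.constrain_intercept:
            self.intercept_, self.intercept_se_ = 1.0, 0.0
        else:
            self.intercept_ = float(full[1])
            self.intercept_se_ = float(se[1])
        self.M_ = M
        self.n_snps_ = m
        return self

    def to_estimate(self) -> EstimateWithSE:
        return EstimateWithSE(
            estimate=self.h2_,
            se=self.h2_se_,
            n_blocks=self.n_blocks,
            p=self.h2_p_,
            intercept=self.intercept_,
            intercept_se=self.intercept_se_,
        )


def _wald_p(est: float, se: float) -> float:
    if se <= 0:
        return 1.0
    return float(np.clip(2.0 * stats.norm.sf(abs(est) / se), np.nextafter(0, 1), 1.0))


class CrossTraitLDSC(BaseEstimator):
    """Bivariate LD score regression: genetic covariance and correlation.

    The per-trait h2 regressions and the cross-trait product regression use
    the same two-pass weighting, so pairing a trait with itself recovers
    r_g = 1 identically.  The cross-trait intercept is left free and absorbs
    shared-sample noise correlation.  SEs jackknife the full ratio
    r_g = gcov / sqrt(h2_1 * h2_2) over blocks.
    """

    def __init__(self, n_blocks: int = 200, M: int | None = None):
        self.n_blocks = n_blocks
        self.M = M

    def fit(self, ld, z1, z2, N1, N2):
        ld = np.asarray(ld, dtype=float)
        z1 = np.asarray(z1, dtype=float)
        z2 = np.asarray(z2, dtype=float)
        m = len(ld)
        if not (len(z1) == len(z2) == m):
            raise ValueError("ld, z1 and z2 must have equal length")
        if m < self.n_blocks:
            raise ValueError(f"{m} SNPs is fewer than {self.n_blocks} jackknife blocks")
        M = self.M if self.M is not None else m

        x1 = np.asarray(N1, dtype=float) * ld / M
        x2 = np.asarray(N2, dtype=float) * ld / M
        xc = np.sqrt(np.asarray(N1, dtype=float) * np.asarray(N2, dtype=float)) * ld / M
        y1 = z1 * z1
        y2 = z2 * z2
        yc = z1 * z2
        lw = np.maximum(ld, 1.0)

        def two_pass(x, y, a_terms=None):
            X = np.column_stack([x, np.ones_like(x)])
            c0 = _wls(X, y, 1.0 / lw)
            slope0, i0 = c0[0], c0[1]
            if a_terms is None:
                a = 1.0 + max(slope0, 0.0) * x
                aa = a * a
            else:
                aa = a_terms
            c = slope0 * x + i0
            w = 1.0 / (lw * (aa + c * c))
            return X, w

        X1, w1 = two_pass(x1, y1)
        X2, w2 = two_pass(x2, y2)
        # per-trait inflation terms from the first-pass slopes feed the cross weights
        s1 = max(_wls(X1, y1, 1.0 / lw)[0], 0.0)
        s2 = max(_wls(X2, y2, 1.0 / lw)[0], 0.0)
        a1 = 1.0 + s1 * x1
        a2 = 1.0 + s2 * x2
        Xc, wc = two_pass(xc, yc, a_terms=a1 * a2)

        clipped = [False]

        def est(keep):
            h1 = _wls(X1[keep], y1[keep], w1[keep])
            h2 = _wls(X2[keep], y2[keep], w2[keep])
            g = _wls(Xc[keep], yc[keep], wc[keep])
            prod = h1[0] * h2[0]
            if prod <= 0:
                clipped[0] = True
                prod = np.nan
            rg = g[0] / np.sqrt(prod) if np.isfinite(prod) else np.nan
            return np.array([h1[0], h1[1], h2[0], h2[1], g[0], g[1], rg])

        full, se, reps = _jackknife(est, m, self.n_blocks)
        if np.isnan(reps[:, 6]).any():
            warnings.warn("negative h2 in some jackknife blocks; r_g SE uses valid blocks")
            valid = reps[~np.isnan(reps[:, 6]), 6]
            b = len(valid)
            se6 = (
                np.sqrt((b - 1) / b * np.sum((valid - valid.mean()) ** 2))
                if b > 1
                else np.nan
            )
            se = se.copy()
            se[6] = se6

        self.h2_1_ = EstimateWithSE(full[0], se[0], self.n_blocks, _wald_p(full[0], se[0]),
                                    intercept=full[1], intercept_se=se[1])
        self.h2_2_ = EstimateWithSE(full[2], se[2], self.n_blocks, _wald_p(full[2], se[2]),
                                    intercept=full[3], intercept_se=se[3])
        self.gcov_ = float(full[4])
        self.gcov_se_ = float(se[4])
        self.cross_intercept_ = float(full[5])
        self.cross_intercept_se_ = float(se[5])
        self.rg_defined_ = bool(full[0] > 0 and full[2] > 0)
        if self.rg_defined_:
            self.rg_ = float(full[6])
            self.rg_se_ = float(se[6])
            self.rg_p_ = _wald_p(self.rg_, self.rg_se_)
            if abs(self.rg_) > 1:
                warnings.warn(
                    f"genetic correlation estimate {self.rg_:.3f} outside [-1, 1]; "
                    "reported unclipped"
                )
        else:
            warnings.warn(
                "r_g undefined: a heritability estimate is non-positive "
                f"(h2_1={full[0]:.4g}, h2_2={full[2]:.4g})"
            )
            self.rg_ = np.nan
            self.rg_se_ = np.nan
            self.rg_p_ = np.nan
        self.M_ = M
        return self

    def to_estimate(self) -> EstimateWithSE:
        return EstimateWithSE(
            estimate=self.rg_,
            se=self.rg_se_,
            n_blocks=self.n_blocks,
            p=self.rg_p_,
            intercept=self.cross_intercept_,
            intercept_se=self.cross_intercept_se_,
        )


class StratifiedLDSC(BaseEstimator):
    """Partitioned heritability: multi-annotation LD score regression.

    Regresses chi-square on per-category scores N*l_{j,c}; coefficients
    tau_c are per-SNP heritability contributions of category membership.
    Category heritability aggregates per-SNP variances over members;
    enrichment is (h2 fraction)/(SNP fraction).  With the single all-ones
    base category this reduces exactly to the univariate regression.
    """

    def __init__(self, n_blocks: int = 200, two_step: bool = True):
        self.n_blocks = n_blocks
        self.two_step = two_step

    def fit(self, ld_categories, chisq, N, annotations):
        L = np.asarray(
            ld_categories.categories if isinstance(ld_categories, LDScores) else ld_categories,
            dtype=float,
        )
        names = (
            ld_categories.category_names
            if isinstance(ld_categories, LDScores) and ld_categories.category_names
            else [f"cat{i}" for i in range(L.shape[1])]
        )
        y = np.asarray(chisq, dtype=float)
        if hasattr(annotations, "columns"):
            A = annotations[[c for c in annotations.columns if c != "SNP"]].to_numpy(float)
        else:
            A = np.asarray(annotations, dtype=float)
        m, C = L.shape
        if A.shape != (m, C):
            raise ValueError("annotation matrix must match LD-score matrix shape")
        counts = A.sum(axis=0)
        if np.any(counts == 0):
            empty = [names[i] for i in np.flatnonzero(counts == 0)]
            raise ValueError(f"annotation categories with zero SNPs: {empty}")
        if m < self.n_blocks:
            raise ValueError(f"{m} SNPs is fewer than {self.n_blocks} jackknife blocks")

        Nf = np.asarray(N, dtype=float)
        X = (Nf * L.T).T  # (m, C)
        X = np.column_stack([X, np.ones(m)])
        ltot = L[:, 0] if names and names[0] in ("base", "cat0") else L.sum(axis=1)
        lw = np.maximum(ltot, 1.0)
        w = 1.0 / lw
        coef0 = _wls(X, y, w)
        if self.two_step:
            fitted = X @ coef0
            i0 = coef0[-1]
            a = 1.0 + np.maximum(fitted - i0, 0.0)
            c = fitted
            w = 1.0 / (lw * (a * a + c * c))
        self.weights_ = w

        def est(keep):
            coef = _wls(X[keep], y[keep], w[keep])
            tau = coef[:-1]
            per_snp = A @ tau
            h2_cat = A.T @ per_snp
            h2_tot = float(per_snp.sum())
            enr = (h2_cat / h2_tot) / (counts / m) if h2_tot != 0 else np.full(C, np.nan)
            return np.concatenate([tau, [coef[-1], h2_tot], enr])

        full, se, _ = _jackknife(est, m, self.n_blocks)
        tau = full[:C]
        tau_se = se[:C]
        per_snp = A @ tau
        h2_cat = A.T @ per_snp
        h2_tot = full[C + 1]
        self.result_ = StratifiedResult(
            category_names=list(names),
            tau=tau,
            tau_se=tau_se,
            tau_z=np.divide(tau, tau_se, out=np.zeros_like(tau), where=tau_se > 0),
            h2_category=h2_cat,
            h2_total=float(h2_tot),
            snp_fraction=counts / m,
            h2_fraction=h2_cat / h2_tot if h2_tot != 0 else np.full(C, np.nan),
            enrichment=full[C + 2 :],
            enrichment_se=se[C + 2 :],
            n_blocks=self.n_blocks,
        )
        self.intercept_ = float(full[C])
        self.intercept_se_ = float(se[C])
        self.h2_total_ = float(h2_tot)
        return self


def observed_to_liability(h2_obs: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale heritability for case-control traits.

    h2_liab = h2_obs * K^2 (1-K)^2 / (P(1-P) * phi(Phi^-1(1-K))^2), with K the
    population prevalence and P the sample case fraction.
    """
    if not 0 < K < 1:
        raise ValueError("population prevalence K must be in (0, 1)")
    if not 0 < P < 1:
        raise ValueError("sample case fraction P must be in (0, 1)")
    t = stats.norm.ppf(1.0 - K)
    phi = stats.norm.pdf(t)
    return h2_obs * K**2 * (1.0 - K) ** 2 / (P * (1.0 - P) * phi**2)


def estimate_h2(chisq, ld, N, n_blocks: int = 200, constrain_intercept: bool = False,
                M: int | None = None) -> EstimateWithSE:
    """Functional wrapper around UnivariateLDSC."""
    model = UnivariateLDSC(n_blocks=n_blocks, constrain_intercept=constrain_intercept, M=M)
    ldv = ld.total if isinstance(ld, LDScores) else ld
    return model.fit(ldv, chisq, N).to_estimate()


def estimate_rg(z1, z2, ld, N1, N2, n_blocks: int = 200, M: int | None = None):
    """Functional wrapper around CrossTraitLDSC; returns the fitted estimator."""
    ldv = ld.total if isinstance(ld, LDScores) else ld
    return CrossTraitLDSC(n_blocks=n_blocks, M=M).fit(ldv, z1, z2, N1, N2)


def stratified_h2(chisq, ld_categories, N, annotations, n_blocks: int = 200) -> StratifiedResult:
    """Functional wrapper around StratifiedLDSC."""
    model = StratifiedLDSC(n_blocks=n_blocks)
    model.fit(ld_categories, chisq, N, annotations)
    return model.result_
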