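"""Bivariate causal mixture model of polygenic overlap.

Effect sizes of each SNP on two traits are modelled as a four-component
mixture: a null component, two trait-specific components, and a shared
(pleiotropic) component with correlated effects,

    (b1j, b2j) ~ pi0*N(0,0) + pi1*N(0,S1) + pi2*N(0,S2) + pi12*N(0,S12),

with S1 = diag(s1^2, 0), S2 = diag(0, s2^2) and S12 having off-diagonal
rho12*s1*s2.  The model is fit to paired GWAS Z-scores by a per-SNP
moment-matched likelihood: conditional on its mixture component, the Z-score
pair of SNP j is bivariate normal with unit noise variance plus an LD- and
sample-size-inflated genetic term (n_i * l_j * s_i^2 on the diagonal,
sqrt(n1*n2) * l_j * rho12*s1*s2 off it, l_j the SNP's LD score).  This is a
tractable approximation that ignores the full convolution of effects across
LD neighbours; see the methods note for what it does and does not capture.

The fitted parameters yield Venn-diagram quantities: the number of causal
variants unique to each trait and shared between them, counting the variants
needed to explain 90% of each trait's SNP heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "MixtureParams",
    "VennSummary",
    "CausalMixtureModel",
    "fit_mixture",
    "venn_counts",
    "variance_capture_fraction",
    "conditional_qq",
]


@dataclass
class MixtureParams:
    """Parameters of the four-component bivariate causal mixture.

    pi0, pi1, pi2, pi12 : mixture proportions (null, trait-1 only,
        trait-2 only, shared); must sum to 1.
    sigma1_sq, sigma2_sq : per-SNP effect-size variances on the
        standardized-genotype scale for causal SNPs of each trait.
    rho12 : correlation of effect sizes within the shared component.
    """

    pi0: float
    pi1: float
    pi2: float
    pi12: float
    sigma1_sq: float
    sigma2_sq: float
    rho12: float

    def __post_init__(self) -> None:
        pis = np.array([self.pi0, self.pi1, self.pi2, self.pi12], dtype=float)
        if np.any(pis < -1e-12) or np.any(pis > 1 + 1e-12):
            raise ValueError("mixture proportions must lie in [0, 1]")
        if abs(pis.sum() - 1.0) > 1e-12:
            raise ValueError(f"mixture proportions must sum to 1 (got {pis.sum()!r})")
        if self.sigma1_sq < 0 or self.sigma2_sq < 0:
            raise ValueError("effect variances must be non-negative")
        if abs(self.rho12) > 1:
            raise ValueError("|rho12| must be <= 1")

    @property
    def proportions(self) -> np.ndarray:
        return np.array([self.pi0, self.pi1, self.pi2, self.pi12])

    @property
    def implied_rg(self) -> float:
        """Genome-wide genetic correlation implied by the mixture.

        r_g = pi12*rho12*s1*s2 / sqrt((pi1+pi12)*s1^2 * (pi2+pi12)*s2^2).
        """
        denom = np.sqrt(
            (self.pi1 + self.pi12) * self.sigma1_sq * (self.pi2 + self.pi12) * self.sigma2_sq
        )
        if denom == 0:
            return np.nan
        s1 = np.sqrt(self.sigma1_sq)
        s2 = np.sqrt(self.sigma2_sq)
        return self.pi12 * self.rho12 * s1 * s2 / denom

    @classmethod
    def from_h2(
        cls,
        h2_1: float,
        h2_2: float,
        m_snps: int,
        pi1: float = 0.0,
        pi2: float = 0.0,
        pi12: float = 0.01,
        rho12: float = 0.0,
    ) -> "MixtureParams":
        """Back-solve per-SNP effect variances from target heritabilities.

        Uses h2 = m * pi_causal * sigma_sq with pi_causal the total causal
        proportion for the trait (trait-specific plus shared component).
        """
        pc1 = pi1 + pi12
        pc2 = pi2 + pi12
        if pc1 <= 0 or pc2 <= 0:
            raise ValueError("each trait needs a positive causal proportion")
        return cls(
            pi0=1.0 - pi1 - pi2 - pi12,
            pi1=pi1,
            pi2=pi2,
            pi12=pi12,
            sigma1_sq=h2_1 / (m_snps * pc1),
            sigma2_sq=h2_2 / (m_snps * pc2),
            rho12=rho12,
        )


@dataclass
class VennSummary:
    """Causal-variant counts (in thousands) for the polygenic-overlap Venn diagram.

    Counts refer to the variants needed to explain 90% of each trait's SNP
    heritability; `fraction_90` is the fraction of causal variants retained
    by that rule (a universal constant for Gaussian effect sizes).
    """

    unique_trait1_k: float
    unique_trait2_k: float
    shared_k: float
    total_trait1_k: float
    total_trait2_k: float
    fraction_90: float
    se: dict = field(default_factory=dict)


def _mixture_nll(theta: np.ndarray, z1, z2, a1, a2, c_scale, pi_floor: float) -> float:
    """Negative log-likelihood of the per-SNP moment-matched mixture.

    theta = (t1, t2, t3, log s1^2, log s2^2, atanh rho); proportions are
    softmax([0, t1, t2, t3]) floored at pi_floor each.
    """
    pis = _theta_to_pis(theta, pi_floor)
    s1sq = np.exp(theta[3])
    s2sq = np.exp(theta[4])
    rho = np.tanh(theta[5])

    v1 = a1 * s1sq  # per-SNP genetic inflation, trait 1
    v2 = a2 * s2sq
    cv = c_scale * rho * np.sqrt(s1sq * s2sq)

    z1sq = z1 * z1
    z2sq = z2 * z2
    z12 = z1 * z2

    def _logpdf(s1, s2, c):
        det = s1 * s2 - c * c
        q = (s2 * z1sq - 2.0 * c * z12 + s1 * z2sq) / det
        return -np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * q

    lp = np.stack(
        [
            _logpdf(1.0, 1.0, 0.0) * np.ones_like(z1),
            _logpdf(1.0 + v1, 1.0, 0.0),
            _logpdf(1.0, 1.0 + v2, 0.0),
            _logpdf(1.0 + v1, 1.0 + v2, cv),
        ]
    )
    return -float(np.sum(logsumexp(lp + np.log(pis)[:, None], axis=0)))


def _theta_to_pis(theta: np.ndarray, pi_floor: float) -> np.ndarray:
    logits = np.concatenate([[0.0], np.asarray(theta[:3], dtype=float)])
    logits = logits - logits.max()
    p = np.exp(logits)
    p /= p.sum()
    return pi_floor + (1.0 - 4.0 * pi_floor) * p


def _theta_to_params(theta: np.ndarray, pi_floor: float) -> MixtureParams:
    pis = _theta_to_pis(theta, pi_floor)
    return MixtureParams(
        pi0=pis[0],
        pi1=pis[1],
        pi2=pis[2],
        pi12=pis[3],
        sigma1_sq=float(np.exp(theta[3])),
        sigma2_sq=float(np.exp(theta[4])),
        rho12=float(np.tanh(theta[5])),
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    k = len(x)
    H = np.empty((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = eps
            ej[j] = eps
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps * eps)
    # guard against NaN from boundary evaluations
    if not np.all(np.isfinite(H)):
        H = np.where(np.isfinite(H), H, 0.0)
        np.fill_diagonal(H, np.maximum(np.diag(H), 1.0 / eps))
    del f0
    return H


class CausalMixtureModel(BaseEstimator):
    """Maximum-likelihood fit of the four-component causal mixture to paired Z-scores.

    Parameters
    ----------
    n_starts : number of random multi-starts of the optimizer.
    max_iter : L-BFGS iteration cap per start.
    random_state : seed for the multi-start draws.
    pi_floor : lower bound for each mixture proportion; defaults to 1/m
        at fit time when None.

    Attributes (after fit)
    ----------------------
    params_ : MixtureParams at the best optimum.
    se_ : dict of delta-method standard errors for the natural parameters.
    loglik_ : maximized log-likelihood.
    loglik_path_ : per-iteration log-likelihood of the winning start
        (non-decreasing).
    null_loglik_ : log-likelihood of the pure-null (unit bivariate normal) model.
    converged_ : whether the winning start reported convergence.
    boundary_ : dict of parameters flagged at or near their bounds.
    """

    def __init__(
        self,
        n_starts: int = 10,
        max_iter: int = 300,
        random_state: int = 0,
        pi_floor: float | None = None,
    ):
        self.n_starts = n_starts
        self.max_iter = max_iter
        self.random_state = random_state
        self.pi_floor = pi_floor

    def fit(self, z1, z2, ld, n1: float, n2: float):
        z1 = np.asarray(z1, dtype=float)
        z2 = np.asarray(z2, dtype=float)
        ld = np.asarray(ld, dtype=float)
        if not (len(z1) == len(z2) == len(ld)):
            raise ValueError("z1, z2 and ld must have equal length")
        m = len(z1)
        pi_floor = self.pi_floor if self.pi_floor is not None else 1.0 / m

        a1 = n1 * ld
        a2 = n2 * ld
        c_scale = np.sqrt(n1 * n2) * ld

        def nll(theta):
            return _mixture_nll(theta, z1, z2, a1, a2, c_scale, pi_floor)

        # data-driven variance scale: excess chi-square per causal SNP
        lbar = float(np.mean(ld))
        exc1 = max(float(np.mean(z1**2)) - 1.0, 1e-3)
        exc2 = max(float(np.mean(z2**2)) - 1.0, 1e-3)

        rng = np.random.default_rng(self.random_state)
        best = None
        best_path: list[float] = []
        traces = []
        for _ in range(self.n_starts):
            t = rng.normal(-4.0, 1.5, size=3)
            pi_guess = _theta_to_pis(np.concatenate([t, np.zeros(3)]), pi_floor)
            u1 = np.log(exc1 / (n1 * lbar * max(pi_guess[1] + pi_guess[3], pi_floor)))
            u2 = np.log(exc2 / (n2 * lbar * max(pi_guess[2] + pi_guess[3], pi_floor)))
            v = float(np.arctanh(np.clip(rng.uniform(-0.8, 0.8), -0.999, 0.999)))
            theta0 = np.concatenate([t, [u1, u2, v]])

            path: list[float] = []
            res = optimize.minimize(
                nll,
                theta0,
                method="L-BFGS-B",
                callback=lambda xk: path.append(-nll(xk)),
                options={"maxiter": self.max_iter},
            )
            traces.append({"start": theta0.tolist(), "fun": float(res.fun), "status": res.message})
            if best is None or res.fun < best.fun:
                best = res
                best_path = path
        if best is None or not np.isfinite(best.fun):
            raise RuntimeError(f"mixture fit failed on all starts; trace: {traces}")

        self.theta_ = best.x
        self.converged_ = bool(best.success)
        self.n_iter_ = int(best.nit)
        self.optim_trace_ = traces
        self.loglik_ = -float(best.fun)
        self.loglik_path_ = best_path
        self.null_loglik_ = -_mixture_nll(
            np.array([-30.0, -30.0, -30.0, -10.0, -10.0, 0.0]), z1, z2, a1, a2, c_scale, 0.0
        )
        self.params_ = _theta_to_params(best.x, pi_floor)
        self.pi_floor_ = pi_floor
        self.m_snps_ = m

        self._compute_se(nll)
        self.boundary_ = {}
        for name in ("pi1", "pi2", "pi12"):
            if getattr(self.params_, name) < 2.5 * pi_floor:
                self.boundary_[name] = getattr(self.params_, name)
        if abs(self.params_.rho12) > 0.995:
            self.boundary_["rho12"] = self.params_.rho12
        if self.boundary_:
            warnings.warn(f"mixture parameters at/near boundary: {self.boundary_}")
        return self

    def _compute_se(self, nll) -> None:
        """Delta-method SEs of the natural parameters from the observed information."""
        H = _numerical_hessian(nll, self.theta_)
        # observed information; pseudo-inverse guards flat directions at bounds
        cov_theta = np.linalg.pinv(H)

        def natural(theta):
            p = _theta_to_params(theta, self.pi_floor_)
            return np.array(
                [p.pi0, p.pi1, p.pi2, p.pi12, p.sigma1_sq, p.sigma2_sq, p.rho12]
            )

        eps = 1e-5
        k = len(self.theta_)
        J = np.empty((7, k))
        for i in range(k):
            e = np.zeros(k)
            e[i] = eps
            J[:, i] = (natural(self.theta_ + e) - natural(self.theta_ - e)) / (2 * eps)
        cov_nat = J @ cov_theta @ J.T
        names = ["pi0", "pi1", "pi2", "pi12", "sigma1_sq", "sigma2_sq", "rho12"]
        var = np.clip(np.diag(cov_nat), 0.0, None)
        self.se_ = dict(zip(names, np.sqrt(var)))
        self.cov_natural_ = cov_nat


def fit_mixture(
    z1, z2, ld, n1: float, n2: float, n_starts: int = 10, random_state: int = 0
) -> CausalMixtureModel:
    """Functional wrapper: fit the causal mixture and return the fitted model."""
    return CausalMixtureModel(n_starts=n_starts, random_state=random_state).fit(
        z1, z2, ld, n1, n2
    )


def variance_capture_fraction(q: float = 0.9) -> float:
    """Fraction of causal variants explaining a fraction q of genetic variance.

    For Gaussian effect sizes b ~ N(0, s^2), the variants with b^2 above a
    threshold t explain E[b^2; b^2>t]/E[b^2] = P(chi2_3 > t/s^2) of the
    variance, while P(b^2 > t) = P(chi2_1 > t/s^2) of the causals are kept.
    The retained fraction is therefore a universal constant independent of s.
    """
    if not 0 < q < 1:
        raise ValueError("q must be in (0,1)")
    u = stats.chi2.isf(q, df=3)
    return float(stats.chi2.sf(u, df=1))


def venn_counts(
    params: MixtureParams, m_snps: int, se: dict | None = None, q: float = 0.9
) -> VennSummary:
    """Venn-diagram counts (thousands) of causal variants explaining 90% of h2.

    Counts scale linearly in m_snps and in the mixture proportions; SEs, when
    proportion SEs are supplied, propagate by the same linear (delta) map.
    """
    f = variance_capture_fraction(q)
    scale = m_snps * f / 1000.0
    out_se = {}
    if se is not None:
        out_se = {
            "unique_trait1_k": se.get("pi1", np.nan) * scale,
            "unique_trait2_k": se.get("pi2", np.nan) * scale,
            "shared_k": se.get("pi12", np.nan) * scale,
        }
    return VennSummary(
        unique_trait1_k=params.pi1 * scale,
        unique_trait2_k=params.pi2 * scale,
        shared_k=params.pi12 * scale,
        total_trait1_k=(params.pi1 + params.pi12) * scale,
        total_trait2_k=(params.pi2 + params.pi12) * scale,
        fraction_90=f,
        se=out_se,
    )


def conditional_qq(
    p_primary,
    p_secondary,
    strata: tuple = (0.1, 0.01, 0.001),
    include_all: bool = True,
) -> pd.DataFrame:
    """Conditional Q-Q table: primary-trait quantiles within secondary-trait strata.

    For each cutoff c, SNPs with secondary p < c form a stratum; within it the
    sorted observed -log10(p) of the primary trait is paired with the expected
    -log10((i-0.5)/n).  Cross-trait enrichment shows as successive leftward
    (upward) separation of strata.  Empty strata are dropped with a warning.
    """
    p1 = np.asarray(p_primary, dtype=float)
    p2 = np.asarray(p_secondary, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("p_primary and p_secondary must have the same length")
    cuts = ([1.0] if include_all else []) + sorted(strata, reverse=True)
    frames = []
    for c in cuts:
        mask = p2 < c if c < 1.0 else np.ones_like(p2, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            warnings.warn(f"conditional Q-Q stratum p<{c} is empty; omitted")
            continue
        obs = np.sort(p1[mask])
        expected = (np.arange(1, n + 1) - 0.5) / n
        frames.append(
            pd.DataFrame(
                {
                    "stratum": c,
                    "expected_neglog10": -np.log10(expected),
                    "observed_neglog10": -np.log10(np.clip(obs, 1e-300, 1.0)),
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["stratum", "expected_neglog10", "observed_neglog10"])
    return pd.concat(frames, ignore_index=True)
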