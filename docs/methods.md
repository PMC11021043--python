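# Methods

This note documents the models behind each module, the choices made where
the design was genuinely open, what the synthetic-data generator does and
does not emulate, and the numerical details a user re-deriving our results
would need. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Generative model for synthetic GWAS data

The generator (`pleiokit.simulate`) produces the full chain that the
analyses assume:

**Genotypes.** A reference panel of `n_ref` individuals with `m` SNPs in
contiguous LD blocks of `block_size` SNPs. Within a block, SNPs follow a
first-order autoregressive correlation, corr(xᵢ, xⱼ) = ρ^|i−j|; across
blocks (and always across chromosome labels) the correlation is zero.
Columns are empirically standardized. Two LD regimes are offered:

- *Homogeneous* (`rho_max=None`): every block uses the same ρ. This yields
  closed-form LD scores — an interior SNP has ℓ = 1 + 2ρ²/(1−ρ²), e.g.
  exactly 5/3 at ρ = 0.5 — and is used for the oracle tests.
- *Heterogeneous* (`rho_max` set): each block draws its AR(1) coefficient
  uniformly from [ρ, ρ_max]. Real genomes have strongly varying local LD,
  and this variation is precisely the leverage of LD score regression:
  with a single ρ, LD scores are nearly constant (only block-edge SNPs
  differ) and the slope of χ² on ℓ is essentially unidentified. The
  recovery studies therefore use ρ ∈ [0.1, 0.9].

**Effects.** Each SNP lands independently in one of four components with
probabilities (π₀, π₁, π₂, π₁₂): no effect, trait-1 only (variance σ₁²),
trait-2 only (σ₂²), or shared, where the pair of effects is bivariate
normal with correlation ρ₁₂. Effects are on the standardized-genotype
scale, so the expected heritability is h² = m·π_causal·σ² and
`MixtureParams.from_h2` back-solves σ² from a target h². The implied
genome-wide genetic correlation is
r_g = π₁₂ρ₁₂σ₁σ₂ / √((π₁+π₁₂)σ₁²·(π₂+π₁₂)σ₂²); with all causals shared it
reduces to ρ₁₂.

**Summary statistics.** Z-scores follow the standard model
Z = √n·Rβ + ε with ε ~ N(0, R), applied block by block. R is the *panel's
empirical* within-block correlation (ridge 10⁻⁶ for the Cholesky), so the
LD the Z-scores are generated under is exactly the LD the estimators see —
this removes reference-mismatch noise from the recovery oracles. Sample
overlap between the two GWAS is modelled by sharing a fraction f of the
noise: ε_t = √f·ε_shared + √(1−f)·ε_own, which makes the null cross-trait
Z correlation equal to f — the quantity the cross-trait regression
intercept and the local-covariance r_ov term absorb. (The generative
mechanism behind overlap-induced correlation is a modelling choice; shared
noise is the simplest construction with the right second moments.)

**What is not emulated:** allele-frequency spectra (all genotypes are
standardized Gaussians), imputation error, minor-allele-count effects,
sex chromosomes, population stratification, and long-range LD. Passing
tests therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to real-data pathologies.

## Summary-statistics QC and harmonization

Mandatory columns are recognised by case-insensitive synonyms; Z is
reconstructed as β/se when absent. Rows are dropped (and counted) when a
mandatory field is missing, when p ∉ (0,1], and when χ² exceeds
max(80, N/1000) — the outlier convention of the LDSC software, exposed as
`chi2_cap`. Duplicate rsIDs keep the first occurrence. Harmonization to a
reference allele frame flips the Z sign for A1/A2 swaps and drops
strand-ambiguous (A/T, C/G) SNPs outright, since allele frequencies are
not guaranteed in the input. Note that at desk scale with sparse causal
architectures the χ² cap can clip genuine signals; the pipeline's default
simulation parameters are chosen so this is rare.

## LD score regression

LD scores use the small-sample bias adjustment r²_adj = r² − (1−r²)/(n−2)
summed over a SNP-count window restricted to the same chromosome; the self
term contributes exactly 1. Per-category scores restrict the inner sum to
annotation members and sum to the total when the categories partition the
SNPs.

The regressions are weighted least squares with two-pass weights. Pass one
uses 1/max(ℓ,1) (down-weighting over-counted SNPs in high LD); pass two
models the variance of the dependent variable as proportional to
ℓ·(a² + c²), where a = 1 + N·ĥ²ℓ/M is the per-trait inflation term and
c the pass-one fitted mean. For the χ² regression with intercept ≈ 1 this
is proportional to the usual 1/(ℓ(1+N ĥ²ℓ/M)²) scheme; its virtue is that
the univariate and cross-trait regressions share one formula
(a₁a₂ + c²), so pairing a trait with itself reproduces the χ² regression
*identically* and r_g = 1 holds exactly — a structural sanity check the
test suite asserts.

Standard errors come from a delete-one-block jackknife over contiguous SNP
blocks (200 by default; configurable, and reduced for small simulations).
For r_g the whole ratio ρ̂_g/√(ĥ₁²ĥ₂²) is jackknifed; blocks where a
heritability goes negative are excluded from the SE with a warning, and a
non-positive full-sample heritability flags r_g as undefined rather than
returning a silent NaN. r_g is never clipped to [−1,1]; out-of-range
values are reported with a warning so the estimator's sampling
distribution stays visible. M defaults to the number of regression SNPs
(the self-contained synthetic setting); for real data it should be set to
the reference SNP count.

Partitioned regression fits χ² on all per-category scores jointly
(coefficients τ_c are per-SNP variance contributions); category
heritability aggregates per-SNP variances over members, enrichment is
(h² fraction)/(SNP fraction), and coefficient z-scores use the jackknife.
The liability-scale conversion h²_liab = h²_obs·K²(1−K)²/(P(1−P)φ(t)²),
t = Φ⁻¹(1−K), requires a population prevalence K supplied by the user — it
is a modelling input, not something estimable from summary statistics.

## Local heritability and covariance

For a region with d SNPs, LD matrix R and Z-scores z, the estimator is
ĥ²_loc = (z′V⁺z − q)/(n − q) with V⁺ the rank-q truncated-SVD
pseudoinverse; under the null z′V⁺z ~ χ²_q. All formulas here take GWAS
Z-scores (the standardized-effect formulation differs by factors of √n).
The rank is the smallest q capturing 99.5% of the LD spectrum energy,
capped at min(50, d). Truncation trades a small downward bias (discarded
spectrum) for stability against noise in the estimated R; at desk scale we
therefore align regions with LD blocks (~50 SNPs), where the cap is not
binding. The cross-trait analogue is
ρ̂_loc = (z₁′V⁺z₂ − q·r_ov)/(√(n₁n₂) − q·r_ov), with r_ov the null
cross-trait Z correlation; the matching correction in the denominator
makes a trait paired with itself under full overlap reproduce ĥ²_loc
exactly, and the two estimators coincide with the uncorrected forms when
r_ov = 0. The covariance p-value uses a normal approximation to the
bilinear form (mean q·r_ov, variance q(1+r_ov²)) — cruder than the χ²
null, stated as such. Local r_g is reported only where both local
heritabilities are positive. SEs for local h² use the noncentral-χ²
variance 2(q+2λ)/(n−q)², λ = ĥ²(n−q). No genome-wide re-weighting across
held-out chromosomes is attempted; the χ² null is the variance model.

## Causal-mixture fit

The likelihood treats each SNP's Z-score pair as an independent draw from
a four-component bivariate normal mixture whose component covariances are
I (noise) plus the LD- and sample-size-inflated genetic term: nᵢℓⱼσᵢ² on
the diagonal and √(n₁n₂)ℓⱼρ₁₂σ₁σ₂ off it. This *moment-matched per-SNP
approximation* replaces the exact convolution of effects over LD
neighbours. Consequences: under strong LD the fitted π parameters absorb
LD smearing (null SNPs tagging a causal neighbour look causal), inflating
π̂ and deflating σ̂² while preserving their product and the implied r_g.
The recovery studies therefore evaluate the fit on independent SNPs,
where the likelihood is exact; on LD data the π̂/σ̂² split should be read
as an effective, not physical, decomposition. The exact convolution
likelihood is out of scope.

Optimization is L-BFGS on an unconstrained parameterization — softmax
logits for the proportions (floored at 1/m to avoid log 0), log variances,
atanh ρ₁₂ — with 10 random starts by default (fixed seeds; data-driven
variance initialisation from the mean χ² excess). SEs are delta-method
transforms of the inverse observed information (central-difference
Hessian); estimates pinned at the π floor have degenerate SEs and are
flagged as boundary cases. Venn counts use the fact that for Gaussian
effects the fraction of causal variants explaining 90% of the variance is
the universal constant P(χ²₁ > u) with P(χ²₃ > u) = 0.9 (≈ 0.445);
counts are (proportion)·m·(fraction), in thousands, with delta-method SEs.

## Adaptive gene tests

The statistics implement the signed-root convention
SPUs(γ₁; z) = sign(s)|s|^{1/γ₁}, s = Σzⱼ^{γ₁}, which keeps the statistic
sign-equivariant when the powered sum is negative (a plain γ₁-th root is
undefined there), and MTSPUsSet raises the per-trait values to γ₂ with the
same signed-power rule for odd γ₂. All p-values are two-sided on |T|.
The Monte-Carlo null draws B samples from N(0, R) (single trait) or
V^{1/2}G R^{1/2} (multi-trait), with R the gene's ridge-regularized
(10⁻⁶) LD from the reference panel and V the trait correlation estimated
from SNPs null in both traits (p > 0.05). Component p-values are
(1 + #{|T⁽ᵇ⁾| ≥ |T_obs|})/(B+1); the adaptive p recalibrates the minimum
component p against leave-one-out null minima, so its floor is 1/(B+1).
B defaults to 10,000 with automatic 10× escalation (cap 10⁶) whenever the
adaptive p falls below 50/B, keeping small p-values resolved. Per-gene RNG
substreams are keyed by gene id, so results are independent of scan order.
Pruning is a greedy left-to-right scan dropping the later SNP of any pair
with r² above threshold (default 0.5, window 100 SNPs — both declared
config, as the original choice is not documented anywhere we could adopt
it from). Gene membership uses BED half-open intervals with no flanking
window.

The pleiotropic-gene rule: significant in the multi-trait test AND in at
least one single-trait test, at α_gene = 0.05/(genes tested). The
threshold ledger always recomputes thresholds from the actual
denominators of the current run; for the gene family at genome scale the
exact quotient 0.05/12,553 = 3.98×10⁻⁶ is used (its −log₁₀ is 5.40).

## Problem sizes and reproducibility

All randomness flows from one master seed through named substreams
(CRC32-keyed), so every figure is reproducible and independent of
execution order. The reference studies use desk-scale reductions chosen
once: 20,000 SNPs / n = 50,000 / 20 replicates for LDSC recovery;
1,000 null genes at B = 1,000 for test calibration (binomial 95% band
0.037–0.064 at α = 0.05); 6,000 independent SNPs × 20 replicates for
mixture recovery; 5,000 SNPs with 50-SNP regions for local/global
consistency. These sizes trade precision for tractability; the estimators
themselves have no scale-specific constants beyond the documented
defaults.

## Known limitations

- The mixture likelihood's π/σ² decomposition is not interpretable under
  strong LD (see above); only products and ratios (h², r_g) are.
- The local-covariance p-value is a normal approximation.
- Liability-scale conversion needs an externally supplied prevalence.
- The generator's Gaussian genotypes cannot probe MAF-dependent biases.
- Strand-ambiguous SNPs are always dropped; no frequency-based rescue.
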