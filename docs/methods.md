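# Methods

## Model

`lderge` estimates h²_I, the proportion of phenotypic variance explained by
genome-wide gene–environment (G×E) interactions, from genome-wide interaction
scan (GWIS) summary statistics and block-wise LD information.

The generative model for a standardized phenotype residual Y (already adjusted
for fixed covariate effects, including the exposure main effect) is

    Y_i = Σ_j G_ji β_j + Σ_j S_ji γ_j + ε_1i E_i + ε_0i,

where G_ji is the standardized genotype of variant j, E_i the standardized
exposure, S_ji = G_ji·E_i the interaction regressor, β_j ~ N(0, h²_g/M) the
polygenic main effects, γ_j ~ N(0, h²_I/M) the polygenic interaction effects,
ε_1 ~ N(0, σ²_1) a residual-by-exposure component (the "R×E" term), and ε_0
the independent residual chosen so Var(Y) = 1.

A marginal GWIS fits, per variant, Y ~ G_j + S_j and reports the Wald Z of
the S_j term.  Under this model the second moments of the Z vector satisfy

    E(Z Zᵀ) = N h²_I L / M + (c + (K(E) − 1)(h²_I + σ²_1)) R,

with R the variant correlation (LD) matrix, L = RᵀR the LD-score matrix, N
the study sample size, K(E) the exposure kurtosis (K − 1 = 2 for a Gaussian
exposure), and c an unconstrained intercept inflated by confounding such as
population stratification.

## Estimators

**Full-LD (eigenvalue-regression) estimator.**  Eigen-decomposing each LD
block R = U D Uᵀ and whitening the Z-scores, z̃ = D^{−1/2} Uᵀ z, diagonalizes
the moment equation:

    E(z̃_j²) = N h²_I d_j / M + (c + 2(h²_I + σ²_1)).

h²_I is the slope of a weighted regression of z̃² on N d / M with a free
intercept.  The whitened regression uses the complete LD matrix; every
eigenvalue contributes a design point.

**Diagonal (LD-score) baseline.**  Regress raw z² on N l / M, where l_j is
variant j's LD score — the diagonal of L only.  Included for head-to-head
efficiency comparisons; the full-LD fit is uniformly more precise in the
package's simulation scenarios.

**Weights.**  Iteratively reweighted least squares starting at h = 0,
intercept = 1.  The full-LD weight of component j is

    w_j = min(d_j, 1) / (N·h·d_j/M + intercept)²,

with min(d, 1) damping components whose large eigenvalues are poorly
estimated from finite reference samples; the baseline weight is
1 / (2·max(l_j, 1)·(N·h·l_j/M + intercept)²).  The fitted composite intercept
replaces the theoretical 1 + 2(h²_I + σ²_1) term inside the weights (the two
are not separately identified), h is clipped at 0 and the intercept floored at
0.01 inside the weights only, and iteration stops when |Δh| < 1e−6 (at most 30
iterations).  The reported estimate is unconstrained and may be negative.

**Inference.**  Standard errors come from a delete-group jackknife over
genomic blocks (default: up to 200 contiguous groups).  The deletions reuse
the weights frozen from the full fit, so each leave-one-out estimate is a
single linear WLS solve; freezing keeps the jackknife SE calibrated against
the empirical estimator SD (recomputing the iterative weights inside each
deletion couples the SE to the point estimate and understates dispersion —
measured directly during development on the package's own simulations).  The
test is a one-sided Wald test, p = 1 − Φ(h²_I / se), one-sided because the
parameter is a variance proportion.

**What is deliberately not estimated.**  σ²_1 could formally be solved from
the intercept, but the intercept is also inflated by confounding; the package
reports the composite intercept with its decomposition formula and flags σ²_1
as non-identifiable.

## Liability scale

For binary traits analyzed on the observed 0/1 scale, estimates (and SEs)
are multiplied by K(1−K)/φ(Φ⁻¹(1−K))² (Robertson) or, under case
oversampling, by K²(1−K)²/(φ(Φ⁻¹(1−K))²·P(1−P)) (Lee), with K and P the
population and sample prevalences.  Both assume a normal liability; a large
interaction component violates this, and liability simulations in the test
suite reproduce the known upward bias for rare traits (prevalence ≤ 5%) with
large h²_I, while prevalence ≥ 10% or h²_I ≤ 5% keeps the bias modest.

## Multi-covariate aggregation

Correlated exposures are sequentially residualized (each regressed on the
residuals before it, then re-standardized to unit variance — required so each
per-covariate h²_I is on the standardized-exposure scale the model assumes).
The resulting exposures are mutually uncorrelated, per-exposure estimates are
treated as independent, and the aggregate is the sum with se = √Σse².  The
phenotype is pre-adjusted once against the full covariate set.  Heritable
covariates can induce residual dependence between per-covariate estimates that
this independence assumption ignores; no correction is attempted.

## Synthetic data

The simulation engine emulates a biobank-style study at desk scale:

- **Genotypes**: per block, a latent Gaussian with AR(1) correlation ρ
  (default 0.9) is thresholded at each variant's Hardy–Weinberg genotype
  frequencies (MAF ~ U(0.05, 0.5)), giving 0/1/2 dosages, then standardized.
  AR(1) decay-with-distance is the default because it is how LD behaves
  inside real quasi-independent blocks; an exchangeable option exists but
  makes blocks numerically rank-one (every variant shares one LD score),
  which degenerates the diagonal baseline's design and concentrates the
  whitened regression on a handful of spike components.  Thresholding
  attenuates correlations relative to the latent ρ by roughly 20–30% at these
  MAFs; ρ is therefore a latent-scale parameter, and realized genotype
  correlations sit between ~0.6ρ and ρ.  Inverting the attenuation exactly is
  impossible at high ρ (it would require latent correlations above 1).
- **Panel**: built from one genotype draw (in-sample realized LD), blocks
  eigen-decomposed with a 1e−6 eigenvalue floor.
- **Phenotypes**: per the generative model; interaction effects are drawn on
  a random 5% causal subset with variance rescaled so the total interaction
  variance equals h²_I exactly, keeping the target parameter comparable
  across causal fractions.  Binary traits threshold the standardized
  liability at Φ⁻¹(1 − prevalence).
- **Direct summary-statistic simulator**: draws Z per block from
  N(0, N·h²_I·L/M + intercept·R) via the block eigen factorization — the fast
  calibration path that skips individual-level data while exercising the full
  estimation pipeline on raw Z vectors.
- **Experiment harness**: replicated scenarios, both estimators on identical
  replicates, reporting mean, precision (1/SD), RMSE and the positive rate at
  α = 0.05.  In the individual-level engine the genotype matrix is fixed per
  scenario and exposure/effects/noise are redrawn per replicate, so the
  in-sample panel is exact and calibration is over the random effects.

Default study conditions: N = 2000 subjects, M = 2000 variants in 40 blocks
of 50, ρ = 0.9, h²_g = 0.2, standard-normal exposure, 500–1000 replicates per
scenario — sized so each calibration run completes in minutes on one core.
What the defaults do not emulate: real LD panels have far wider LD-score
spread than the synthetic AR(1) blocks, so the baseline's diagonal design is
weakly identified here and the full-LD estimator's measured precision
advantage (roughly 200–270%) greatly exceeds what real-panel analyses show
(~19–24%); the dominance ordering, not its magnitude, is the transferable
conclusion.

## Numerical and degenerate-input choices

- Eigen components with d ≤ 1e−6 are dropped (noise components of
  rank-deficient blocks); eigenvalues are reported descending.
- A fit is rejected when all eigenvalues (or LD scores) are equal — the slope
  is unidentifiable (this includes the R = I panel, for which whitening is
  the identity map and both estimators' designs are constant).
- Jackknife groups that leave an unidentifiable design after deletion are
  merged with a neighbor, with a warning.
- Allele harmonization flips Z when the study's counted allele is the panel's
  other allele and drops strand-ambiguous (A/T, C/G) variants; an overlap
  below 50% is treated as a genome-build mismatch.
- Block partitioning uses single-linkage merging of linked pairs (|r| above
  threshold within the bp window), the minimal contiguous blocks satisfying
  the constraint; chromosome changes always break blocks.
- When per-variant N varies by more than 10%, the minimum N is used
  (conservative) with a warning.

## Known limitations

- **Desk-scale test calibration.**  With only ~40 genomic blocks, the
  jackknife SE is positively correlated with the point estimate (z̃² responses
  are scaled χ²₁, whose variance tracks their squared mean), making the
  one-sided Wald test conservative: measured null rejection at α = 0.05 is
  ≈ 0.037 (continuous) and ≈ 0.030 (binary liability) against a nominal
  0.05.  The deficit shrinks as 1/√(number of leverage units); scaling the
  measured estimator skew to a realistic panel (≈ 1000 blocks, ≈ 400k
  variants) predicts rejection ≈ 0.046–0.049.  The simulation harness
  therefore validates calibration qualitatively at desk scale and
  quantitatively only in the large-panel regime.
- Polygenicity is assumed for the interaction effects; concentrated
  architectures bias h²_I downward.
- G–E correlation is not modeled; adjusting the phenotype for the exposure
  before the scan removes its main effect but not dependence between genotype
  and exposure.
- The logistic-scan path reports log-odds-scale Z-scores to an
  observed-scale estimator; at biobank sample sizes this matches the linear
  path closely (verified in the test suite), but small-sample logistic scans
  should prefer the linear path.
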