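# lderge

Estimation of the phenotypic variance explained by genome-wide
gene–environment (G×E) interactions from interaction-scan summary statistics
and full linkage-disequilibrium (LD) information.

## The problem

Biobank studies routinely run genome-wide interaction scans (GWIS): for each
variant j, a regression of the phenotype on the variant and on the
variant-by-exposure product reports a Wald Z-score for the interaction term.
The genome-wide quantity of interest is h²_I, the proportion of phenotypic
variance explained by all interaction effects jointly, under the polygenic
model

    Y = Σ_j G_j β_j + Σ_j (G_j·E) γ_j + ε₁·E + ε₀,       γ_j ~ N(0, h²_I/M).

LD-score-based methods estimate h²_I by regressing squared Z-scores on LD
scores — the diagonal of the squared LD matrix — which discards most of the
LD information and yields imprecise estimates for a component that is often
below 2% of phenotypic variance.  This package implements the full-LD
alternative: eigen-decompose each quasi-independent LD block R = U D Uᵀ,
whiten the Z-scores z̃ = D^{−1/2} Uᵀ z, and fit

    E(z̃_j²) = N·h²_I·d_j/M + intercept

by iteratively reweighted least squares, with a delete-block jackknife for
standard errors and a one-sided Wald test.  The diagonal LD-score estimator
is included as a baseline, along with Robertson/Lee liability-scale
transforms for binary traits, sequential-residualization aggregation of
multiple covariates' interaction variance, and a simulation engine that
reproduces the method's calibration experiments at desk scale.

Intended users: statistical geneticists working with GWIS summary statistics
who want variance-component estimates without individual-level genotype
access, and method developers needing a compact, fully synthetic testbed.

## Worked example

Calibration experiment — 200 replicates per scenario, both estimators on
identical simulated summary statistics (40 AR(1)-correlated blocks of 50
variants, N = M = 2000):

```python
from lderge import SimulationConfig, run_experiment

grid = [SimulationConfig(h2_I=v, replicates=200, seed=5 + k)
        for k, v in enumerate((0.0, 0.02))]
print(run_experiment(grid).to_string(index=False))
```

```
       scenario  method  truth  mean_estimate  precision     rmse  positive_rate  replicates
 h2I=0.0|s1=0.0 lder_ge   0.00       0.000471  67.127345 0.014867          0.015         200
 h2I=0.0|s1=0.0 ldsc_ge   0.00       0.003170  17.295482 0.057761          0.050         200
h2I=0.02|s1=0.0 lder_ge   0.02       0.020292  51.541811 0.019355          0.240         200
h2I=0.02|s1=0.0 ldsc_ge   0.02       0.022567  14.853582 0.067204          0.110         200
```

Reading the table: both estimators are essentially unbiased (mean ≈ truth:
0.0005 and 0.020 for the full-LD fit), but the full-LD estimator is several
times more precise than the diagonal baseline here (precision = 1/SD, 67 vs
17 under the null), which translates into higher power at h²_I = 0.02 (0.24
vs 0.11 at α = 0.05).  `positive_rate` under the null is the type-I error.

A single fit on one simulated dataset, through the same API the CLI uses:

```python
import numpy as np
from lderge import (SimulationConfig, make_synthetic_panel, simulate_exposure,
                    simulate_phenotype, run_gwis_linear, lderge_fit,
                    transform_zscores)

cfg = SimulationConfig(n=2000, m=2000, h2_I=0.03, seed=7)
panel, X = make_synthetic_panel(cfg, np.random.default_rng(7),
                                return_genotypes=True)
rng = np.random.default_rng(8)
E = simulate_exposure(cfg, rng)
Y, _ = simulate_phenotype(X, E, cfg, rng)
stats = run_gwis_linear(X, E, Y - Y.mean())
result = lderge_fit(transform_zscores(stats, panel), cfg.n, cfg.m)
print(f"h2_I = {result.h2_I:.4f}  se = {result.se:.4f}  p = {result.p_value:.4g}")
```

```
h2_I = 0.0177  se = 0.0167  p = 0.1455
```

One desk-scale replicate is noisy (true value 0.03, estimate 0.018 ± 0.017);
the variance component is resolved by sample size in real data and by
replication in the calibration harness above.

## Command line

```
lderge panel    --geno geno.npy --variants variants.tsv --maf 0.05 \
                --r-threshold 0.00373 --window-kb 100 --shrink auto --out panel.npz
lderge gwis     --geno geno.npy --variants variants.tsv --exposure e.txt \
                --pheno y.txt --out sumstats.tsv
lderge fit      --sumstats sumstats.tsv --panel panel.npz --method lder --out fit
lderge fit      --sumstats sumstats.tsv --panel panel.npz --binary \
                --prevalence 0.1 --out fit_liab
lderge aggregate --geno geno.npy --variants variants.tsv --pheno y.txt \
                --covariates covs.tsv --order age,sex,bmi --panel panel.npz --out agg
lderge simulate --config grid.yaml --seed 1 --out metrics.tsv
```

Summary statistics are tab-delimited with header columns CHR, ID, POS, A1,
A2, N and Z_INT (or BETA_INT + SE_INT).  Panels are single `.npz` archives
with self-describing metadata.  Fit results are written as twin JSON + TSV
files with a provenance header.

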