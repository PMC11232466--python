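"""Genome-wide interaction scan (GWIS): per-variant variant-by-exposure tests.

For each variant j the phenotype residual is regressed on the variant main
effect G_j and the interaction product S_j = G_j * E; the Wald Z of the S_j
coefficient is the GWIS interaction Z-score consumed by the estimator.  Both a
linear and a logistic path are provided; with large samples the two give nearly
identical downstream variance estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ld_panel import VariantInfo, _placeholder_variants

__all__ = [
    "GWISRecord",
    "SummaryStats",
    "residualize_phenotype",
    "run_gwis_linear",
    "run_gwis_logistic",
    "align_alleles",
    "standardize",
]

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class GWISRecord:
    """One variant's interaction summary statistic."""

    variant: VariantInfo
    z_interaction: float
    beta_main: float
    n: int
    model: str = "linear"
    beta_interaction: float = np.nan
    se_interaction: float = np.nan

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError(f"{self.variant.id}: sample size must be positive")
        if not np.isfinite(self.z_interaction):
            raise ValueError(f"{self.variant.id}: non-finite interaction Z")


@dataclass
class SummaryStats:
    """Ordered GWIS records with study sample size N and variant count M."""

    records: list[GWISRecord]
    n: int
    m: int = field(default=0)

    def __post_init__(self) -> None:
        if self.m == 0:
            self.m = len(self.records)
        if self.m != len(self.records):
            raise ValueError("m must equal the number of records")
        ns = np.array([r.n for r in self.records], dtype=float)
        if ns.size and ns.max() / ns.min() >= 1.1:
            warnings.warn(
                "per-variant N varies by more than 10%; the minimum N is used downstream",
                stacklevel=2,
            )

    @property
    def z(self) -> np.ndarray:
        return np.array([r.z_interaction for r in self.records])

    @property
    def min_n(self) -> int:
        return min(r.n for r in self.records)

    def ids(self) -> list[str]:
        return [r.variant.id for r in self.records]


def standardize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Center and scale to unit variance with denominator n (population SD)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("cannot standardize a constant vector")
    return (x - mu) / sd


def residualize_phenotype(Y: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """OLS residuals of Y on the covariate matrix (which must include an intercept).

    The returned residuals are orthogonal to every covariate column.  A
    rank-deficient covariate matrix is rejected with the offending columns
    named.
    """
    Y = np.asarray(Y, dtype=float)
    C = np.atleast_2d(np.asarray(covariates, dtype=float))
    if C.shape[0] != Y.shape[0]:
        C = C.T
    rank = np.linalg.matrix_rank(C)
    if rank < C.shape[1]:
        # identify a minimal set of dependent columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(C, mode="economic", pivoting=True)
        dependent = sorted(piv[rank:].tolist())
        raise ValueError(f"covariate matrix is rank-deficient; dependent column(s) {dependent}")
    coef, *_ = np.linalg.lstsq(C, Y, rcond=None)
    return Y - C @ coef


def run_gwis_linear(
    G: np.ndarray,
    E: np.ndarray,
    Y_res: np.ndarray,
    variants: Sequence[VariantInfo] | None = None,
) -> SummaryStats:
    """Marginal interaction scan: per variant, OLS of Y_res on (1, G_j, G_j*E).

    Columns of G and E must be standardized (mean 0, variance 1).  The Wald Z
    of the product term is reported.  Variants whose product term has zero
    variance are dropped with a warning.

    The per-variant fits are solved in closed form simultaneously: after
    centering, the two-predictor coefficients come from each variant's 2x2
    normal equations, with residual variance on n - 3 degrees of freedom.
    """
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float).ravel()
    y = np.asarray(Y_res, dtype=float).ravel()
    n, m = G.shape
    _check_standardized(G, E)

    S = G * E[:, None]
    y_c = y - y.mean()
    G_c = G - G.mean(axis=0)
    S_c = S - S.mean(axis=0)

    gg = np.einsum("ij,ij->j", G_c, G_c)
    ss = np.einsum("ij,ij->j", S_c, S_c)
    gs = np.einsum("ij,ij->j", G_c, S_c)
    gy = G_c.T @ y_c
    sy = S_c.T @ y_c
    yy = float(y_c @ y_c)

    det = gg * ss - gs * gs
    ok = ss > 1e-12 * n
    ok &= det > 1e-12
    if not np.all(ok):
        warnings.warn(
            f"dropped {int((~ok).sum())} variant(s) with degenerate interaction term",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_g = (ss * gy - gs * sy) / det
        beta_s = (gg * sy - gs * gy) / det
        rss = yy - beta_g * gy - beta_s * sy
        sigma2 = np.maximum(rss, 0.0) / (n - 3)
        se_s = np.sqrt(sigma2 * gg / det)
        z = beta_s / se_s

    if variants is None:
        variants = _placeholder_variants(m)
    records = [
        GWISRecord(
            variant=variants[j],
            z_interaction=float(z[j]),
            beta_main=float(beta_g[j]),
            n=n,
            model="linear",
            beta_interaction=float(beta_s[j]),
            se_interaction=float(se_s[j]),
        )
        for j in range(m)
        if ok[j]
    ]
    return SummaryStats(records=records, n=n)


def run_gwis_logistic(
    G: np.ndarray,
    E: np.ndarray,
    y_binary: np.ndarray,
    covariates: np.ndarray | None = None,
    variants: Sequence[VariantInfo] | None = None,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> SummaryStats:
    """Per-variant logistic fits of a binary outcome on (covariates, G_j, G_j*E).

    Newton-Raphson (equivalently IRLS) is run for all variants simultaneously;
    the Wald Z of the product term is reported.  Variants showing divergence
    symptomatic of perfect separation are dropped with a warning.
    """
    G = np.asarray(G, dtype=float)
    E = np.asarray(E, dtype=float).ravel()
    y = np.asarray(y_binary, dtype=float).ravel()
    n, m = G.shape
    uniq = np.unique(y)
    if not np.all(np.isin(uniq, (0.0, 1.0))) or uniq.size < 2:
        raise ValueError("y must be binary {0,1} with both classes present")

    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            C = C.T
        if not np.any(np.ptp(C, axis=0) == 0):
            C = np.column_stack([np.ones(n), C])
    k = C.shape[1]
    p = k + 2  # covariates + G_j + S_j

    S = G * E[:, None]
    # design per variant: X_j = [C, G_j, S_j]; batched Newton across variants
    beta = np.zeros((m, p))
    beta[:, 0] = np.log(y.mean() / (1 - y.mean()))  # intercept warm start
    alive = np.ones(m, dtype=bool)

    for _ in range(max_iter):
        eta = C @ beta[:, :k].T + G * beta[:, k] + S * beta[:, k + 1]  # n x m
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        resid = y[:, None] - mu
        # score vector per variant
        score = np.empty((m, p))
        score[:, :k] = resid.T @ C
        score[:, k] = np.einsum("ij,ij->j", resid, G)
        score[:, k + 1] = np.einsum("ij,ij->j", resid, S)
        # Fisher information per variant
        info = np.empty((m, p, p))
        for a in range(k):
            wc = w * C[:, a : a + 1]
            info[:, a, :k] = wc.T @ C
            info[:, a, k] = np.einsum("ij,ij->j", wc, G)
            info[:, a, k + 1] = np.einsum("ij,ij->j", wc, S)
        info[:, k, :k] = info[:, :k, k]
        info[:, k + 1, :k] = info[:, :k, k + 1]
        info[:, k, k] = np.einsum("ij,ij->j", w * G, G)
        info[:, k, k + 1] = np.einsum("ij,ij->j", w * G, S)
        info[:, k + 1, k] = info[:, k, k + 1]
        info[:, k + 1, k + 1] = np.einsum("ij,ij->j", w * S, S)
        try:
            step = np.linalg.solve(info, score[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            step = np.stack(
                [np.linalg.lstsq(info[j], score[j], rcond=None)[0] for j in range(m)]
            )
        beta += step
        bad = ~np.all(np.isfinite(beta), axis=1) | (np.abs(beta).max(axis=1) > 50)
        if bad.any():
            alive &= ~bad
            beta[bad] = 0.0
        if np.abs(step[alive]).max(initial=0.0) < tol:
            break

    # final information for SEs
    eta = C @ beta[:, :k].T + G * beta[:, k] + S * beta[:, k + 1]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    se = np.full(m, np.nan)
    for j in np.flatnonzero(alive):
        Xj = np.column_stack([C, G[:, j], S[:, j]])
        Ij = (Xj * w[:, j : j + 1]).T @ Xj
        try:
            cov = np.linalg.inv(Ij)
            se[j] = np.sqrt(cov[k + 1, k + 1])
        except np.linalg.LinAlgError:
            alive[j] = False
    if not alive.all():
        warnings.warn(
            f"dropped {int((~alive).sum())} variant(s): separation or singular fit",
            stacklevel=2,
        )

    if variants is None:
        variants = _placeholder_variants(m)
    records = [
        GWISRecord(
            variant=variants[j],
            z_interaction=float(beta[j, k + 1] / se[j]),
            beta_main=float(beta[j, k]),
            n=n,
            model="logistic",
            beta_interaction=float(beta[j, k + 1]),
            se_interaction=float(se[j]),
        )
        for j in np.flatnonzero(alive)
    ]
    return SummaryStats(records=records, n=n)


def align_alleles(stats: SummaryStats, panel_variants: Sequence[VariantInfo]) -> SummaryStats:
    """Harmonize study summary statistics to a panel's variant order and allele coding.

    Variants are intersected by ID; the Z sign flips when the study's counted
    allele is the panel's other allele; strand-ambiguous variants (A/T, C/G)
    are dropped.  Output order follows the panel.  Fewer than 50% of panel
    variants matching is treated as a build mismatch and rejected.
    """
    study = {}
    for rec in stats.records:
        if rec.variant.id in study:
            raise ValueError(f"duplicate variant ID in summary statistics: {rec.variant.id}")
        study[rec.variant.id] = rec

    out: list[GWISRecord] = []
    matched = 0
    for pv in panel_variants:
        rec = study.get(pv.id)
        if rec is None:
            continue
        matched += 1
        sv = rec.variant
        if frozenset((sv.a1.upper(), sv.a2.upper())) in _AMBIGUOUS:
            continue
        if (sv.a1, sv.a2) == (pv.a1, pv.a2):
            flip = 1.0
        elif (sv.a1, sv.a2) == (pv.a2, pv.a1):
            flip = -1.0
        else:
            continue  # allele mismatch beyond a swap: not the same variant
        out.append(
            GWISRecord(
                variant=pv,
                z_interaction=flip * rec.z_interaction,
                beta_main=flip * rec.beta_main,
                n=rec.n,
                model=rec.model,
                beta_interaction=flip * rec.beta_interaction,
                se_interaction=rec.se_interaction,
            )
        )
    if matched < 0.5 * len(panel_variants):
        raise ValueError(
            f"only {matched}/{len(panel_variants)} panel variants found in summary "
            "statistics; genome-build or ID-scheme mismatch suspected"
        )
    return SummaryStats(records=out, n=stats.n)


def _check_standardized(G: np.ndarray, E: np.ndarray, tol: float = 1e-4) -> None:
    if abs(float(E.mean())) > tol or abs(float(E.var()) - 1.0) > 1e-2:
        raise ValueError("exposure E must be standardized (mean 0, var 1)")
    mu = G.mean(axis=0)
    var = G.var(axis=0)
    if np.abs(mu).max() > tol or np.abs(var - 1.0).max() > 1e-2:
        raise ValueError("genotype columns must be standardized (mean 0, var 1)")
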