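"""Variance-component estimation for gene-environment interactions.

Two method-of-moments estimators of h2_I, the proportion of phenotypic
variance explained by genome-wide variant-by-exposure interactions, fitted
from GWIS interaction Z-scores:

* the full-LD eigenvalue-regression estimator: Z-scores are whitened per
  block by D^{-1/2} U' from the LD eigen-decomposition R = U D U', after which

      E(z~_j^2) = N h2_I d_j / M + (c + 2 (h2_I + sigma1^2)),

  a straight line in the eigenvalue d_j whose slope-over-(N/M) is h2_I and
  whose intercept is a composite of confounding inflation c and the residual-
  by-exposure term sigma1^2;

* the LD-score (diagonal) baseline: E(z_j^2) = N h2_I l_j / M + intercept,
  with l_j the variant's LD score, which uses only the diagonal of the
  squared LD matrix.

Both are fitted by iteratively reweighted least squares with a free intercept
and a delete-block jackknife for standard errors; inference is a one-sided
Wald test (h2_I is a variance proportion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .gwis import SummaryStats
from .ld_panel import EigenSystem

__all__ = [
    "TransformedStats",
    "EstimateResult",
    "transform_zscores",
    "lderge_fit",
    "ldsc_ge_fit",
    "jackknife_se",
    "wald_test",
    "intercept_components",
    "InterceptDecomposition",
    "bernoulli_kurtosis",
]

# Floor applied to the fitted intercept *inside the weights only*, keeping the
# weight denominator positive when a noisy iterate dips near zero.  The
# reported intercept is unconstrained.
_WEIGHT_INTERCEPT_FLOOR = 1e-2


@dataclass
class TransformedStats:
    """Whitened Z-scores and aligned eigenvalues, kept per block for the jackknife."""

    z_tilde: list[np.ndarray]
    d: list[np.ndarray]
    block_ids: list[int]

    def __post_init__(self) -> None:
        for zt, dd in zip(self.z_tilde, self.d):
            if len(zt) != len(dd):
                raise ValueError("z_tilde and d lengths differ within a block")

    @property
    def n_blocks(self) -> int:
        return len(self.z_tilde)

    @property
    def n_components(self) -> int:
        return sum(len(z) for z in self.z_tilde)


@dataclass
class EstimateResult:
    """Point estimate, composite intercept, jackknife SE and one-sided p-value."""

    h2_I: float
    intercept: float
    se: float
    p_value: float
    n_blocks_jackknife: int
    leave_one_out: np.ndarray
    method: str
    iterations: int
    converged: bool = True
    m_used: int = 0
    n_used: int = 0


def transform_zscores(
    stats: SummaryStats | np.ndarray, panel: Sequence[EigenSystem]
) -> TransformedStats:
    """Whiten the GWIS Z-score vector block by block: z~ = D^{-1/2} U' z.

    ``stats`` must already be aligned to the panel's variant order (see
    :func:`lderge.gwis.align_alleles`); a raw Z vector in panel order is also
    accepted.  Only retained eigen-components are used, so the transformed
    vector has length sum(n_retained).
    """
    z = stats.z if isinstance(stats, SummaryStats) else np.asarray(stats, dtype=float)
    total_m = sum(es.m for es in panel)
    if len(z) != total_m:
        raise ValueError(
            f"summary statistics carry {len(z)} variants but the panel expects {total_m}"
        )
    z_tilde, d, ids = [], [], []
    offset = 0
    for es in panel:
        zb = z[offset : offset + es.m]
        offset += es.m
        z_tilde.append((es.U.T @ zb) / np.sqrt(es.D))
        d.append(es.D.copy())
        ids.append(es.block_id)
    return TransformedStats(z_tilde=z_tilde, d=d, block_ids=ids)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least-squares slope and intercept of y on x."""
    sw = w.sum()
    swx = float(w @ x)
    swy = float(w @ y)
    swxx = float(w @ (x * x))
    swxy = float(w @ (x * y))
    det = sw * swxx - swx * swx
    if det <= 0 or not np.isfinite(det):
        raise ValueError("regression design is degenerate (no eigenvalue spread)")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swy - slope * swx) / sw
    return slope, intercept


def _iwls_fit(
    x: np.ndarray,
    y: np.ndarray,
    prefac: np.ndarray,
    n: int,
    m: int,
    max_iter: int,
    tol: float,
) -> tuple[float, float, int, bool]:
    """Iterative WLS of y on n*x/m with weights prefac / (n*h*x/m + intercept)^2.

    Starts at h = 0, intercept = 1; h is clipped at 0 inside the weights only.
    Returns (h, intercept, iterations, converged).
    """
    design = n * x / m
    if np.ptp(design) < 1e-12 * max(1.0, np.abs(design).max()):
        raise ValueError("all eigenvalues/LD scores identical: slope unidentifiable")
    h, icpt = 0.0, 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = max(h, 0.0) * design + max(icpt, _WEIGHT_INTERCEPT_FLOOR)
        w = prefac / (denom * denom)
        h_new, icpt_new = _wls_line(design, y, w)
        delta = abs(h_new - h)
        h, icpt = h_new, icpt_new
        if delta < tol:
            converged = True
            break
    return h, icpt, it, converged


def _blockwise_fit(
    x_blocks: list[np.ndarray],
    y_blocks: list[np.ndarray],
    prefac_blocks: list[np.ndarray],
    n: int,
    m: int,
    method: str,
    max_iter: int,
    tol: float,
    n_jackknife_groups: int,
    jackknife: bool,
) -> EstimateResult:
    x = np.concatenate(x_blocks)
    y = np.concatenate(y_blocks)
    pf = np.concatenate(prefac_blocks)
    h, icpt, iters, converged = _iwls_fit(x, y, pf, n, m, max_iter, tol)
    if not converged:
        warnings.warn(f"{method}: IWLS did not converge in {max_iter} iterations", stacklevel=3)

    if not jackknife:
        return EstimateResult(
            h2_I=h,
            intercept=icpt,
            se=float("nan"),
            p_value=float("nan"),
            n_blocks_jackknife=0,
            leave_one_out=np.empty(0),
            method=method,
            iterations=iters,
            converged=converged,
            m_used=m,
            n_used=n,
        )

    # Jackknife deletions reuse the weights frozen from the full fit, so each
    # leave-one-out estimate is a single linear WLS solve.  Freezing keeps the
    # jackknife SE calibrated against the empirical estimator SD; recomputing
    # the iterative weights inside each deletion couples the SE to the point
    # estimate and was measured to understate dispersion badly.
    design = n * x / m
    w_frozen = pf / (max(h, 0.0) * design + max(icpt, _WEIGHT_INTERCEPT_FLOOR)) ** 2
    sizes = [len(xb) for xb in x_blocks]
    cuts = np.cumsum([0, *sizes])

    def fit_subset(block_idx: Sequence[int]) -> float:
        keep = np.concatenate([np.arange(cuts[b], cuts[b + 1]) for b in block_idx])
        return _wls_line(design[keep], y[keep], w_frozen[keep])[0]

    se, loo = jackknife_se(fit_subset, len(x_blocks), n_groups=n_jackknife_groups)
    p = wald_test(h, se)
    return EstimateResult(
        h2_I=h,
        intercept=icpt,
        se=se,
        p_value=p,
        n_blocks_jackknife=len(loo),
        leave_one_out=loo,
        method=method,
        iterations=iters,
        converged=converged,
        m_used=m,
        n_used=n,
    )


def lderge_fit(
    t: TransformedStats,
    n: int,
    m: int,
    max_iter: int = 30,
    tol: float = 1e-6,
    n_jackknife_groups: int = 200,
    jackknife: bool = True,
) -> EstimateResult:
    """Full-LD fit: regress z~_j^2 on n*d_j/m with iterative weights.

    The weight of component j is min(d_j, 1) / (n*h*d_j/m + intercept)^2,
    recomputed from the current iterate; min(d_j, 1) damps noise from large
    eigenvalues estimated with finite reference samples.  The estimate is
    unconstrained and may be negative.  With ``jackknife`` the blocks are
    grouped into at most ``n_jackknife_groups`` contiguous groups and the SE
    comes from delete-one-group refits.
    """
    if n <= 0 or m <= 0:
        raise ValueError("n and m must be positive")
    y = [zt * zt for zt in t.z_tilde]
    pf = [np.minimum(dd, 1.0) for dd in t.d]
    return _blockwise_fit(
        t.d, y, pf, n, m, "lder_ge", max_iter, tol, n_jackknife_groups, jackknife
    )


def ldsc_ge_fit(
    stats: SummaryStats | np.ndarray,
    ld_scores: np.ndarray,
    n: int | None = None,
    m: int | None = None,
    max_iter: int = 30,
    tol: float = 1e-6,
    n_jackknife_groups: int = 200,
    jackknife: bool = True,
    block_sizes: Sequence[int] | None = None,
) -> EstimateResult:
    """Diagonal (LD-score) baseline: regress z_j^2 on n*l_j/m with iterative weights.

    The weight of variant j is 1 / (2 * max(l_j, 1) * (n*h*l_j/m + intercept)^2),
    the reciprocal of the large-sample variance of z_j^2 under the moment
    model.  ``block_sizes`` gives the panel's block structure for the
    jackknife; without it, variants are split into contiguous runs.
    """
    if isinstance(stats, SummaryStats):
        z = stats.z
        n = n if n is not None else stats.min_n
        m = m if m is not None else stats.m
    else:
        z = np.asarray(stats, dtype=float)
        if n is None or m is None:
            raise ValueError("n and m are required when passing a raw Z vector")
    l = np.asarray(ld_scores, dtype=float)
    if len(l) != len(z):
        raise ValueError("ld_scores and Z-scores have different lengths")
    if np.any(l < 1.0 - 1e-8):
        raise ValueError("LD scores must be >= 1 (each variant correlates with itself)")

    if block_sizes is None:
        n_chunks = min(n_jackknife_groups, len(z))
        idx = np.array_split(np.arange(len(z)), n_chunks)
        block_sizes = [len(i) for i in idx]
    cuts = np.cumsum([0, *block_sizes])
    if cuts[-1] != len(z):
        raise ValueError("block_sizes do not sum to the number of variants")
    x_blocks = [l[a:b] for a, b in zip(cuts[:-1], cuts[1:])]
    y_blocks = [z[a:b] ** 2 for a, b in zip(cuts[:-1], cuts[1:])]
    pf_blocks = [0.5 / np.maximum(xb, 1.0) for xb in x_blocks]
    return _blockwise_fit(
        x_blocks, y_blocks, pf_blocks, n, m, "ldsc_ge", max_iter, tol, n_jackknife_groups, jackknife
    )


def jackknife_se(
    fit_over_blocks: Callable[[Sequence[int]], float],
    n_blocks: int,
    n_groups: int = 200,
) -> tuple[float, np.ndarray]:
    """Delete-block-group jackknife standard error.

    Blocks are grouped into ``min(n_groups, n_blocks)`` contiguous groups;
    ``fit_over_blocks`` refits on the retained block indices.  With B groups
    and leave-one-out estimates theta_(b),

        se = sqrt( (B-1)/B * sum_b (theta_(b) - mean)^2 ).

    A deletion that leaves an unidentifiable design is merged with its
    neighbor (with a warning).
    """
    if n_blocks < 2:
        raise ValueError("jackknife needs at least 2 blocks")
    n_groups = min(n_groups, n_blocks)
    groups = [g.tolist() for g in np.array_split(np.arange(n_blocks), n_groups)]

    loo: list[float] = []
    b = 0
    while b < len(groups):
        keep = [i for g in groups[:b] + groups[b + 1 :] for i in g]
        try:
            loo.append(fit_over_blocks(keep))
            b += 1
        except ValueError:
            if len(groups) <= 2:
                raise
            nb = b + 1 if b + 1 < len(groups) else b - 1
            warnings.warn(
                f"jackknife group {b} leaves an unidentifiable design; merged with neighbor",
                stacklevel=2,
            )
            lo, hi = min(b, nb), max(b, nb)
            groups[lo] = groups[lo] + groups[hi]
            del groups[hi]
            b = min(b, lo)
    theta = np.asarray(loo)
    B = len(theta)
    se = float(np.sqrt((B - 1) / B * np.sum((theta - theta.mean()) ** 2)))
    return se, theta


def wald_test(h2_I: float, se: float) -> float:
    """One-sided Wald p-value, p = 1 - Phi(h2_I / se).

    One-sided because the parameter is a variance proportion; the positive
    direction is the scientifically meaningful alternative.  A zero SE is
    degenerate: p = 0 for a positive estimate, 1 otherwise.
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    if se == 0:
        warnings.warn("zero standard error: degenerate Wald test", stacklevel=2)
        return 0.0 if h2_I > 0 else 1.0
    return float(norm.sf(h2_I / se))


@dataclass(frozen=True)
class InterceptDecomposition:
    """The composite regression intercept and its model decomposition.

    Under the moment model the intercept equals

        c + (K(E) - 1) * (h2_I + sigma1^2),

    with c the confounding inflation (1 in its absence) and K(E) the exposure
    kurtosis; a standard-normal exposure gives K - 1 = 2.  Because c, h2_I and
    sigma1^2 enter through a single number, sigma1^2 is NOT identifiable from
    the intercept and is deliberately not solved for: confounding (e.g.
    population stratification) inflates c and would masquerade as a
    residual-by-exposure effect.
    """

    intercept: float
    kurtosis_E: float
    interaction_factor: float  # K(E) - 1
    formula: str = "intercept = c + (K(E) - 1) * (h2_I + sigma1^2)"
    sigma1_identifiable: bool = False


def intercept_components(intercept: float, kurtosis_E: float = 3.0) -> InterceptDecomposition:
    """Annotate a fitted intercept with its model decomposition.

    Reports the exposure-kurtosis factor K(E) - 1 multiplying (h2_I + sigma1^2)
    without attempting to solve for sigma1^2 (non-identifiable; see
    :class:`InterceptDecomposition`).
    """
    if not np.isfinite(kurtosis_E):
        raise ValueError("exposure kurtosis must be finite")
    return InterceptDecomposition(
        intercept=float(intercept),
        kurtosis_E=float(kurtosis_E),
        interaction_factor=float(kurtosis_E) - 1.0,
    )


def bernoulli_kurtosis(p: float) -> float:
    """Kurtosis of a standardized Bernoulli(p) exposure: (1 - 6pq)/(pq) + 3."""
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    q = 1.0 - p
    return (1.0 - 6.0 * p * q) / (p * q) + 3.0
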