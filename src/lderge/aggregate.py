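"""Aggregated multi-covariate interaction variance.

Correlated environmental covariates are made mutually independent by
sequential residualization (each covariate regressed on all earlier ones, the
residual re-standardized), after which per-covariate interaction variance
estimates are independent and simply add: the total is the sum of estimates
and its variance the sum of squared standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .estimator import EstimateResult, wald_test

__all__ = [
    "CovariateSet",
    "AggregateResult",
    "sequential_residualize",
    "aggregate_ge_variance",
    "order_sensitivity",
]


@dataclass
class CovariateSet:
    """Covariates and their sequentially residualized, re-standardized versions."""

    names: list[str]
    values: np.ndarray
    residualized: np.ndarray


@dataclass
class AggregateResult:
    """Summed interaction variance across independent residualized covariates."""

    total_h2_I: float
    se: float
    p_value: float
    per_covariate: list[tuple[str, float, float]]


def sequential_residualize(
    covariates: np.ndarray,
    order: Sequence[str] | None = None,
    names: Sequence[str] | None = None,
) -> CovariateSet:
    """Orthogonalize covariate columns in the given order.

    Column k is regressed (with intercept) on columns 0..k-1's residuals and
    the residual is re-standardized to mean 0, variance 1, so each acts as a
    standardized exposure on the scale the interaction model assumes.  A
    column numerically spanned by its predecessors is rejected by name.
    """
    C = np.asarray(covariates, dtype=float)
    if C.ndim != 2:
        raise ValueError("covariates must be a 2-D matrix")
    n, k = C.shape
    if n <= k:
        raise ValueError(f"need more samples ({n}) than covariates ({k})")
    if names is None:
        names = [f"cov{j}" for j in range(k)]
    names = list(names)
    if order is None:
        order = names
    idx = [names.index(nm) for nm in order]

    values = C[:, idx]
    resid = np.empty_like(values)
    for j in range(k):
        col = values[:, j]
        if np.ptp(col) == 0:
            raise ValueError(f"covariate {order[j]!r} is constant")
        r = col - col.mean()
        if j > 0:
            Q = resid[:, :j]  # already orthonormal-ish: standardized, mutually orthogonal
            r = r - Q @ ((Q.T @ r) / n)
        var = r @ r / n
        if var < 1e-10:
            raise ValueError(
                f"covariate {order[j]!r} is numerically spanned by its predecessors"
            )
        resid[:, j] = r / np.sqrt(var)
    return CovariateSet(names=list(order), values=values, residualized=resid)


def aggregate_ge_variance(
    estimates: Sequence[EstimateResult],
    names: Sequence[str] | None = None,
) -> AggregateResult:
    """Sum independent per-covariate estimates; se = sqrt(sum se^2); one-sided p."""
    if len(estimates) == 0:
        raise ValueError("no estimates to aggregate")
    for est in estimates:
        if not est.se > 0:
            raise ValueError("every estimate must carry a positive standard error")
    if names is None:
        names = [f"cov{j}" for j in range(len(estimates))]
    total = float(sum(e.h2_I for e in estimates))
    se = float(np.sqrt(sum(e.se**2 for e in estimates)))
    return AggregateResult(
        total_h2_I=total,
        se=se,
        p_value=wald_test(total, se),
        per_covariate=[(nm, e.h2_I, e.se) for nm, e in zip(names, estimates)],
    )


def order_sensitivity(
    covariates: np.ndarray,
    orders: Sequence[Sequence[str]],
    fit_for_exposure: Callable[[np.ndarray, str], EstimateResult],
    names: Sequence[str] | None = None,
):
    """Aggregate under several residualization orders and compare the totals.

    ``fit_for_exposure(e, name)`` maps one residualized standardized exposure
    column to an :class:`EstimateResult` (it encapsulates GWIS + estimator for
    that exposure).  Returns (per-order results, max pairwise |difference of
    totals| in combined-SE units).
    """
    if len(orders) < 2:
        raise ValueError("need at least 2 orders to compare")
    results: list[AggregateResult] = []
    for order in orders:
        cs = sequential_residualize(covariates, order=order, names=names)
        ests = [fit_for_exposure(cs.residualized[:, j], cs.names[j]) for j in range(len(order))]
        results.append(aggregate_ge_variance(ests, names=cs.names))
    max_delta_se_units = 0.0
    for a in range(len(results)):
        for b in range(a + 1, len(results)):
            ra, rb = results[a], results[b]
            combined = np.sqrt(ra.se**2 + rb.se**2)
            delta = abs(ra.total_h2_I - rb.total_h2_I)
            if combined > 0:
                max_delta_se_units = max(max_delta_se_units, delta / combined)
    return results, max_delta_se_units
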