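"""Observed-to-liability scale transforms for binary traits.

Under the liability-threshold model a binary trait arises when a latent
standard-normal liability exceeds t = Phi^{-1}(1 - K), K the population
prevalence.  Variance proportions estimated on the observed 0/1 scale are
mapped to the liability scale by the Robertson transform, or by Lee's
transform when cases are oversampled (sample prevalence P != K).  Standard
errors scale by the same multiplier.

The transforms assume a normal liability; a large interaction component makes
the liability non-normal, and with rare diseases (prevalence below ~5-10%)
the transformed estimate is then biased upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "LiabilityParams",
    "robertson_transform",
    "robertson_multiplier",
    "lee_transform",
    "lee_multiplier",
]


@dataclass(frozen=True)
class LiabilityParams:
    """Prevalences and the implied liability threshold/density."""

    prevalence_K: float
    prevalence_P: float
    threshold_t: float
    density_z: float

    @classmethod
    def from_prevalence(cls, K: float, P: float | None = None) -> "LiabilityParams":
        _check_prevalence(K, "population prevalence K")
        if P is None:
            P = K
        else:
            _check_prevalence(P, "sample prevalence P")
        t = norm.ppf(1.0 - K)
        return cls(prevalence_K=K, prevalence_P=P, threshold_t=t, density_z=norm.pdf(t))


def _check_prevalence(x: float, name: str) -> None:
    if not 0.0 < x < 1.0:
        raise ValueError(f"{name} must be in (0, 1), got {x}")


def robertson_multiplier(K: float) -> float:
    """K(1-K) / phi(Phi^{-1}(1-K))^2 — observed-to-liability variance multiplier."""
    p = LiabilityParams.from_prevalence(K)
    return K * (1.0 - K) / (p.density_z**2)


def robertson_transform(h2_obs: float, K: float, se: float | None = None):
    """Liability-scale variance proportion: h2_obs * K(1-K) / z^2.

    ``se``, if given, is scaled by the same multiplier and a (value, se) pair
    is returned; otherwise just the transformed value.
    """
    mult = robertson_multiplier(K)
    if se is None:
        return h2_obs * mult
    return h2_obs * mult, se * mult


def lee_multiplier(K: float, P: float) -> float:
    """K^2 (1-K)^2 / (z^2 P (1-P)) — additionally corrects case oversampling."""
    p = LiabilityParams.from_prevalence(K, P)
    return (K**2 * (1.0 - K) ** 2) / (p.density_z**2 * P * (1.0 - P))


def lee_transform(h2_obs: float, K: float, P: float, se: float | None = None):
    """Liability-scale transform for case-control ascertainment.

    Reduces to the Robertson transform when the sample prevalence equals the
    population prevalence.
    """
    mult = lee_multiplier(K, P)
    if se is None:
        return h2_obs * mult
    return h2_obs * mult, se * mult
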