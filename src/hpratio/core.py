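"""Equilibrium algebra of the producer-herbivore biomass ratio.

A two-level community with producer biomass ``P`` and herbivore biomass ``H``
following Lotka-Volterra dynamics

    dP/dt = g(P) P - x P - f(P) P H
    dH/dt = k f(P) P H - m H

has, at its coexistence equilibrium, a biomass ratio that is independent of
the herbivore functional response f(P):

    H*/P* = k (g - x) / m

On a log scale this factors additively into conversion efficiency ``k``,
grazeable fraction ``beta = 1 - x/g``, specific production ``g`` and
herbivore mortality ``m``:

    log(H*/P*) = log k + log beta + log g - log m

Each mechanistic rate is in turn modelled as a power law of a measurable
ecological factor (producer C:P stoichiometry, edible fraction, specific
production rate, relative carnivore abundance), which composes into the
log-linear predictor implemented by :func:`predict_log_ratio`.

All logarithms default to base *e*; every function accepts ``log_base`` and
results carry the base used, because the intercept (but not the slopes) of
the log-linear model depends on it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DEFAULT_LOG_BASE",
    "CommunityParams",
    "FactorMapping",
    "FactorVector",
    "equilibrium_ratio",
    "grazeable_fraction",
    "log_ratio_decomposition",
    "predict_log_ratio",
]

#: Natural log by default.  The slopes (epsilons) of the log-linear model are
#: invariant to this choice; only the intercept gamma rescales as
#: gamma_b = gamma_e / ln(b).
DEFAULT_LOG_BASE: float = math.e


def _log(x: float, base: float) -> float:
    if base <= 0 or base == 1.0:
        raise ValueError(f"log base must be positive and != 1, got {base}")
    return math.log(x) / math.log(base)


@dataclass(frozen=True)
class CommunityParams:
    """Mechanistic rates of one producer-herbivore system.

    Parameters
    ----------
    g : float
        Biomass-specific primary production rate (gC gC^-1 d^-1).
    x : float
        Producer loss rate other than grazing (gC gC^-1 d^-1).
    k : float
        Herbivore conversion efficiency, fraction of ingested carbon
        converted to herbivore biomass (dimensionless, in (0, 1]).
    m : float
        Herbivore per-capita mortality rate (gC gC^-1 d^-1).
    f : float
        Per-capita grazing coefficient (m^2 gC^-1 d^-1).  Used only by the
        dynamical simulator; the equilibrium ratio does not depend on it.
    """

    g: float
    x: float
    k: float
    m: float
    f: float = 1.0

    def __post_init__(self) -> None:
        if not self.g > 0:
            raise ValueError(f"g must be > 0, got {self.g}")
        if self.x < 0:
            raise ValueError(f"x must be >= 0, got {self.x}")
        if not 0 < self.k <= 1:
            raise ValueError(f"k must be in (0, 1], got {self.k}")
        if not self.m > 0:
            raise ValueError(f"m must be > 0, got {self.m}")
        if not self.f > 0:
            raise ValueError(f"f must be > 0, got {self.f}")


def _require_coexistence(params: CommunityParams) -> None:
    if params.g <= params.x:
        raise ValueError(
            f"no positive herbivore equilibrium: g={params.g} <= x={params.x}"
        )


def equilibrium_ratio(params: CommunityParams) -> float:
    """Equilibrium herbivore-to-producer biomass ratio H*/P* = k(g - x)/m.

    The per-capita grazing coefficient ``f`` cancels, so the returned ratio
    is independent of the functional-response parameterization.
    """
    _require_coexistence(params)
    return params.k * (params.g - params.x) / params.m


def grazeable_fraction(g: float, x: float) -> float:
    """Fraction beta = 1 - x/g of primary production consumed by herbivores.

    beta is a gauge of inefficiency in producer defence: beta = 1 means every
    unit of production is grazed at equilibrium; small beta means most
    production is lost through the non-grazing channel ``x``.
    """
    if g <= 0:
        raise ValueError(f"g must be > 0, got {g}")
    if x < 0:
        raise ValueError(f"x must be >= 0, got {x}")
    if g <= x:
        raise ValueError(f"beta undefined for g <= x (g={g}, x={x})")
    return 1.0 - x / g


def log_ratio_decomposition(
    params: CommunityParams, log_base: float = DEFAULT_LOG_BASE
) -> tuple[float, float, float, float]:
    """Additive decomposition (log k, log beta, log g, -log m).

    The four addends sum exactly to ``log(equilibrium_ratio(params))`` in the
    same base, since k(g - x)/m = k * beta * g / m.
    """
    _require_coexistence(params)
    beta = grazeable_fraction(params.g, params.x)
    return (
        _log(params.k, log_base),
        _log(beta, log_base),
        _log(params.g, log_base),
        -_log(params.m, log_base),
    )


@dataclass
class FactorMapping:
    """Power-law links between measurable factors and mechanistic rates.

    The four mechanistic rates are modelled as
    ``k = q1 * a_nut**eps1``, ``beta = q2 * a_edi**eps2``,
    ``g = q3 * mu**eps3`` and ``m = q4 * theta**eps4``.  Only the composite
    intercept ``gamma = log q1 + log q2 + log q3 - log q4`` is identifiable
    from biomass-ratio data, so the q's may be left unset with ``gamma``
    given directly.

    ``eps4`` follows the reporting convention in which a positive value means
    carnivores *depress* the biomass ratio (the raw regression coefficient on
    log theta is ``-eps4``).
    """

    eps1: float
    eps2: float
    eps3: float
    eps4: float
    gamma: Optional[float] = None
    q1: Optional[float] = None
    q2: Optional[float] = None
    q3: Optional[float] = None
    q4: Optional[float] = None
    log_base: float = field(default=DEFAULT_LOG_BASE)

    def __post_init__(self) -> None:
        qs = (self.q1, self.q2, self.q3, self.q4)
        have_qs = all(q is not None for q in qs)
        if any(q is not None and q <= 0 for q in qs):
            raise ValueError("conversion factors q1..q4 must be positive")
        if have_qs:
            implied = (
                _log(self.q1, self.log_base)
                + _log(self.q2, self.log_base)
                + _log(self.q3, self.log_base)
                - _log(self.q4, self.log_base)
            )
            if self.gamma is None:
                self.gamma = implied
            elif not math.isclose(self.gamma, implied, rel_tol=1e-9, abs_tol=1e-9):
                raise ValueError(
                    f"gamma={self.gamma} inconsistent with q's (implied {implied})"
                )
        elif self.gamma is None:
            raise ValueError("either gamma or all of q1..q4 must be given")


@dataclass(frozen=True)
class FactorVector:
    """One community's measurable factor values.

    a_nut : producer carbon:nutrient ratio (molar C:P here; dimensionless)
    a_edi : edible fraction of producer biomass, in (0, 1]
    mu    : specific production rate (gC g chl-a^-1 d^-1)
    theta : relative carnivore abundance, CPUE + 1 (>= 1)
    """

    a_nut: float
    a_edi: float
    mu: float
    theta: float

    def __post_init__(self) -> None:
        for name in ("a_nut", "a_edi", "mu", "theta"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        if self.a_edi > 1:
            raise ValueError(f"a_edi must be <= 1, got {self.a_edi}")
        if self.theta < 1:
            raise ValueError(f"theta = CPUE + 1 must be >= 1, got {self.theta}")


def predict_log_ratio(
    mapping: FactorMapping,
    factors: FactorVector,
    log_base: Optional[float] = None,
) -> float:
    """Log biomass ratio predicted by the composed power-law model.

    log(H*/P*) = eps1 log(a_nut) + eps2 log(a_edi) + eps3 log(mu)
                 - eps4 log(theta) + gamma

    Note the explicit minus sign on the carnivore term: ``eps4`` is reported
    positive for a negative effect on the ratio.  ``log_base`` defaults to
    the mapping's own base (in which its gamma is expressed).
    """
    base = mapping.log_base if log_base is None else log_base
    if mapping.gamma is None:  # pragma: no cover - guarded in __post_init__
        raise ValueError("mapping has no gamma")
    return (
        mapping.eps1 * _log(factors.a_nut, base)
        + mapping.eps2 * _log(factors.a_edi, base)
        + mapping.eps3 * _log(factors.mu, base)
        - mapping.eps4 * _log(factors.theta, base)
        + mapping.gamma
    )
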