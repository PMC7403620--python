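"""General discrete distributions (GDD) for dN/dS (omega) and synonymous rates.

Two 3-bin GDDs drive the branch-site mixture model:

* the omega distribution, with rates constrained 0 <= w1 <= w2 <= 1 <= w3 so
  the last bin is the (potentially) positively selected class, and
* the alpha distribution of site-specific synonymous rate multipliers,
  constrained to unit mean for identifiability: given raw shapes
  0 <= a1 <= 1 <= a3 and weights (f1, f2, f3), the realized rates are
  (c*a1, c, c*a3) with c = 1/(f1*a1 + f2 + f3*a3).

Both support a user-adjustable category count K; K = 3 is the default used
throughout.  Unconstrained real-vector transforms are provided so that
optimizers can work without explicit constraints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

_EPS = 1e-12


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    p = np.clip(p, _EPS, 1 - _EPS)
    return np.log(p) - np.log1p(-p)


def weights_to_logits(weights: np.ndarray) -> np.ndarray:
    """Stick-breaking logits for a point on the simplex (K-1 values)."""
    w = np.asarray(weights, dtype=float)
    logits = []
    remaining = 1.0
    for k in range(len(w) - 1):
        frac = w[k] / remaining if remaining > _EPS else 0.0
        logits.append(_logit(frac))
        remaining -= w[k]
    return np.array(logits)


def logits_to_weights(logits: np.ndarray) -> np.ndarray:
    z = np.atleast_1d(np.asarray(logits, dtype=float))
    w = np.empty(len(z) + 1)
    remaining = 1.0
    for k, zk in enumerate(z):
        w[k] = remaining * _sigmoid(zk)
        remaining -= w[k]
    w[-1] = max(remaining, 0.0)
    return w


@dataclass(frozen=True)
class DiscreteDistribution:
    """A finite discrete distribution of non-negative rates."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        rates = np.atleast_1d(np.asarray(self.rates, dtype=float))
        weights = np.atleast_1d(np.asarray(self.weights, dtype=float))
        object.__setattr__(self, "rates", rates)
        object.__setattr__(self, "weights", weights)
        if rates.shape != weights.shape:
            raise ValueError("rates and weights must have equal length")
        if np.any(rates < 0) or not np.all(np.isfinite(rates)):
            raise ValueError("rates must be finite and non-negative")
        if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must lie on the simplex")

    @property
    def K(self) -> int:
        return len(self.rates)

    def mean(self) -> float:
        return float(self.weights @ self.rates)

    def variance(self) -> float:
        m = self.mean()
        return float(self.weights @ (self.rates - m) ** 2)

    def to_pairs(self):
        return [[float(r), float(w)] for r, w in zip(self.rates, self.weights)]


class OmegaDistribution(DiscreteDistribution):
    """GDD for the branch-site dN/dS ratio.

    The last category is anchored at >= 1, all earlier categories at <= 1,
    with rates non-decreasing, so that testing "no positive selection" is
    the boundary constraint rate[-1] = 1.
    """

    def __post_init__(self):
        super().__post_init__()
        r = self.rates
        if np.any(np.diff(r) < -1e-9):
            raise ValueError("omega rates must be non-decreasing")
        if self.K >= 2:
            if r[-2] > 1 + 1e-9:
                raise ValueError("all omega categories except the last must be <= 1")
            if r[-1] < 1 - 1e-9:
                raise ValueError("the last omega category must be >= 1")

    @property
    def omega3(self) -> float:
        return float(self.rates[-1])

    @property
    def p3(self) -> float:
        return float(self.weights[-1])


class AlphaDistribution(DiscreteDistribution):
    """Unit-mean GDD for site-specific synonymous rate multipliers."""

    def __post_init__(self):
        super().__post_init__()
        if np.any(np.diff(self.rates) < -1e-9):
            raise ValueError("alpha rates must be non-decreasing")
        if abs(self.mean() - 1.0) > 1e-9:
            raise ValueError("alpha distribution must have mean 1")

    @classmethod
    def from_raw(cls, raw_rates, weights) -> "AlphaDistribution":
        """Normalize arbitrary non-negative raw rates to unit mean."""
        raw = np.asarray(raw_rates, dtype=float)
        w = np.asarray(weights, dtype=float)
        m = float(w @ raw)
        if m <= 0:
            raise ValueError("raw alpha rates have zero mean")
        return cls(rates=raw / m, weights=w)

    def is_point_mass(self, tol: float = 1e-9) -> bool:
        return bool(np.all(np.abs(self.rates - 1.0) <= tol))


def point_mass_alpha() -> AlphaDistribution:
    """The degenerate alpha distribution of the no-SRV (BUSTED) model."""
    return AlphaDistribution(rates=np.array([1.0]), weights=np.array([1.0]))


def make_alpha_distribution(a1: float, a3: float, f1: float, f2: float
                            ) -> AlphaDistribution:
    """Build the 3-bin unit-mean alpha GDD from its four hyperparameters.

    Shapes satisfy 0 <= a1 <= 1 <= a3; realized rates are (c*a1, c, c*a3)
    with c chosen so the mean is exactly 1.
    """
    if not (0 <= a1 <= 1 + 1e-12):
        raise ValueError("a1 must lie in [0, 1]")
    if a3 < 1 - 1e-12:
        raise ValueError("a3 must be >= 1")
    f3 = 1.0 - f1 - f2
    if min(f1, f2, f3) < -1e-12:
        raise ValueError("alpha weights must lie on the simplex")
    c = 1.0 / (f1 * a1 + f2 + f3 * a3)
    return AlphaDistribution(rates=np.array([c * a1, c, c * a3]),
                             weights=np.array([f1, f2, f3]))


def coefficient_of_variation(dist: DiscreteDistribution) -> float:
    """CV = sd / mean of a discrete rate distribution."""
    m = dist.mean()
    if m <= 0:
        raise ValueError("CV undefined for a zero-mean distribution")
    return float(np.sqrt(dist.variance()) / m)


# ---------------------------------------------------------------------------
# Unconstrained transforms (optimizer parameterization)
# ---------------------------------------------------------------------------

OMEGA_CAP = 1e4  # upper bound on the selected-class omega during optimization


def omega_to_vector(dist: OmegaDistribution) -> np.ndarray:
    """Map an omega GDD to an unconstrained vector (2K-1 values for K bins).

    Rates below the anchor at 1 use chained sigmoids (structural ordering);
    the top rate uses log(rate - 1), clamped just above the boundary.
    """
    r = np.clip(dist.rates, _EPS, OMEGA_CAP)
    K = dist.K
    xs = []
    upper = 1.0
    for k in range(K - 2, -1, -1):  # rates K-2 ... 0, each <= next
        frac = min(r[k] / upper, 1 - _EPS) if upper > _EPS else _EPS
        xs.append(_logit(frac))
        upper = r[k]
    xs = xs[::-1]
    top = max(r[K - 1] - 1.0, 1e-9)
    xs.append(np.log(top))
    return np.concatenate([xs, weights_to_logits(dist.weights)])


def omega_from_vector(x: np.ndarray, K: int = 3) -> OmegaDistribution:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite omega parameter vector")
    rates = np.empty(K)
    upper = 1.0
    for k in range(K - 2, -1, -1):
        upper = upper * _sigmoid(x[k])
        rates[k] = upper
    rates[K - 1] = 1.0 + min(np.exp(x[K - 1]), OMEGA_CAP)
    weights = logits_to_weights(x[K:])
    return OmegaDistribution(rates=rates, weights=weights)


def constrained_omega_from_vector(x: np.ndarray, K: int = 3) -> OmegaDistribution:
    """Omega GDD with the selected class pinned at 1 (null model).

    The vector has one fewer rate parameter than the unconstrained form.
    """
    x = np.asarray(x, dtype=float)
    rates = np.empty(K)
    upper = 1.0
    for k in range(K - 2, -1, -1):
        upper = upper * _sigmoid(x[k])
        rates[k] = upper
    rates[K - 1] = 1.0
    weights = logits_to_weights(x[K - 1:])
    return OmegaDistribution(rates=rates, weights=weights)


def constrained_omega_to_vector(dist: OmegaDistribution) -> np.ndarray:
    r = np.clip(dist.rates, _EPS, 1.0)
    K = dist.K
    xs = []
    upper = 1.0
    for k in range(K - 2, -1, -1):
        frac = min(r[k] / upper, 1 - _EPS) if upper > _EPS else _EPS
        xs.append(_logit(frac))
        upper = r[k]
    xs = xs[::-1]
    return np.concatenate([xs, weights_to_logits(dist.weights)])


def alpha_to_vector(dist: AlphaDistribution) -> np.ndarray:
    """Map a 3-bin alpha GDD to an unconstrained 4-vector (a1, a3, f logits)."""
    if dist.K != 3:
        raise ValueError("vector transform implemented for the 3-bin alpha GDD")
    c = dist.rates[1]
    a1 = np.clip(dist.rates[0] / c, _EPS, 1 - _EPS)
    a3 = max(dist.rates[2] / c, 1.0 + 1e-9)
    return np.concatenate([[_logit(a1), np.log(a3 - 1.0)],
                           weights_to_logits(dist.weights)])


def alpha_from_vector(y: np.ndarray) -> AlphaDistribution:
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite alpha parameter vector")
    a1 = _sigmoid(y[0])
    a3 = 1.0 + min(np.exp(y[1]), 1e6)
    f = logits_to_weights(y[2:4])
    return make_alpha_distribution(a1, a3, f[0], f[1])


def check_degenerate(dist: DiscreteDistribution, rel_tol: float = 1e-3,
                     weight_tol: float = 1e-4) -> list[str]:
    """Warn about overfitting symptoms: near-equal rates or vanishing weights."""
    issues = []
    r, w = dist.rates, dist.weights
    for k in range(dist.K - 1):
        denom = max(abs(r[k + 1]), 1e-12)
        if abs(r[k + 1] - r[k]) / denom < rel_tol:
            issues.append(f"rate categories {k + 1} and {k + 2} nearly equal "
                          f"({r[k]:.4g} vs {r[k + 1]:.4g})")
    for k in range(dist.K):
        if w[k] < weight_tol:
            issues.append(f"weight of category {k + 1} is negligible ({w[k]:.2e})")
    for msg in issues:
        warnings.warn("possible overfitting: " + msg, stacklevel=2)
    return issues
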