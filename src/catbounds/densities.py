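"""Attribute distributions on a bounded interval.

The model places a population on a continuous attribute space [a, b]
(political ideology, skin tone, ...) with density rho(x).  Every quantity
downstream — group prototypes, categorization errors, boundary dynamics —
is built from partial masses ``int_lo^hi rho`` and truncated first/second
moments of rho.  Each density family therefore exposes exact partial
moments up to order two, which makes the error functionals closed-form
rather than nested quadratures.

Supported families:

``uniform``
    Constant density on [a, b].
``beta``
    Beta(alpha, beta) on [0, 1], affinely rescaled to [a, b].
``bimodal_beta``
    Equal mixture of Beta(alpha, beta) and Beta(beta, alpha); symmetric
    about the midpoint of the attribute space.
``empirical``
    Piecewise-constant histogram estimated from samples (or, with the
    ``beta_moments`` method, a Beta fit by the method of moments).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
from scipy import special
from scipy.stats import beta as beta_dist

from ._exceptions import DataError, DegenerateGroupError, DomainError, ParameterError

__all__ = [
    "AttributeDensity",
    "UniformDensity",
    "BetaDensity",
    "BimodalBetaDensity",
    "HistogramDensity",
    "make_density",
    "mass",
    "center_of_mass",
    "fit_from_samples",
]

#: total mass over [a, b] must equal 1 within this tolerance
_NORMALIZATION_TOL = 1e-8


class AttributeDensity:
    """A probability density rho(x) on a bounded attribute space [a, b].

    Subclasses implement :meth:`pdf` and the exact partial moment
    ``int_lo^hi x^k rho(x) dx`` for k in {0, 1, 2}.  All downstream error
    functionals are expressed through those moments.
    """

    family: str
    a: float
    b: float

    def __init__(self, a: float, b: float) -> None:
        a, b = float(a), float(b)
        if not (a < b):
            raise DomainError(f"attribute space requires a < b, got a={a}, b={b}")
        self.a = a
        self.b = b

    # -- subclass surface --------------------------------------------------
    def pdf(self, x):
        """Evaluate rho at x (scalar or array); 0 outside [a, b]."""
        raise NotImplementedError

    def partial_moment(self, k: int, lo: float, hi: float) -> float:
        """Exact ``int_lo^hi x^k rho(x) dx`` for k in {0, 1, 2}."""
        raise NotImplementedError

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n i.i.d. samples."""
        raise NotImplementedError

    # -- shared API --------------------------------------------------------
    def _check_interval(self, lo: float, hi: float) -> tuple[float, float]:
        if lo > hi:
            raise DomainError(f"interval requires lo <= hi, got ({lo}, {hi})")
        if lo < self.a - 1e-12 or hi > self.b + 1e-12:
            raise DomainError(
                f"interval ({lo}, {hi}) outside attribute space [{self.a}, {self.b}]"
            )
        return max(lo, self.a), min(hi, self.b)

    def mass(self, lo: float, hi: float) -> float:
        """Population fraction in [lo, hi]."""
        lo, hi = self._check_interval(lo, hi)
        return float(self.partial_moment(0, lo, hi))

    def center_of_mass(self, lo: float, hi: float) -> float:
        """Mean attribute position of the population restricted to [lo, hi].

        This is the group prototype: all members of a category are
        cognitively collapsed onto this single position.
        """
        lo, hi = self._check_interval(lo, hi)
        m0 = self.partial_moment(0, lo, hi)
        if m0 <= 0.0:
            raise DegenerateGroupError(
                f"interval ({lo}, {hi}) carries zero population mass"
            )
        com = self.partial_moment(1, lo, hi) / m0
        # guard tiny quadrature round-off at segment edges
        return float(min(max(com, lo), hi))

    # map [a,b] <-> the unit interval used by the Beta families
    def _to_unit(self, x):
        return (np.asarray(x, dtype=float) - self.a) / (self.b - self.a)

    def _from_unit(self, y):
        return self.a + (self.b - self.a) * np.asarray(y, dtype=float)


class UniformDensity(AttributeDensity):
    """Constant density 1/(b-a) on [a, b]."""

    family = "uniform"

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.a) & (x <= self.b)
        return np.where(inside, 1.0 / (self.b - self.a), 0.0)

    def partial_moment(self, k: int, lo: float, hi: float) -> float:
        c = 1.0 / (self.b - self.a)
        return c * (hi ** (k + 1) - lo ** (k + 1)) / (k + 1)

    def rvs(self, n, rng):
        return rng.uniform(self.a, self.b, size=n)


def _beta_unit_partial_moment(k: int, alpha: float, beta: float, lo: float, hi: float) -> float:
    """int_lo^hi y^k f_beta(y; alpha, beta) dy on the unit interval.

    Uses y^k f(y; alpha, beta) = c_k f(y; alpha+k, beta) with
    c_k = B(alpha+k, beta)/B(alpha, beta), so the integral is a difference
    of regularized incomplete beta functions.
    """
    if k == 0:
        c = 1.0
    else:
        c = math.exp(
            special.betaln(alpha + k, beta) - special.betaln(alpha, beta)
        )
    return c * (special.betainc(alpha + k, beta, hi) - special.betainc(alpha + k, beta, lo))


class BetaDensity(AttributeDensity):
    """Beta(alpha, beta) rescaled from [0, 1] to [a, b].

    f_beta(y; alpha, beta) = y^(alpha-1) (1-y)^(beta-1) / B(alpha, beta).
    The supported regime is alpha, beta >= 1 (bounded pdf); smaller shape
    parameters are accepted but the endpoint singularities are integrable
    and handled analytically through the incomplete beta function.
    """

    family = "beta"

    def __init__(self, a: float, b: float, alpha: float, beta: float) -> None:
        super().__init__(a, b)
        if alpha <= 0 or beta <= 0:
            raise ParameterError(
                f"Beta shape parameters must be positive, got alpha={alpha}, beta={beta}"
            )
        self.alpha = float(alpha)
        self.beta = float(beta)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        y = self._to_unit(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            val = beta_dist.pdf(y, self.alpha, self.beta) / (self.b - self.a)
        return np.where((x >= self.a) & (x <= self.b), val, 0.0)

    def partial_moment(self, k: int, lo: float, hi: float) -> float:
        lo_u, hi_u = float(self._to_unit(lo)), float(self._to_unit(hi))
        lo_u, hi_u = min(max(lo_u, 0.0), 1.0), min(max(hi_u, 0.0), 1.0)
        # x = a + s*y; expand x^k in unit-interval moments
        s = self.b - self.a
        mu = [
            _beta_unit_partial_moment(j, self.alpha, self.beta, lo_u, hi_u)
            for j in range(k + 1)
        ]
        total = 0.0
        for j in range(k + 1):
            total += math.comb(k, j) * self.a ** (k - j) * s**j * mu[j]
        return total

    def rvs(self, n, rng):
        return self._from_unit(rng.beta(self.alpha, self.beta, size=n))


class BimodalBetaDensity(AttributeDensity):
    """Equal mixture of Beta(alpha, beta) and Beta(beta, alpha) on [a, b].

    The two components are mirror images, so the mixture is symmetric about
    (a+b)/2; with e.g. alpha=2, beta=7 it is bimodal with well-separated
    modes, emulating a polarized population.
    """

    family = "bimodal_beta"

    def __init__(self, a: float, b: float, alpha: float, beta: float) -> None:
        super().__init__(a, b)
        if alpha <= 0 or beta <= 0:
            raise ParameterError(
                f"Beta shape parameters must be positive, got alpha={alpha}, beta={beta}"
            )
        self.alpha = float(alpha)
        self.beta = float(beta)
        self._c1 = BetaDensity(a, b, alpha, beta)
        self._c2 = BetaDensity(a, b, beta, alpha)

    def pdf(self, x):
        return 0.5 * (self._c1.pdf(x) + self._c2.pdf(x))

    def partial_moment(self, k, lo, hi):
        return 0.5 * (
            self._c1.partial_moment(k, lo, hi) + self._c2.partial_moment(k, lo, hi)
        )

    def rvs(self, n, rng):
        pick = rng.random(n) < 0.5
        out = np.where(
            pick,
            rng.beta(self.alpha, self.beta, size=n),
            rng.beta(self.beta, self.alpha, size=n),
        )
        return self._from_unit(out)


class HistogramDensity(AttributeDensity):
    """Piecewise-constant density from equal-width histogram bins."""

    family = "empirical"

    def __init__(self, a: float, b: float, edges: Sequence[float], heights: Sequence[float]) -> None:
        super().__init__(a, b)
        edges = np.asarray(edges, dtype=float)
        heights = np.asarray(heights, dtype=float)
        if edges.ndim != 1 or heights.ndim != 1 or len(edges) != len(heights) + 1:
            raise ParameterError("need len(edges) == len(heights) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ParameterError("bin edges must be strictly increasing")
        if np.any(heights < 0):
            raise ParameterError("bin heights must be non-negative")
        total = float(np.sum(heights * np.diff(edges)))
        if abs(total - 1.0) > _NORMALIZATION_TOL:
            heights = heights / total
        self.edges = edges
        self.heights = heights

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        idx = np.clip(np.searchsorted(self.edges, x, side="right") - 1, 0, len(self.heights) - 1)
        inside = (x >= self.a) & (x <= self.b)
        return np.where(inside, self.heights[idx], 0.0)

    def partial_moment(self, k: int, lo: float, hi: float) -> float:
        # clip each bin to [lo, hi] and integrate x^k exactly
        left = np.clip(self.edges[:-1], lo, hi)
        right = np.clip(self.edges[1:], lo, hi)
        seg = (right ** (k + 1) - left ** (k + 1)) / (k + 1)
        return float(np.sum(self.heights * seg))

    def rvs(self, n, rng):
        widths = np.diff(self.edges)
        probs = self.heights * widths
        probs = probs / probs.sum()
        bins = rng.choice(len(self.heights), size=n, p=probs)
        return self.edges[bins] + widths[bins] * rng.random(n)


_FAMILIES = {"uniform", "beta", "bimodal_beta", "empirical"}


def make_density(family: str, a: float, b: float, **params) -> AttributeDensity:
    """Construct an :class:`AttributeDensity`.

    Parameters
    ----------
    family
        One of ``uniform``, ``beta``, ``bimodal_beta``, ``empirical``.
    a, b
        Bounds of the attribute space, a < b.
    **params
        ``alpha``/``beta`` for the Beta families; ``edges``/``heights``
        for ``empirical``.
    """
    if family not in _FAMILIES:
        raise ParameterError(f"unknown density family {family!r}; choose from {sorted(_FAMILIES)}")
    if family == "uniform":
        return UniformDensity(a, b)
    if family == "beta":
        return BetaDensity(a, b, params["alpha"], params["beta"])
    if family == "bimodal_beta":
        return BimodalBetaDensity(a, b, params["alpha"], params["beta"])
    return HistogramDensity(a, b, params["edges"], params["heights"])


def mass(density: AttributeDensity, lo: float, hi: float) -> float:
    """Population fraction ``int_lo^hi rho(x) dx``."""
    return density.mass(lo, hi)


def center_of_mass(density: AttributeDensity, lo: float, hi: float) -> float:
    """Truncated mean ``int_lo^hi x rho dx / int_lo^hi rho dx``."""
    return density.center_of_mass(lo, hi)


#: default number of equal-width histogram bins for empirical densities
DEFAULT_BINS = 64

#: minimum sample size accepted by :func:`fit_from_samples`
MIN_SAMPLES = 30


def fit_from_samples(
    samples: Sequence[float],
    a: float = 0.0,
    b: float = 1.0,
    method: str = "histogram",
    bins: int = DEFAULT_BINS,
) -> AttributeDensity:
    """Estimate an attribute density from observed attribute values.

    ``histogram`` returns a piecewise-constant density on ``bins``
    equal-width bins; ``beta_moments`` fits Beta(alpha, beta) by matching
    the sample mean and variance of the values rescaled to [0, 1]:

        alpha = m (m(1-m)/v - 1),  beta = (1-m) (m(1-m)/v - 1).
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1:
        raise DataError("samples must be one-dimensional")
    if len(x) < MIN_SAMPLES:
        raise DataError(f"need at least {MIN_SAMPLES} samples, got {len(x)}")
    if np.any(x < a) or np.any(x > b):
        raise DataError(f"samples outside attribute space [{a}, {b}]")
    if method == "histogram":
        counts, edges = np.histogram(x, bins=bins, range=(a, b))
        heights = counts / (len(x) * np.diff(edges))
        return HistogramDensity(a, b, edges, heights)
    if method == "beta_moments":
        y = (x - a) / (b - a)
        m = float(np.mean(y))
        v = float(np.var(y, ddof=1))
        if v <= 0 or v >= m * (1 - m):
            raise DataError("sample moments incompatible with a Beta distribution")
        common = m * (1 - m) / v - 1.0
        return BetaDensity(a, b, m * common, (1 - m) * common)
    raise ParameterError(f"unknown fitting method {method!r}")
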