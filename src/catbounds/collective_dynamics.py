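"""Collective error, boundary gradient flow, and fixed points.

A group's collective categorization error is the in-group-mass-weighted
average of the individual errors of its members,

    Err(z) = (1 / int_in rho) int_in err(u, z) rho(u) du,

and the group adjusts its category boundary by gradient descent,

    dz/dt = -k dErr/dz,

with k a rate constant that only rescales time.  The boundary settles at
a stable fixed point — an interior minimum of Err.  For a uniform
population on [0, 1] this is available in closed form,
Err(z) = z^2/3 - z/4 + 1/12, with stable fixed point z* = 3/8 for the
left group (5/8 for the right by symmetry).

Because err(u, z) is quadratic in u with moment-valued coefficients,
Err(z) reduces to partial moments of rho up to order two and is evaluated
exactly; the gradient is a central finite difference on that evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from ._exceptions import DegenerateGroupError, DomainError, SolverError
from .category_error import GroupSide, _split, individual_error_coefficients
from .densities import AttributeDensity

__all__ = [
    "DynamicsConfig",
    "BoundaryState",
    "Trajectory",
    "FixedPointResult",
    "collective_error",
    "collective_error_gradient",
    "uniform_collective_error",
    "integrate_boundary",
    "find_fixed_points",
]

#: relative edge margin: z is kept in (a + eps, b - eps), eps = EDGE_MARGIN_REL*(b-a)
EDGE_MARGIN_REL = 1e-4
#: relative step of the central difference used for dErr/dz
GRADIENT_STEP_REL = 1e-5
#: relative step of the second difference used for stability classification
CURVATURE_STEP_REL = 1e-4
#: |d2Err/dz2| below this is reported as "marginal" rather than classified
MARGINAL_CURVATURE = 1e-6
#: gradient magnitude accepted as a root
ROOT_TOL = 1e-9


@dataclass(frozen=True)
class DynamicsConfig:
    """Settings for the boundary gradient flow dz/dt = -k dErr/dz.

    k only rescales time; the fixed points do not depend on it.  z0
    defaults to the midpoint of the attribute space.  edge_margin keeps
    the boundary away from the edges, where a group's mass (the
    denominator of Err) vanishes.
    """

    k: float = 1.0
    z0: Optional[float] = None
    t_max: Optional[float] = None
    convergence_tol: float = 1e-8
    edge_margin: Optional[float] = None

    def __post_init__(self):
        if self.k <= 0:
            raise DomainError(f"rate constant k must be positive, got {self.k}")
        if self.convergence_tol <= 0:
            raise DomainError("convergence_tol must be positive")

    def resolve(self, density: AttributeDensity) -> tuple[float, float, float]:
        """(z0, t_max, eps) with defaults filled in for this density."""
        width = density.b - density.a
        eps = self.edge_margin if self.edge_margin is not None else EDGE_MARGIN_REL * width
        z0 = self.z0 if self.z0 is not None else 0.5 * (density.a + density.b)
        t_max = self.t_max if self.t_max is not None else 100.0 / self.k
        if not (density.a + eps <= z0 <= density.b - eps):
            raise DomainError(f"z0={z0} outside admissible range for edge margin {eps}")
        return z0, t_max, eps


@dataclass(frozen=True)
class BoundaryState:
    """A boundary position with its error and gradient at one instant."""

    z: float
    side: GroupSide
    Err: float
    dErr_dz: float
    t: float = 0.0


@dataclass
class Trajectory:
    """Time course of an integrated boundary."""

    times: np.ndarray
    positions: np.ndarray
    errors: np.ndarray
    converged: bool
    side: GroupSide


@dataclass(frozen=True)
class FixedPointResult:
    """An interior zero of the error gradient with its stability label."""

    z_star: float
    stability: str  # "stable" | "unstable" | "marginal"
    Err_at_star: float


def collective_error(density: AttributeDensity, z: float, side: GroupSide) -> float:
    """Average collective in-group error Err(z).

    With err(u, z) = u^2 + B u + C (see
    :func:`catbounds.category_error.individual_error_coefficients`),

        Err(z) = (m2_in + B m1_in) / m0_in + C,

    where m_k are in-group partial moments of rho.
    """
    side = GroupSide(side)
    A, B, C = individual_error_coefficients(density, z, side)
    in_lo, in_hi, _, _ = _split(density, z, side)
    m0 = density.partial_moment(0, in_lo, in_hi)
    m1 = density.partial_moment(1, in_lo, in_hi)
    m2 = density.partial_moment(2, in_lo, in_hi)
    err = (A * m2 + B * m1) / m0 + C
    return max(err, 0.0)


def uniform_collective_error(z: float) -> float:
    """Closed-form Err(z) = z^2/3 - z/4 + 1/12 for uniform [0, 1], left group."""
    return z * z / 3.0 - z / 4.0 + 1.0 / 12.0


def collective_error_gradient(
    density: AttributeDensity, z: float, side: GroupSide
) -> float:
    """dErr/dz by central finite difference (step 1e-5 of the space width)."""
    h = GRADIENT_STEP_REL * (density.b - density.a)
    if not (density.a < z - h and z + h < density.b):
        raise DomainError(f"z={z} too close to an edge for finite-difference step {h}")
    return (collective_error(density, z + h, side) - collective_error(density, z - h, side)) / (2.0 * h)


def _curvature(density: AttributeDensity, z: float, side: GroupSide) -> float:
    h = CURVATURE_STEP_REL * (density.b - density.a)
    return (
        collective_error(density, z + h, side)
        - 2.0 * collective_error(density, z, side)
        + collective_error(density, z - h, side)
    ) / (h * h)


def integrate_boundary(
    density: AttributeDensity,
    side: GroupSide,
    config: DynamicsConfig | None = None,
) -> Trajectory:
    """Integrate the boundary flow dz/dt = -k dErr/dz until it settles.

    Uses an adaptive explicit Runge-Kutta integrator (RK45, rtol 1e-8);
    the flow is one-dimensional and non-stiff.  Stops when the speed
    |dz/dt| drops below ``convergence_tol`` or at ``t_max`` (returned with
    ``converged=False``, not an exception).  z is clamped to stay an
    edge-margin away from the ends of the attribute space.
    """
    side = GroupSide(side)
    config = config or DynamicsConfig()
    z0, t_max, eps = config.resolve(density)
    lo, hi = density.a + eps, density.b - eps

    def rhs(t, y):
        z = min(max(y[0], lo), hi)
        return [-config.k * collective_error_gradient(density, z, side)]

    def settled(t, y):
        return abs(rhs(t, y)[0]) - config.convergence_tol

    settled.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, t_max),
        [z0],
        method="RK45",
        rtol=1e-8,
        atol=1e-10,
        events=settled,
        dense_output=False,
    )
    if not sol.success:
        raise SolverError(f"boundary integration failed: {sol.message}")
    positions = np.clip(sol.y[0], lo, hi)
    errors = np.array([collective_error(density, z, side) for z in positions])
    converged = len(sol.t_events[0]) > 0 or abs(
        rhs(sol.t[-1], [positions[-1]])[0]
    ) < config.convergence_tol
    return Trajectory(
        times=sol.t, positions=positions, errors=errors, converged=bool(converged), side=side
    )


def find_fixed_points(
    density: AttributeDensity,
    side: GroupSide,
    grid_n: int = 256,
    edge_margin: Optional[float] = None,
) -> list[FixedPointResult]:
    """Locate interior zeros of dErr/dz and classify their stability.

    Scans the gradient's sign on a ``grid_n``-point grid over
    (a + eps, b - eps), refines each sign change with Brent's method to
    |gradient| < 1e-9, and labels a root stable when the numerically
    estimated second derivative of Err is positive (marginal when its
    magnitude is below 1e-6).  Returns roots sorted by position; an empty
    list when the gradient never changes sign.
    """
    side = GroupSide(side)
    if grid_n < 64:
        raise DomainError(f"grid_n must be >= 64, got {grid_n}")
    width = density.b - density.a
    eps = edge_margin if edge_margin is not None else EDGE_MARGIN_REL * width
    grid = np.linspace(density.a + eps, density.b - eps, grid_n)

    def _grad(z: float) -> float:
        # thin-tailed densities can leave ~zero mass on one side near the
        # edges; such grid points carry no usable sign information
        try:
            return collective_error_gradient(density, z, side)
        except DegenerateGroupError:
            return np.nan

    grads = np.array([_grad(z) for z in grid])
    results: list[FixedPointResult] = []
    finite = np.isfinite(grads[:-1]) & np.isfinite(grads[1:])
    for i in np.flatnonzero(finite & (np.sign(grads[:-1]) * np.sign(grads[1:]) < 0)):
        root = brentq(
            lambda z: collective_error_gradient(density, z, side),
            grid[i],
            grid[i + 1],
            xtol=1e-13,
            rtol=8.9e-16,
        )
        if abs(collective_error_gradient(density, root, side)) > ROOT_TOL:
            continue
        curv = _curvature(density, root, side)
        if abs(curv) < MARGINAL_CURVATURE:
            stability = "marginal"
        else:
            stability = "stable" if curv > 0 else "unstable"
        results.append(
            FixedPointResult(
                z_star=float(root),
                stability=stability,
                Err_at_star=collective_error(density, root, side),
            )
        )
    # exact-zero grid hits (e.g. symmetric start) would be missed by sign
    # products; treat them as roots too
    for i in np.flatnonzero(np.isfinite(grads) & (grads == 0.0)):
        z = float(grid[i])
        if any(abs(z - r.z_star) < 1e-9 for r in results):
            continue
        curv = _curvature(density, z, side)
        stability = (
            "marginal" if abs(curv) < MARGINAL_CURVATURE else ("stable" if curv > 0 else "unstable")
        )
        results.append(FixedPointResult(z, stability, collective_error(density, z, side)))
    return sorted(results, key=lambda r: r.z_star)
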