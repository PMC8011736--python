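"""Two-group solution and the inbetweener region.

Each group evolves its own boundary independently (group 1 from the left
extreme, group 2 from the right; their error functionals do not couple).
Both settle at boundaries more restrictive than the middle of the
attribute spectrum, leaving an interval (z1*, z2*) of individuals that
both groups categorize as out-group — the inbetweeners.  For a uniform
population on [0, 1] the region is [0.375, 0.625], a quarter of the
population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._exceptions import DegenerateGroupError, SolverError
from .category_error import GroupSide
from .collective_dynamics import (
    EDGE_MARGIN_REL,
    DynamicsConfig,
    FixedPointResult,
    collective_error,
    find_fixed_points,
    integrate_boundary,
)
from .densities import AttributeDensity

__all__ = [
    "BoundaryPair",
    "InbetweenerRegion",
    "solve_boundary",
    "solve_two_groups",
    "inbetweener_region",
    "grid_oracle",
]


@dataclass(frozen=True)
class BoundaryPair:
    """Stable boundaries of the left (z1*) and right (z2*) groups."""

    z1_star: float
    z2_star: float
    density: AttributeDensity


@dataclass(frozen=True)
class InbetweenerRegion:
    """The interval excluded by both groups and its population fraction."""

    lo: float
    hi: float
    fraction: float
    nonempty: bool


def solve_boundary(
    density: AttributeDensity,
    side: GroupSide,
    config: DynamicsConfig | None = None,
) -> FixedPointResult:
    """Stable fixed point reached from the configured start position.

    Integrates the gradient flow from z0 and snaps the settled position to
    the matching root from :func:`find_fixed_points` (root-refined to
    |dErr/dz| < 1e-9); the integration selects the basin, the root-finder
    supplies the precise position.
    """
    side = GroupSide(side)
    config = config or DynamicsConfig()
    traj = integrate_boundary(density, side, config)
    if not traj.converged:
        raise SolverError(
            f"{side.value} group boundary did not settle within t_max; "
            f"final z={traj.positions[-1]:.6f}"
        )
    z_end = traj.positions[-1]
    roots = find_fixed_points(density, side)
    stable = [r for r in roots if r.stability == "stable"]
    if not stable:
        raise SolverError(f"no stable fixed point found for the {side.value} group")
    return min(stable, key=lambda r: abs(r.z_star - z_end))


def solve_two_groups(
    density: AttributeDensity, config: DynamicsConfig | None = None
) -> BoundaryPair:
    """Solve both groups' boundary dynamics independently."""
    z1 = solve_boundary(density, GroupSide.LEFT, config).z_star
    z2 = solve_boundary(density, GroupSide.RIGHT, config).z_star
    return BoundaryPair(z1_star=z1, z2_star=z2, density=density)


def inbetweener_region(
    density: AttributeDensity, pair: BoundaryPair
) -> InbetweenerRegion:
    """Interval between the two boundaries and its population mass.

    Nonempty when z1* < z2*: everyone strictly between the boundaries is
    out-group to both groups.  Crossed boundaries (z1* > z2*, not seen in
    any of the studied densities) are reported with ``nonempty=False``
    and a warning rather than an error.
    """
    lo = min(pair.z1_star, pair.z2_star)
    hi = max(pair.z1_star, pair.z2_star)
    nonempty = pair.z1_star < pair.z2_star
    if pair.z1_star > pair.z2_star:
        warnings.warn(
            f"crossed boundaries: z1*={pair.z1_star:.6f} > z2*={pair.z2_star:.6f}; "
            "no mutually excluded region exists",
            stacklevel=2,
        )
    return InbetweenerRegion(
        lo=lo, hi=hi, fraction=density.mass(lo, hi), nonempty=nonempty
    )


def grid_oracle(
    density: AttributeDensity, side: GroupSide, grid_n: int = 2048
) -> float:
    """Derivative-free check: argmin of Err(z) on a uniform grid.

    Exhaustively evaluates the collective error over (a + eps, b - eps)
    and returns the minimizing grid point; used to cross-validate the
    gradient-based solver to within one grid spacing.
    """
    side = GroupSide(side)
    if grid_n < 256:
        raise ValueError(f"grid_n must be >= 256, got {grid_n}")
    eps = EDGE_MARGIN_REL * (density.b - density.a)
    grid = np.linspace(density.a + eps, density.b - eps, grid_n)

    def _err(z: float) -> float:
        try:
            return collective_error(density, z, side)
        except DegenerateGroupError:
            return np.inf

    errs = np.array([_err(z) for z in grid])
    return float(grid[int(np.argmin(errs))])
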