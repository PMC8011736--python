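"""Individual-level categorization quantities.

A member of a group perceives everyone in a category as sitting at the
category's prototype — the center of mass of the population on that side
of the boundary z.  When an in-group member at position u meets a random
partner at v (drawn from the population density rho), the categorization
error of that encounter is the squared difference between the true
distance D_i = |u - v| and the prototype-based distance D_g (0 for an
in-group partner, |g_out - g_in| for an out-group one).  Averaging over
partners gives the individual error

    err(u, z) = int_a^b (D_g - D_i)^2 rho(v) dv,

which splits into an in-group term int (u-v)^2 rho dv and an out-group
term int (D_g - |u-v|)^2 rho dv.  Because the integrand is quadratic in v
on each side of z, err(u, z) is itself a quadratic polynomial in u whose
coefficients are partial moments of rho — evaluated exactly by the
density families in :mod:`catbounds.densities`.

For the uniform density on [0, 1] (left group) the polynomial collapses
to the closed form

    err(u, z) = u^2 - u z + z^2/2 - z/4 + 1/12,

used throughout the tests as a regression oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from ._exceptions import DegenerateGroupError, DomainError
from .densities import AttributeDensity

__all__ = [
    "GroupSide",
    "GroupPositions",
    "PairDistances",
    "group_positions",
    "pair_distances",
    "individual_error",
    "individual_error_coefficients",
    "uniform_individual_error",
]

#: minimum mass either group may carry before it is considered degenerate
MIN_GROUP_MASS = 1e-12


class GroupSide(str, Enum):
    """Which extreme of the attribute space a group contains.

    ``left`` — group 1, in-group is [a, z); ``right`` — group 2, in-group
    is [z, b].  Membership exactly at z follows the out-group of the left
    group by convention (measure-zero for continuous densities, but fixed
    so histogram densities behave deterministically).
    """

    LEFT = "left"
    RIGHT = "right"


@dataclass(frozen=True)
class GroupPositions:
    """Prototype positions for a boundary z seen from one group's side."""

    g_in: float
    g_out: float
    z: float
    side: GroupSide

    @property
    def group_distance(self) -> float:
        """Distance |g_out - g_in| between the two prototypes."""
        return abs(self.g_out - self.g_in)


@dataclass(frozen=True)
class PairDistances:
    """Individual distance D_i and prototype distance D_g for one encounter."""

    D_i: float
    D_g: float


def _split(density: AttributeDensity, z: float, side: GroupSide):
    """(in_lo, in_hi, out_lo, out_hi) for a boundary z on the given side."""
    if side == GroupSide.LEFT:
        return density.a, z, z, density.b
    return z, density.b, density.a, z


def group_positions(
    density: AttributeDensity, z: float, side: GroupSide
) -> GroupPositions:
    """Prototypes g_in, g_out — truncated centers of mass on each side of z."""
    side = GroupSide(side)
    if not (density.a < z < density.b):
        raise DomainError(f"boundary z={z} must lie strictly inside ({density.a}, {density.b})")
    in_lo, in_hi, out_lo, out_hi = _split(density, z, side)
    if density.mass(in_lo, in_hi) < MIN_GROUP_MASS or density.mass(out_lo, out_hi) < MIN_GROUP_MASS:
        raise DegenerateGroupError(f"boundary z={z} leaves one group with ~zero mass")
    return GroupPositions(
        g_in=density.center_of_mass(in_lo, in_hi),
        g_out=density.center_of_mass(out_lo, out_hi),
        z=z,
        side=side,
    )


def _in_group(u: float, positions: GroupPositions) -> bool:
    if positions.side == GroupSide.LEFT:
        return u < positions.z
    return u >= positions.z


def pair_distances(u: float, v: float, positions: GroupPositions) -> PairDistances:
    """Distances for one encounter between in-group member u and partner v."""
    if not _in_group(u, positions):
        raise DomainError(
            f"u={u} is not in the in-group of the {positions.side.value} "
            f"group with boundary z={positions.z}"
        )
    D_i = abs(u - v)
    D_g = 0.0 if _in_group(v, positions) else positions.group_distance
    return PairDistances(D_i=D_i, D_g=D_g)


def individual_error_coefficients(
    density: AttributeDensity, z: float, side: GroupSide
) -> tuple[float, float, float]:
    """Coefficients (A, B, C) with err(u, z) = A u^2 + B u + C.

    Expanding the two integrals of err(u, z):

        in-group:   u^2 m0_in - 2 u m1_in + m2_in
        out-group:  D_g^2 m0_out -/+ 2 D_g (m1_out - u m0_out)
                    + (m2_out - 2 u m1_out + u^2 m0_out)

    where m_k are partial moments of rho over each side, and the sign of
    the cross term follows from |u - v| = v - u (left group, partner to
    the right) or u - v (right group).  A = m0_in + m0_out = 1 always.
    """
    side = GroupSide(side)
    pos = group_positions(density, z, side)
    in_lo, in_hi, out_lo, out_hi = _split(density, z, side)
    m0_out = density.partial_moment(0, out_lo, out_hi)
    m1_out = density.partial_moment(1, out_lo, out_hi)
    m1_tot = density.partial_moment(1, density.a, density.b)
    m2_tot = density.partial_moment(2, density.a, density.b)
    Dg = pos.group_distance
    sgn = 1.0 if side == GroupSide.LEFT else -1.0
    A = 1.0
    B = -2.0 * m1_tot + sgn * 2.0 * Dg * m0_out
    C = m2_tot + Dg * Dg * m0_out - sgn * 2.0 * Dg * m1_out
    return A, B, C


def individual_error(
    density: AttributeDensity, u: float, z: float, side: GroupSide
) -> float:
    """Individual categorization error err(u, z) for in-group member u.

    Expected squared mismatch between true pairwise distance and
    prototype-based distance over random partners v ~ rho.
    """
    side = GroupSide(side)
    pos = group_positions(density, z, side)
    if not _in_group(u, pos):
        raise DomainError(f"u={u} is not in the in-group for z={z}, side={side.value}")
    A, B, C = individual_error_coefficients(density, z, side)
    err = A * u * u + B * u + C
    return max(err, 0.0)


def uniform_individual_error(u: float, z: float) -> float:
    """Closed-form err(u, z) for the uniform density on [0, 1], left group."""
    return u * u - u * z + z * z / 2.0 - z / 4.0 + 1.0 / 12.0
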