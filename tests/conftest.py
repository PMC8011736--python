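"""Shared fixtures and brute-force integration oracles.

The oracles deliberately avoid the package's moment-based evaluation
path: they integrate the density on dense grids (Riemann / trapezoid
sums), so agreement between the two routes is a genuine cross-check.
"""

import numpy as np
import pytest

from catbounds import make_density
from catbounds.category_error import GroupSide

# the four attribute distributions studied in the model's examples
FAMILY_MATRIX = [
    ("uniform", {}),
    ("beta", {"alpha": 2, "beta": 2}),
    ("beta", {"alpha": 2, "beta": 4}),
    ("bimodal_beta", {"alpha": 2, "beta": 7}),
]


@pytest.fixture(params=FAMILY_MATRIX, ids=lambda p: f"{p[0]}{p[1] or ''}")
def density(request):
    family, params = request.param
    return make_density(family, 0.0, 1.0, **params)


@pytest.fixture
def uniform01():
    return make_density("uniform", 0.0, 1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


# ---------------------------------------------------------------------------
# brute-force oracles


def riemann_mass(density, lo, hi, n=200_001):
    """Trapezoid-rule mass of [lo, hi]."""
    if hi <= lo:
        return 0.0
    x = np.linspace(lo, hi, n)
    return float(np.trapezoid(density.pdf(x), x))


def riemann_com(density, lo, hi, n=200_001):
    """Trapezoid-rule center of mass over [lo, hi]."""
    x = np.linspace(lo, hi, n)
    p = density.pdf(x)
    return float(np.trapezoid(x * p, x) / np.trapezoid(p, x))


def riemann_individual_error(density, u, z, side, n=100_001):
    """Direct numerical evaluation of err(u, z) = int (D_g - D_i)^2 rho dv."""
    side = GroupSide(side)
    a, b = density.a, density.b
    if side == GroupSide.LEFT:
        in_lo, in_hi, out_lo, out_hi = a, z, z, b
    else:
        in_lo, in_hi, out_lo, out_hi = z, b, a, z
    g_in = riemann_com(density, in_lo, in_hi, n)
    g_out = riemann_com(density, out_lo, out_hi, n)
    Dg = abs(g_out - g_in)
    v_in = np.linspace(in_lo, in_hi, n)
    v_out = np.linspace(out_lo, out_hi, n)
    term_in = np.trapezoid((u - v_in) ** 2 * density.pdf(v_in), v_in)
    term_out = np.trapezoid((Dg - np.abs(u - v_out)) ** 2 * density.pdf(v_out), v_out)
    return float(term_in + term_out)


def riemann_collective_error(density, z, side, n=2001):
    """Direct double-sum evaluation of Err(z)."""
    side = GroupSide(side)
    if side == GroupSide.LEFT:
        in_lo, in_hi = density.a, z
    else:
        in_lo, in_hi = z, density.b
    u = np.linspace(in_lo, in_hi, n)
    p = density.pdf(u)
    errs = np.array(
        [riemann_individual_error(density, ui, z, side, n=n) for ui in u]
    )
    return float(np.trapezoid(errs * p, u) / np.trapezoid(p, u))
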