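"""Collective error, gradient flow, and fixed-point location."""

import numpy as np
import pytest

from catbounds import (
    DynamicsConfig,
    GroupSide,
    collective_error,
    collective_error_gradient,
    find_fixed_points,
    integrate_boundary,
    make_density,
)
from catbounds.collective_dynamics import uniform_collective_error
from conftest import FAMILY_MATRIX, riemann_collective_error


class TestCollectiveError:
    def test_uniform_closed_form_examples(self, uniform01):
        # Err(z) = z^2/3 - z/4 + 1/12
        assert collective_error(uniform01, 0.375, GroupSide.LEFT) == pytest.approx(
            0.036458333333, abs=1e-8
        )
        assert collective_error(uniform01, 0.5, GroupSide.LEFT) == pytest.approx(
            0.041666666667, abs=1e-8
        )

    def test_uniform_closed_form_random(self, uniform01, rng):
        for z in rng.uniform(0.05, 0.95, size=100):
            assert collective_error(uniform01, z, GroupSide.LEFT) == pytest.approx(
                uniform_collective_error(z), abs=1e-8
            )

    def test_symmetric_density_left_right_equal_at_midpoint(self):
        d = make_density("beta", 0, 1, alpha=2, beta=2)
        assert collective_error(d, 0.5, GroupSide.LEFT) == pytest.approx(
            collective_error(d, 0.5, GroupSide.RIGHT), abs=1e-10
        )

    @pytest.mark.parametrize("family,params", FAMILY_MATRIX[1:])
    def test_matches_riemann_double_sum(self, family, params):
        d = make_density(family, 0, 1, **params)
        for z in (0.35, 0.6):
            assert collective_error(d, z, GroupSide.LEFT) == pytest.approx(
                riemann_collective_error(d, z, GroupSide.LEFT), abs=1e-5
            )


class TestGradient:
    def test_vanishes_at_uniform_fixed_point(self, uniform01):
        assert collective_error_gradient(uniform01, 0.375, GroupSide.LEFT) == pytest.approx(
            0.0, abs=1e-6
        )

    def test_uniform_derivative_closed_form(self, uniform01, rng):
        # d/dz of z^2/3 - z/4 + 1/12 is 2z/3 - 1/4
        assert collective_error_gradient(uniform01, 0.5, GroupSide.LEFT) == pytest.approx(
            1.0 / 12.0, abs=1e-6
        )
        for z in rng.uniform(0.05, 0.95, size=20):
            assert collective_error_gradient(uniform01, z, GroupSide.LEFT) == pytest.approx(
                2 * z / 3 - 0.25, abs=1e-6
            )

    def test_midpoint_pushes_left_group_leftward(self):
        """From the middle of a symmetric spectrum the error decreases leftward."""
        for family, params in [("uniform", {}), ("beta", {"alpha": 2, "beta": 2})]:
            d = make_density(family, 0, 1, **params)
            assert collective_error_gradient(d, 0.5, GroupSide.LEFT) > 0
            assert collective_error(d, 0.45, GroupSide.LEFT) < collective_error(
                d, 0.5, GroupSide.LEFT
            )


class TestIntegration:
    def test_uniform_converges_to_stable_boundary(self, uniform01):
        traj = integrate_boundary(uniform01, GroupSide.LEFT, DynamicsConfig(z0=0.5))
        assert traj.converged
        assert traj.positions[-1] == pytest.approx(0.375, abs=1e-4)

    def test_starting_at_fixed_point_stays(self, uniform01):
        traj = integrate_boundary(uniform01, GroupSide.LEFT, DynamicsConfig(z0=0.375))
        assert np.all(np.abs(traj.positions - 0.375) < 1e-6)

    def test_rate_constant_only_rescales_time(self, uniform01):
        slow = integrate_boundary(uniform01, GroupSide.LEFT, DynamicsConfig(k=1, z0=0.5))
        fast = integrate_boundary(uniform01, GroupSide.LEFT, DynamicsConfig(k=10, z0=0.5))
        assert fast.positions[-1] == pytest.approx(slow.positions[-1], abs=1e-6)
        assert fast.times[-1] < slow.times[-1]

    def test_error_descent_along_trajectory(self, density):
        traj = integrate_boundary(density, GroupSide.LEFT, DynamicsConfig(z0=0.6))
        assert np.all(np.diff(traj.errors) <= 1e-9)

    def test_times_strictly_increasing(self, uniform01):
        traj = integrate_boundary(uniform01, GroupSide.LEFT, DynamicsConfig(z0=0.7))
        assert np.all(np.diff(traj.times) > 0)


class TestFixedPoints:
    def test_uniform_left(self, uniform01):
        results = find_fixed_points(uniform01, GroupSide.LEFT)
        assert len(results) == 1
        assert results[0].z_star == pytest.approx(0.375, abs=1e-9)
        assert results[0].stability == "stable"

    def test_uniform_right(self, uniform01):
        results = find_fixed_points(uniform01, GroupSide.RIGHT)
        assert len(results) == 1
        assert results[0].z_star == pytest.approx(0.625, abs=1e-9)
        assert results[0].stability == "stable"

    def test_symmetric_beta_mirror(self):
        d = make_density("beta", 0, 1, alpha=2, beta=2)
        left = find_fixed_points(d, GroupSide.LEFT)
        right = find_fixed_points(d, GroupSide.RIGHT)
        stable_l = [r for r in left if r.stability == "stable"]
        stable_r = [r for r in right if r.stability == "stable"]
        assert len(stable_l) == len(stable_r) == 1
        assert stable_l[0].z_star == pytest.approx(1 - stable_r[0].z_star, abs=1e-6)

    def test_k_does_not_enter_fixed_points(self, uniform01):
        # the flow's rate constant never appears in the gradient root problem;
        # solving with different k must land on the same set
        zs = set()
        for k in (0.1, 1.0, 10.0):
            traj = integrate_boundary(uniform01, GroupSide.LEFT, DynamicsConfig(k=k, z0=0.5))
            zs.add(round(traj.positions[-1], 6))
        assert zs == {0.375}

    def test_stable_point_is_grid_argmin(self, density):
        from catbounds import grid_oracle

        for side in (GroupSide.LEFT, GroupSide.RIGHT):
            stable = [
                r for r in find_fixed_points(density, side) if r.stability == "stable"
            ]
            assert stable
            oracle = grid_oracle(density, side, 2048)
            spacing = 1.0 / 2047
            assert min(abs(r.z_star - oracle) for r in stable) <= spacing

    def test_affine_equivariance(self):
        """Rescaling the attribute space rescales the fixed point."""
        c, s = 2.0, 3.0
        d0 = make_density("beta", 0, 1, alpha=2, beta=4)
        d1 = make_density("beta", c, c + s, alpha=2, beta=4)
        z0 = find_fixed_points(d0, GroupSide.LEFT)[0].z_star
        z1 = find_fixed_points(d1, GroupSide.LEFT)[0].z_star
        assert z1 == pytest.approx(c + s * z0, abs=1e-6)

    def test_restrictive_boundaries_straddle_median(self):
        """Both groups exclude more than half the spectrum: z1* below the
        population median, z2* above it."""
        from scipy.stats import beta as beta_dist

        cases = [
            (make_density("uniform", 0, 1), 0.5),
            (make_density("beta", 0, 1, alpha=2, beta=2), 0.5),
            (make_density("bimodal_beta", 0, 1, alpha=2, beta=7), 0.5),
            (
                make_density("beta", 0, 1, alpha=2, beta=4),
                float(beta_dist.median(2, 4)),
            ),
        ]
        for d, median in cases:
            z1 = [r for r in find_fixed_points(d, GroupSide.LEFT) if r.stability == "stable"][0]
            z2 = [r for r in find_fixed_points(d, GroupSide.RIGHT) if r.stability == "stable"][0]
            assert z1.z_star < median < z2.z_star
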