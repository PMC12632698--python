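"""Midpoint and Brownian quadratic-cost inference, with the exact sparse
solver as oracle."""

import numpy as np
import pytest

from spatialarg import (
    LocationTable,
    infer_fast_weighted,
    infer_midpoint,
    quadratic_cost,
    solve_exact_quadratic,
)
from spatialarg.errors import NumericalError, ValidationError

from conftest import build_arg, sim_spatial, S


def _cherry_children_at(x0, x1):
    return build_arg(
        nodes=[(0, S), (0, S), (1, 0)],
        edges=[(2, 0, 0, 1), (2, 1, 0, 1)],
        locations={0: (x0, 0.0), 1: (x1, 0.0)},
    )


def _max_coord_diff(a: LocationTable, b: LocationTable, nodes):
    return max(
        max(abs(a[u][0] - b[u][0]), abs(a[u][1] - b[u][1])) for u in nodes
    )


class TestMidpoint:
    def test_cherry_midpoint(self):
        res = infer_midpoint(_cherry_children_at(0.0, 2.0))
        assert res.locations[2] == pytest.approx((1.0, 0.0))

    def test_balanced_four_tip_symmetry(self, balanced_4tip):
        # strip internal locations and re-infer
        samples_only = balanced_4tip.with_locations(
            LocationTable(
                {u: balanced_4tip.locations[u] for u in range(4)}, crs="unit_grid"
            )
        )
        res = infer_midpoint(samples_only)
        assert res.locations[4] == pytest.approx((0.0, 1.0))
        assert res.locations[5] == pytest.approx((4.0, 1.0))
        assert res.locations[6] == pytest.approx((2.0, 1.0))

    def test_caterpillar_hand_recursion(self, caterpillar):
        # inner = mean((0,0),(2,0)) = (1,0); root = mean((1,0),(8,0)) = (4.5,0)
        res = infer_midpoint(caterpillar)
        assert res.locations[3] == pytest.approx((1.0, 0.0))
        assert res.locations[4] == pytest.approx((4.5, 0.0))

    def test_children_counted_once_despite_multiple_edges(self):
        arg = build_arg(
            nodes=[(0, S), (0, S), (1, 0)],
            edges=[(2, 0, 0, 0.25), (2, 0, 0.5, 1.0), (2, 1, 0, 1)],
            locations={0: (0.0, 0.0), 1: (2.0, 0.0)},
        )
        res = infer_midpoint(arg)
        assert res.locations[2] == pytest.approx((1.0, 0.0))

    def test_sample_locations_fixed(self, samples_only):
        res = infer_midpoint(samples_only)
        for s in samples_only.samples:
            assert res.locations[int(s)] == samples_only.locations[int(s)]

    def test_unlocated_samples_rejected(self, two_tree_pair):
        with pytest.raises(ValidationError):
            infer_midpoint(two_tree_pair)


class TestFastWeighted:
    def test_cherry_equal_weights(self):
        res = infer_fast_weighted(_cherry_children_at(0.0, 4.0))
        assert res.locations[2] == pytest.approx((2.0, 0.0), abs=1e-8)

    def test_unequal_branch_weighted_mean(self, unequal_branch):
        # w = 1/1 and 1/3; x = (0*1 + 4*(1/3)) / (4/3) = 1
        res = infer_fast_weighted(unequal_branch)
        assert res.locations[2][0] == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exact_solver(self, seed):
        arg = sim_spatial(seed=100 + seed)
        coords = {int(s): arg.locations[int(s)] for s in arg.samples}
        arg = arg.with_locations(LocationTable(coords, crs="unit_grid"))
        fast = infer_fast_weighted(arg)
        exact = solve_exact_quadratic(arg)
        assert fast.converged
        assert _max_coord_diff(
            fast.locations, exact.locations, range(arg.num_nodes)
        ) <= 1e-6

    def test_zero_length_branch_rejected_at_construction(self):
        # a zero-duration branch violates the time ordering invariant
        # before inference can even run
        with pytest.raises(ValidationError):
            build_arg(
                nodes=[(0, S), (0, S), (0, 0)],
                edges=[(2, 0, 0, 1), (2, 1, 0, 1)],
                locations={0: (0.0, 0.0), 1: (1.0, 0.0)},
            )

    def test_nonconvergence_is_flagged_not_raised(self, samples_only):
        res = infer_fast_weighted(samples_only, max_iter=1, tol=1e-300)
        assert res.converged is False
        assert res.iterations >= 1
        assert np.isfinite(res.residual)


class TestExactSolver:
    def test_closed_forms(self, unequal_branch):
        res = solve_exact_quadratic(unequal_branch)
        assert res.locations[2][0] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_cost_not_worse_than_midpoint(self, seed):
        arg = sim_spatial(seed=200 + seed)
        coords = {int(s): arg.locations[int(s)] for s in arg.samples}
        arg = arg.with_locations(LocationTable(coords, crs="unit_grid"))
        exact = solve_exact_quadratic(arg)
        mid = infer_midpoint(arg)
        assert quadratic_cost(arg, exact.locations) <= quadratic_cost(
            arg, mid.locations
        ) + 1e-12

    def test_perturbation_increases_cost(self, samples_only):
        exact = solve_exact_quadratic(samples_only)
        base = quadratic_cost(samples_only, exact.locations)
        free = int(np.flatnonzero(~samples_only.is_sample)[0])
        for eps in (1e-3, -1e-3):
            for axis in (0, 1):
                coords = dict(exact.locations.coords)
                x, y = coords[free]
                coords[free] = (x + eps, y) if axis == 0 else (x, y + eps)
                perturbed = LocationTable(coords, crs=exact.locations.crs)
                assert quadratic_cost(samples_only, perturbed) > base

    def test_disconnected_node_named(self):
        arg = build_arg(
            nodes=[(0, S), (0, S), (1, 0), (2, 0)],  # node 3 isolated
            edges=[(2, 0, 0, 1), (2, 1, 0, 1)],
            locations={0: (0.0, 0.0), 1: (1.0, 0.0)},
        )
        with pytest.raises(NumericalError, match="3"):
            solve_exact_quadratic(arg)


class TestInvariants:
    @pytest.mark.parametrize("method", [infer_midpoint, solve_exact_quadratic])
    def test_convex_hull_containment(self, samples_only, method):
        from scipy.spatial import ConvexHull, Delaunay

        pts = samples_only.locations.as_array(samples_only.samples)
        hull = Delaunay(pts)
        res = method(samples_only)
        inferred = res.locations.as_array(range(samples_only.num_nodes))
        # allow boundary tolerance
        shifted = Delaunay(
            (pts - pts.mean(0)) * (1 + 1e-9) + pts.mean(0)
        )
        assert (shifted.find_simplex(inferred) >= 0).all()

    @pytest.mark.parametrize("method", [infer_midpoint, solve_exact_quadratic])
    def test_rigid_motion_equivariance(self, samples_only, method):
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        shift = np.array([2.5, -1.0])
        moved_coords = {
            int(s): tuple(R @ np.array(samples_only.locations[int(s)]) + shift)
            for s in samples_only.samples
        }
        moved = samples_only.with_locations(
            LocationTable(moved_coords, crs="custom")
        )
        base = method(samples_only).locations.as_array(
            range(samples_only.num_nodes)
        )
        res = method(moved).locations.as_array(range(samples_only.num_nodes))
        assert np.allclose(res, base @ R.T + shift, atol=1e-8)
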