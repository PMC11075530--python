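import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from topothought import (
    SemanticPath,
    circuitousness,
    consecutive_distances,
    extract_features,
    min_path_exact,
    min_path_heuristic,
    min_required_speed,
    mvee,
    normalized_volume,
    path_length,
    project_to_affine_subspace,
    speed,
    unit_ball_volume,
)
from topothought.synthetic import brute_force_min_path, verify_mvee_optimality
from topothought.topography import Ellipsoid

from conftest import random_points


def _random_rotation(d: int, seed: int) -> np.ndarray:
    q, r = np.linalg.qr(np.random.default_rng(seed).normal(size=(d, d)))
    return q * np.sign(np.diag(r))


class TestSpeed:
    def test_three_four_five(self):
        pts = np.array([[0.0, 0.0], [3.0, 4.0], [3.0, 0.0]])
        np.testing.assert_allclose(consecutive_distances(pts), [5.0, 4.0])
        assert speed(pts) == pytest.approx(4.5)

    def test_collinear_equal_spacing(self):
        pts = np.arange(8.0)[:, None] * 1.7
        assert speed(pts) == pytest.approx(1.7)

    def test_degenerate_and_too_short(self):
        assert speed(np.zeros((4, 3))) == 0.0
        with pytest.raises(ValueError, match="too short"):
            consecutive_distances(np.zeros((1, 3)))

    def test_accepts_semantic_path(self):
        p = SemanticPath("x", np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert speed(p) == pytest.approx(5.0)


class TestProjection:
    def test_affine_hull_of_three_points(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(3, 300))
        proj, d, basis = project_to_affine_subspace(base)
        assert d == 2 and proj.shape == (3, 2)

    def test_identical_points_have_dim_zero(self):
        proj, d, _ = project_to_affine_subspace(np.ones((5, 10)))
        assert d == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_pairwise_distances_preserved(self, seed):
        pts = random_points(seed, 9, 40)
        proj, d, _ = project_to_affine_subspace(pts)
        assert d == 8
        np.testing.assert_allclose(pdist(proj), pdist(pts), atol=1e-9)


class TestMVEE:
    def test_one_dimensional_pair_is_spanning_interval(self):
        ell = mvee(np.array([[0.0], [7.5]]))
        assert ell.volume == pytest.approx(7.5, abs=1e-12)
        assert ell.center[0] == pytest.approx(3.75)

    def test_unit_square_gives_circumscribed_disk(self):
        sq = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        ell = mvee(sq)
        assert ell.volume == pytest.approx(math.pi / 2, abs=1e-9)
        np.testing.assert_allclose(ell.center, [0.5, 0.5], atol=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_containment_and_john_conditions(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(rng.integers(5, 11), rng.integers(2, 5)))
        pts = project_to_affine_subspace(pts)[0]
        ell = mvee(pts)
        assert ell.mahalanobis(pts).max() <= 1.0 + 1e-6
        assert verify_mvee_optimality(pts, ell, tol=1e-3).passed

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_high_precision_oracle(self, seed):
        pts = project_to_affine_subspace(random_points(seed + 50, 8, 3))[0]
        ell = mvee(pts, tol=1e-7)
        oracle = mvee(pts, tol=1e-12, max_iter=200_000)
        assert ell.volume == pytest.approx(oracle.volume, rel=1e-4)

    def test_adding_outside_point_strictly_increases_volume(self):
        pts = project_to_affine_subspace(random_points(3, 7, 3))[0]
        ell = mvee(pts)
        outside = ell.center + 2.5 * (pts[0] - ell.center)
        bigger = mvee(np.vstack([pts, outside]))
        assert bigger.volume > ell.volume * (1 + 1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="d\\+1"):
            mvee(np.eye(3)[:2] @ np.eye(3))  # 2 points claimed to span 3-d

    def test_degenerate_zero_dim(self):
        ell = mvee(np.zeros((4, 0)))
        assert ell.volume == 0.0 and ell.d == 0


class TestNormalizedVolume:
    def test_sphere_closed_form(self):
        r, d = 2.0, 3
        ell = Ellipsoid(
            center=np.zeros(d), shape=np.eye(d) / r**2,
            volume=unit_ball_volume(d) * r**d,
            log_volume=math.log(unit_ball_volume(d) * r**d), d=d,
        )
        assert normalized_volume(ell, T=10) == pytest.approx(
            unit_ball_volume(d) ** (1 / d) * r
        )
        assert normalized_volume(ell, T=10, mode="per_chunk") == pytest.approx(
            unit_ball_volume(d) ** (1 / d) * r / 10
        )
        assert normalized_volume(ell, T=10, mode="raw") == pytest.approx(ell.volume)

    def test_scaling_homogeneity(self):
        pts = project_to_affine_subspace(random_points(9, 8, 3))[0]
        v1 = normalized_volume(mvee(pts), T=8)
        v3 = normalized_volume(mvee(3.0 * pts), T=8)
        assert v3 == pytest.approx(3.0 * v1, rel=1e-6)

    def test_zero_dim_is_zero(self):
        ell = mvee(np.zeros((4, 0)))
        assert normalized_volume(ell, T=4) == 0.0


class TestExactPath:
    def test_trivial_sizes(self):
        two = min_path_exact(np.array([[0.0], [4.0]]))
        assert two.solver == "trivial" and two.total_length == pytest.approx(4.0)
        three = min_path_exact(np.array([[0.0], [2.0], [1.0]]))
        assert three.order == (0, 1, 2)
        assert three.total_length == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(int(rng.integers(4, 10)), 2))
        ex = min_path_exact(pts)
        bf = brute_force_min_path(pts)
        assert ex.total_length == pytest.approx(bf.total_length, abs=1e-9)
        assert ex.order == bf.order  # shared lexicographic tie-break

    def test_endpoints_fixed(self):
        pts = random_points(1, 8, 3)
        sol = min_path_exact(pts)
        assert sol.order[0] == 0 and sol.order[-1] == 7
        assert sorted(sol.order) == list(range(8))

    def test_refuses_large_instances(self):
        with pytest.raises(ValueError, match="heuristic"):
            min_path_exact(np.zeros((20, 2)), exact_max=12)


class TestHeuristicPath:
    def test_identity_optimal_for_sorted_collinear(self):
        pts = np.sort(np.random.default_rng(0).normal(size=9))[:, None]
        sol = min_path_heuristic(pts, seed=0)
        assert sol.total_length == pytest.approx(pts[-1, 0] - pts[0, 0])

    @pytest.mark.parametrize("seed", range(10))
    def test_bracketed_by_exact_and_observed(self, seed):
        pts = random_points(seed + 100, 12, 3)
        he = min_path_heuristic(pts, restarts=5, seed=7)
        ex = min_path_exact(pts)
        observed = path_length(pts, range(12))
        assert ex.total_length - 1e-9 <= he.total_length <= observed + 1e-9

    def test_seed_determinism(self):
        pts = random_points(5, 15, 4)
        a = min_path_heuristic(pts, restarts=8, seed=11)
        b = min_path_heuristic(pts, restarts=8, seed=11)
        assert a.order == b.order and a.total_length == b.total_length


class TestSpeedDecomposition:
    def test_min_required_speed_examples(self):
        sol = min_path_exact(np.array([[0.0], [4.0]]))
        assert min_required_speed(sol, 2) == pytest.approx(4.0)
        pts = np.arange(6.0)[:, None] * 0.5
        assert min_required_speed(min_path_exact(pts), 6) == pytest.approx(0.5)

    def test_interior_shuffle_leaves_min_speed_unchanged(self):
        pts = random_points(2, 9, 3)
        shuffled = pts[[0, 4, 2, 6, 3, 5, 1, 7, 8]]
        a = min_required_speed(min_path_exact(pts), 9)
        b = min_required_speed(min_path_exact(shuffled), 9)
        assert a == pytest.approx(b, rel=1e-12)

    def test_circuitousness_conventions(self):
        assert circuitousness(1.5, 1.0) == (1.5, False)
        assert circuitousness(0.0, 0.0) == (1.0, True)
        with pytest.raises(ValueError, match="inconsistency"):
            circuitousness(1.0, 0.0)

    def test_single_interior_point_is_never_circuitous(self):
        # with endpoints fixed, T = 3 admits exactly one order
        pts = np.array([[0.0], [2.0], [1.0]])
        sp = speed(pts)
        ms = min_required_speed(min_path_exact(pts), 3)
        assert circuitousness(sp, ms)[0] == pytest.approx(1.0)


class TestExtractFeatures:
    def _path(self, seed, T=10, d=4):
        return SemanticPath(f"p{seed}", random_points(seed, T, d))

    @pytest.mark.parametrize("seed", range(8))
    def test_log_identity(self, seed):
        f = extract_features(self._path(seed))
        dev = abs(
            math.log(f.speed) - math.log(f.circuitousness) - math.log(f.min_required_speed)
        )
        assert dev < 1e-9
        assert f.circuitousness >= 1 - 1e-9  # exact solver at this size
        assert f.solver == "exact"

    @pytest.mark.parametrize("seed", range(5))
    def test_rigid_motion_invariance(self, seed):
        pts = random_points(seed, 9, 5)
        R = _random_rotation(5, seed + 1)
        shift = np.random.default_rng(seed + 2).normal(size=5)
        moved = pts @ R.T + shift
        f0 = extract_features(SemanticPath("a", pts), mvee_tol=1e-10)
        f1 = extract_features(SemanticPath("b", moved), mvee_tol=1e-10)
        for attr in ("speed", "norm_volume", "min_required_speed", "circuitousness"):
            assert getattr(f1, attr) == pytest.approx(getattr(f0, attr), rel=1e-8)

    def test_scaling_homogeneity(self):
        pts = random_points(11, 10, 4)
        c = 2.5
        f0 = extract_features(SemanticPath("a", pts), mvee_tol=1e-10)
        f1 = extract_features(SemanticPath("b", c * pts), mvee_tol=1e-10)
        assert f1.speed == pytest.approx(c * f0.speed)
        assert f1.min_required_speed == pytest.approx(c * f0.min_required_speed)
        assert f1.norm_volume == pytest.approx(c * f0.norm_volume, rel=1e-8)
        assert f1.circuitousness == pytest.approx(f0.circuitousness, rel=1e-9)

    def test_interior_permutation_changes_only_order_features(self):
        pts = random_points(13, 10, 4)
        perm = [0, 5, 2, 7, 4, 1, 8, 3, 6, 9]
        f0 = extract_features(SemanticPath("a", pts))
        f1 = extract_features(SemanticPath("b", pts[perm]))
        assert f1.min_required_speed == pytest.approx(f0.min_required_speed, rel=1e-9)
        assert f1.norm_volume == pytest.approx(f0.norm_volume, rel=1e-9)
        assert f1.speed >= f0.min_required_speed * (1 - 1e-9)

    def test_solver_tag_switches_to_heuristic(self):
        f = extract_features(self._path(3, T=20), exact_max=12, restarts=2, seed=1)
        assert f.solver == "heuristic"

    def test_compute_min_path_off(self):
        f = extract_features(self._path(4), compute_min_path=False)
        assert math.isnan(f.min_required_speed) and f.solver == "none"

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            extract_features(SemanticPath("x", np.zeros((1, 3))))
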