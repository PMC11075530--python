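"""Topography features of a semantic path: speed, volume, minimum required
speed, and circuitousness.

Given a document's path {x_1, ..., x_T} in embedding space:

- **speed** is the mean Euclidean distance between consecutive points —
  total distance travelled divided by T-1;
- **volume** is the Lebesgue volume of the minimum-volume enclosing ellipsoid
  (Löwner–John ellipsoid) of the points, computed in the affine hull of the
  points (effective dimension d <= T-1) because T ~ 22 points in a 300-d
  ambient space span a proper subspace where the full-dimensional volume
  is identically zero;
- **minimum required speed** is the length of the shortest Hamiltonian path
  through all points with the first and last point fixed (an open-path
  Traveling Salesperson optimum), divided by T-1;
- **circuitousness** = speed / minimum required speed (>= 1 when the exact
  solver is used): how suboptimally the content is ordered given what it
  covers.  By construction log(speed) = log(circuitousness) +
  log(minimum required speed).

The MVEE is solved with the Khachiyan dual (D-optimal design) iteration with
Wolfe–Atwood away steps; the exact TSP uses Held–Karp dynamic programming over
interior-point subsets, and larger instances use 2-opt local search over
several deterministic and seeded random starts.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .embeddings import SemanticPath

__all__ = [
    "Ellipsoid",
    "PathSolution",
    "TopographyFeatures",
    "consecutive_distances",
    "speed",
    "project_to_affine_subspace",
    "unit_ball_volume",
    "mvee",
    "normalized_volume",
    "path_length",
    "min_path_exact",
    "min_path_heuristic",
    "min_required_speed",
    "circuitousness",
    "extract_features",
    "MVEENonConvergence",
    "DEFAULT_EXACT_MAX",
    "DEFAULT_RESTARTS",
    "DEFAULT_MVEE_TOL",
    "DEFAULT_RANK_TOL",
]

DEFAULT_EXACT_MAX = 12      # max interior points for the exact Held–Karp solver
DEFAULT_RESTARTS = 10       # random restarts for the 2-opt heuristic
DEFAULT_MVEE_TOL = 1e-7     # Khachiyan convergence tolerance
DEFAULT_RANK_TOL = 1e-9     # relative singular-value cutoff for the affine hull
DEFAULT_MVEE_MAX_ITER = 10_000


class MVEENonConvergence(RuntimeError):
    """Khachiyan iteration did not reach tolerance; carries diagnostics."""

    def __init__(self, iterations: int, gap: float, tol: float):
        self.iterations = iterations
        self.gap = gap
        self.tol = tol
        super().__init__(
            f"MVEE did not converge in {iterations} iterations "
            f"(remaining relative gap {gap:.3e}, tol {tol:.1e})"
        )


def _as_points(path) -> np.ndarray:
    pts = path.points if isinstance(path, SemanticPath) else np.asarray(path, dtype=float)
    if pts.ndim != 2:
        raise ValueError("points must be a 2-d array (T, D)")
    return np.asarray(pts, dtype=float)


# ---------------------------------------------------------------------------
# Speed
# ---------------------------------------------------------------------------

def consecutive_distances(path) -> np.ndarray:
    """Euclidean distances between consecutive path points (length T-1)."""
    pts = _as_points(path)
    if pts.shape[0] < 2:
        raise ValueError("path too short: need at least 2 points")
    return np.linalg.norm(np.diff(pts, axis=0), axis=1)


def speed(path) -> float:
    """Mean consecutive distance: total distance travelled / (T-1)."""
    return float(consecutive_distances(path).mean())


# ---------------------------------------------------------------------------
# Affine-hull projection and minimum-volume enclosing ellipsoid
# ---------------------------------------------------------------------------

def project_to_affine_subspace(
    points, rank_tol: float = DEFAULT_RANK_TOL
) -> tuple[np.ndarray, int, np.ndarray]:
    """Express points in an orthonormal basis of their affine hull.

    Returns ``(projected, d, basis)`` where ``projected`` has shape (T, d),
    ``d`` is the number of singular values exceeding ``rank_tol`` times the
    largest, and ``basis`` (d, D) maps back to the centered ambient space.
    Pairwise distances are preserved (orthonormal basis).
    """
    pts = _as_points(points)
    if pts.shape[0] < 1:
        raise ValueError("need at least one point")
    center = pts.mean(axis=0)
    X = pts - center
    # SVD of the centered cloud; right singular vectors span the affine hull
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    if s.size == 0 or s[0] == 0.0:
        return np.zeros((pts.shape[0], 0)), 0, np.zeros((0, pts.shape[1]))
    d = int(np.sum(s > rank_tol * s[0]))
    basis = vt[:d]
    return X @ basis.T, d, basis


def unit_ball_volume(d: int) -> float:
    """Lebesgue volume of the unit ball in d dimensions (1.0 for d = 0)."""
    return math.pi ** (d / 2) / math.gamma(d / 2 + 1)


@dataclass
class Ellipsoid:
    """Enclosing ellipsoid {x : (x-c)^T A (x-c) <= 1} in effective dimension d.

    ``volume`` is the d-dimensional Lebesgue measure U_d / sqrt(det A);
    ``log_volume`` is kept separately because det A under/overflows for
    d ~ 20.  A degenerate (d = 0) ellipsoid has volume 0.
    """

    center: np.ndarray
    shape: np.ndarray
    volume: float
    log_volume: float
    d: int
    iterations: int = 0
    support_weights: np.ndarray | None = None

    def mahalanobis(self, points) -> np.ndarray:
        pts = _as_points(points)
        diff = pts - self.center
        return np.einsum("ij,jk,ik->i", diff, self.shape, diff)


def mvee(
    points,
    tol: float = DEFAULT_MVEE_TOL,
    max_iter: int = DEFAULT_MVEE_MAX_ITER,
) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of full-rank points (Khachiyan).

    Solves the dual D-optimal design problem with the Wolfe–Atwood
    add/decrease iteration: at each step either increase the weight of the
    point with the largest Mahalanobis value or decrease the weight of the
    active point with the smallest, until both sided optimality gaps fall
    below ``tol``.  The returned shape matrix is rescaled so the farthest
    point lies exactly on the boundary, guaranteeing containment.

    ``points`` must already be expressed in their full-rank dimension d
    (see :func:`project_to_affine_subspace`) with T >= d + 1.
    """
    P = _as_points(points)
    T, d = P.shape
    if d == 0:
        c = np.zeros(0) if T == 0 else P.mean(axis=0)
        return Ellipsoid(center=c, shape=np.zeros((0, 0)), volume=0.0,
                         log_volume=-math.inf, d=0)
    if T < d + 1:
        raise ValueError(f"need at least d+1 = {d + 1} points in dimension {d}, got {T}")

    Q = np.hstack([P, np.ones((T, 1))])  # lifted points, shape (T, d+1)
    u = np.full(T, 1.0 / T)
    n = d + 1
    it = 0
    for it in range(1, max_iter + 1):
        X = Q.T @ (Q * u[:, None])
        try:
            Xinv = np.linalg.inv(X)
        except np.linalg.LinAlgError:
            Xinv = np.linalg.pinv(X)
        M = np.einsum("ij,jk,ik->i", Q, Xinv, Q)
        j_plus = int(np.argmax(M))
        kappa_plus = M[j_plus]
        active = u > 0
        M_active = np.where(active, M, np.inf)
        j_minus = int(np.argmin(M_active))
        kappa_minus = M_active[j_minus]
        up_gap = kappa_plus / n - 1.0
        down_gap = 1.0 - kappa_minus / n
        if up_gap <= tol and down_gap <= tol:
            break
        if up_gap >= down_gap:
            # add step toward the most-violating point
            beta = (kappa_plus - n) / (n * (kappa_plus - 1.0))
            u *= 1.0 - beta
            u[j_plus] += beta
        else:
            # away (decrease) step at the least-needed active point
            beta = min(
                (n - kappa_minus) / (n * (kappa_minus - 1.0)) if kappa_minus > 1.0 else u[j_minus] / (1.0 - u[j_minus]),
                u[j_minus] / (1.0 - u[j_minus]),
            )
            u *= 1.0 + beta
            u[j_minus] -= beta
            u[j_minus] = max(u[j_minus], 0.0)
    else:
        X = Q.T @ (Q * u[:, None])
        M = np.einsum("ij,jk,ik->i", Q, np.linalg.pinv(X), Q)
        gap = max(M.max() / n - 1.0, 1.0 - np.where(u > 0, M, np.inf).min() / n)
        raise MVEENonConvergence(max_iter, float(gap), tol)

    c = P.T @ u
    scatter = P.T @ (P * u[:, None]) - np.outer(c, c)
    A = np.linalg.inv(scatter) / d
    # rescale so the farthest point sits exactly on the boundary
    diff = P - c
    m = np.einsum("ij,jk,ik->i", diff, A, diff)
    m_max = float(m.max())
    if m_max > 0:
        A = A / m_max
    sign, logdet = np.linalg.slogdet(A)
    if sign <= 0:
        raise MVEENonConvergence(it, math.nan, tol)
    log_vol = math.log(unit_ball_volume(d)) - 0.5 * logdet
    return Ellipsoid(
        center=c,
        shape=A,
        volume=math.exp(log_vol) if log_vol < 700 else math.inf,
        log_volume=log_vol,
        d=d,
        iterations=it,
        support_weights=u,
    )


def normalized_volume(ell: Ellipsoid, T: int, mode: str = "dim_root") -> float:
    """Length-scale normalization of an ellipsoid volume.

    - ``dim_root`` (default): volume^(1/d), a per-dimension length scale
      comparable across documents with different effective dimension;
    - ``per_chunk``: volume^(1/d) / T;
    - ``raw``: the d-dimensional volume itself.

    T and d are always reported alongside in feature tables so downstream
    analyses can control for document length.
    """
    if ell.d == 0:
        return 0.0
    if mode == "raw":
        return ell.volume
    dim_root = math.exp(ell.log_volume / ell.d)
    if mode == "dim_root":
        return dim_root
    if mode == "per_chunk":
        return dim_root / T
    raise ValueError(f"unknown volume mode {mode!r}")


# ---------------------------------------------------------------------------
# Open-path TSP with fixed endpoints
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PathSolution:
    """A visiting order with fixed endpoints and its total length.

    ``order`` is a permutation of 0..T-1 with order[0] = 0 and
    order[-1] = T-1.  ``solver`` is ``"exact"`` (global optimum),
    ``"heuristic"`` (2-opt local optimum), or ``"trivial"`` (T <= 3,
    only one admissible order).
    """

    order: tuple[int, ...]
    total_length: float
    solver: str


def path_length(points, order) -> float:
    """Sum of consecutive Euclidean distances along ``order``."""
    pts = _as_points(points)
    idx = np.asarray(order, dtype=int)
    return float(np.linalg.norm(np.diff(pts[idx], axis=0), axis=1).sum())


def _check_path_input(pts: np.ndarray) -> None:
    if pts.shape[0] < 2:
        raise ValueError("path too short: need at least 2 points")


def min_path_exact(path, exact_max: int = DEFAULT_EXACT_MAX) -> PathSolution:
    """Globally shortest Hamiltonian path with endpoints fixed at x_1, x_T.

    Held–Karp dynamic programming over subsets of the T-2 interior points;
    refuses instances with more than ``exact_max`` interior points.  Ties are
    broken toward the lexicographically smallest order.
    """
    pts = _as_points(path)
    _check_path_input(pts)
    T = pts.shape[0]
    m = T - 2
    if m > exact_max:
        raise ValueError(
            f"{m} interior points exceed exact_max={exact_max}; use min_path_heuristic"
        )
    if T == 2:
        return PathSolution((0, 1), float(np.linalg.norm(pts[1] - pts[0])), "trivial")
    if T == 3:
        return PathSolution((0, 1, 2), path_length(pts, (0, 1, 2)), "trivial")

    D = squareform(pdist(pts))
    interior = list(range(1, T - 1))
    end = T - 1
    full = (1 << m) - 1
    # g[mask][j] = min cost of a path starting at interior j, visiting exactly
    # the interior set `mask` (j not in mask), then finishing at the endpoint.
    g = [[0.0] * m for _ in range(full + 1)]
    for j in range(m):
        g[0][j] = D[interior[j], end]
    masks_by_count: list[list[int]] = [[] for _ in range(m + 1)]
    for mask in range(1, full + 1):
        masks_by_count[mask.bit_count()].append(mask)
    for count in range(1, m):
        for mask in masks_by_count[count]:
            for j in range(m):
                if mask & (1 << j):
                    continue
                best = math.inf
                mm = mask
                while mm:
                    k = (mm & -mm).bit_length() - 1
                    cand = D[interior[j], interior[k]] + g[mask ^ (1 << k)][k]
                    if cand < best:
                        best = cand
                    mm &= mm - 1
                g[mask][j] = best
    # forward-greedy reconstruction: at each position take the smallest
    # interior index whose completion cost attains the optimum, which yields
    # the lexicographically smallest optimal order
    order = [0]
    rem = full
    total = 0.0
    while rem:
        best = math.inf
        best_j = -1
        for j in range(m):
            if not rem & (1 << j):
                continue
            cand = D[order[-1], interior[j]] + g[rem ^ (1 << j)][j]
            if cand < best:
                best = cand
                best_j = j
        total += D[order[-1], interior[best_j]]
        order.append(interior[best_j])
        rem ^= 1 << best_j
    total += D[order[-1], end]
    order.append(end)
    return PathSolution(tuple(order), float(total), "exact")


def _two_opt(D: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Best-improvement 2-opt for an open path with fixed endpoints."""
    T = order.shape[0]
    if T <= 3:
        return order
    m = T - 2  # interior positions 1..T-2
    lower = np.where(
        np.arange(m)[None, :] > np.arange(m)[:, None], 0.0, np.inf
    )  # only j > i reversals are meaningful
    while True:
        P = D[order[:, None], order[None, :]]
        cons = P[np.arange(T - 1), np.arange(1, T)]
        # delta of reversing segment i..j (1 <= i < j <= T-2):
        #   P[i-1, j] + P[i, j+1] - P[i-1, i] - P[j, j+1]
        delta = (
            P[0:m, 1 : m + 1] + P[1 : m + 1, 2 : m + 2]
            - cons[:m, None] - cons[None, 1 : m + 1]
            + lower
        )
        k = int(np.argmin(delta))
        bi, bj = divmod(k, m)
        if delta[bi, bj] >= -1e-12:
            return order
        ii, jj = bi + 1, bj + 1
        order = np.concatenate([order[:ii], order[ii : jj + 1][::-1], order[jj + 1 :]])


def min_path_heuristic(
    path, restarts: int = DEFAULT_RESTARTS, seed: int = 0
) -> PathSolution:
    """2-opt heuristic for the fixed-endpoint shortest path.

    Starts: the identity (observed) order, nearest-neighbor construction from
    the first point, and ``restarts`` seeded random interior orders; each is
    improved by best-improvement 2-opt until no improving segment reversal
    remains.  Because the identity order is always a candidate, the returned
    length never exceeds the observed path length.  Deterministic for a fixed
    seed.
    """
    pts = _as_points(path)
    _check_path_input(pts)
    T = pts.shape[0]
    if T == 2:
        return PathSolution((0, 1), float(np.linalg.norm(pts[1] - pts[0])), "trivial")
    if T == 3:
        return PathSolution((0, 1, 2), path_length(pts, (0, 1, 2)), "trivial")
    D = squareform(pdist(pts))
    end = T - 1

    starts: list[np.ndarray] = [np.arange(T)]
    # nearest-neighbor from the start, endpoint excluded until last
    remaining = set(range(1, T - 1))
    nn = [0]
    while remaining:
        cur = nn[-1]
        nxt = min(remaining, key=lambda k: (D[cur, k], k))
        nn.append(nxt)
        remaining.remove(nxt)
    nn.append(end)
    starts.append(np.array(nn))
    rng = np.random.default_rng(seed)
    for _ in range(restarts):
        interior = rng.permutation(np.arange(1, T - 1))
        starts.append(np.concatenate([[0], interior, [end]]))

    best_order: np.ndarray | None = None
    best_len = math.inf
    for start in starts:
        improved = _two_opt(D, start)
        length = float(D[improved[:-1], improved[1:]].sum())
        if length < best_len - 1e-12 or (
            abs(length - best_len) <= 1e-12
            and best_order is not None
            and tuple(improved) < tuple(best_order)
        ):
            best_len = length
            best_order = improved
    assert best_order is not None
    return PathSolution(tuple(int(v) for v in best_order), best_len, "heuristic")


def min_required_speed(sol: PathSolution, T: int) -> float:
    """Shortest-path length divided by T-1."""
    if T < 2:
        raise ValueError("need T >= 2")
    return sol.total_length / (T - 1)


def circuitousness(speed_value: float, min_speed: float) -> tuple[float, bool]:
    """speed / minimum required speed; returns (value, degenerate_flag).

    A path whose points all coincide has both speeds 0; by convention its
    circuitousness is 1 with the degenerate flag set.  min_speed = 0 with
    speed > 0 is impossible for a valid path and raises.
    """
    if min_speed == 0.0:
        if speed_value > 0.0:
            raise ValueError(
                "internal inconsistency: zero minimum required speed with positive speed"
            )
        return 1.0, True
    return speed_value / min_speed, False


# ---------------------------------------------------------------------------
# Combined per-document features
# ---------------------------------------------------------------------------

@dataclass
class TopographyFeatures:
    """All topography features of one document.

    speed = min_required_speed * circuitousness holds to numerical tolerance;
    circuitousness >= 1 whenever ``solver`` is exact.
    """

    doc_id: str
    T: int
    d: int
    speed: float
    raw_volume: float
    log_raw_volume: float
    norm_volume: float
    min_required_speed: float
    circuitousness: float
    solver: str
    dropped_chunks: int = 0
    degenerate: bool = False


def extract_features(
    path: SemanticPath,
    volume_mode: str = "dim_root",
    exact_max: int = DEFAULT_EXACT_MAX,
    restarts: int = DEFAULT_RESTARTS,
    seed: int = 0,
    rank_tol: float = DEFAULT_RANK_TOL,
    mvee_tol: float = DEFAULT_MVEE_TOL,
    mvee_max_iter: int = DEFAULT_MVEE_MAX_ITER,
    compute_min_path: bool = True,
) -> TopographyFeatures:
    """Compute every topography feature of one semantic path.

    Uses the exact Held–Karp solver when the interior has at most
    ``exact_max`` points, the seeded 2-opt heuristic otherwise; the choice is
    recorded in the ``solver`` tag.  ``compute_min_path=False`` skips the
    shortest-path computation (min_required_speed and circuitousness are NaN)
    for workloads that only need speed and volume.

    Raises ``ValueError`` for paths flagged too short (T < 2); callers
    processing corpora should check ``path.flags`` first.
    """
    pts = path.points
    T = pts.shape[0]
    if T < 2:
        raise ValueError(f"path {path.doc_id!r} too short for features (T={T})")
    sp = speed(pts)

    projected, d, _ = project_to_affine_subspace(pts, rank_tol=rank_tol)
    ell = mvee(projected, tol=mvee_tol, max_iter=mvee_max_iter)
    nvol = normalized_volume(ell, T, mode=volume_mode)

    if compute_min_path:
        if T - 2 <= exact_max:
            sol = min_path_exact(pts, exact_max=exact_max)
        else:
            sol = min_path_heuristic(pts, restarts=restarts, seed=seed)
        ms = min_required_speed(sol, T)
        circ, degenerate = circuitousness(sp, ms)
        solver = sol.solver
    else:
        ms = math.nan
        circ = math.nan
        degenerate = False
        solver = "none"

    return TopographyFeatures(
        doc_id=path.doc_id,
        T=T,
        d=d,
        speed=sp,
        raw_volume=ell.volume,
        log_raw_volume=ell.log_volume,
        norm_volume=nvol,
        min_required_speed=ms,
        circuitousness=circ,
        solver=solver,
        dropped_chunks=path.dropped_chunks,
        degenerate=degenerate,
    )
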