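"""Synthetic fixtures and independent oracles.

Everything here is deterministic given a seed and platform-independent
(word vectors derive from a cryptographic hash of the word), so the rest of
the package is testable without downloading pretrained embeddings or any
natural-language resource.

- :func:`hash_embedding_store` — pseudo-random unit word vectors keyed by
  (word, seed);
- :func:`generate_planted_path` — smooth low-curvature trajectories with
  controllable step size and global scale, optionally with the interior
  order shuffled (raises speed and circuitousness while leaving volume and
  minimum required speed unchanged);
- :func:`generate_corpus` — whole synthetic corpora of ~550-word documents
  from an artificial vocabulary, with an author-level outcome generated as a
  linear function of the standardized log-volume and log-speed actually
  measured on the generated texts, plus Gaussian noise;
- :func:`brute_force_min_path` — exhaustive fixed-endpoint shortest-path
  enumeration (oracle for the exact TSP solver);
- :func:`verify_mvee_optimality` — John optimality conditions for a claimed
  minimum-volume enclosing ellipsoid.
"""

from __future__ import annotations

import hashlib
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .embeddings import EmbeddingStore, SemanticPath
from .textproc import RawDocument
from .topography import Ellipsoid, PathSolution, mvee, path_length, project_to_affine_subspace, speed

__all__ = [
    "hash_embedding_store",
    "PlantedPathSpec",
    "generate_planted_path",
    "SyntheticCorpusSpec",
    "SyntheticCorpus",
    "generate_corpus",
    "brute_force_min_path",
    "verify_mvee_optimality",
    "MVEEOptimalityReport",
]


# ---------------------------------------------------------------------------
# Hash-based embedding store
# ---------------------------------------------------------------------------

def _word_generator(word: str, seed: int) -> np.random.Generator:
    digest = hashlib.blake2b(f"{seed}\x00{word}".encode("utf-8"), digest_size=8).digest()
    return np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))


def hash_embedding_store(vocabulary, d: int = 300, seed: int = 0) -> EmbeddingStore:
    """Deterministic pseudo-random unit vectors for each word.

    The vector of a word is a function of (word, seed) only — independent of
    vocabulary order, call count, or platform — so two stores built for
    overlapping vocabularies agree on the overlap.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    table = {}
    for word in vocabulary:
        vec = _word_generator(word, seed).standard_normal(d)
        norm = np.linalg.norm(vec)
        while norm == 0.0:  # astronomically unlikely; regenerate deterministically
            vec = _word_generator(word + "\x01", seed).standard_normal(d)
            norm = np.linalg.norm(vec)
        table[word] = vec / norm
    return EmbeddingStore(table, dim=d)


# ---------------------------------------------------------------------------
# Planted paths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPathSpec:
    """A smooth trajectory with planted geometry.

    ``step`` is the consecutive step length of the base curve and ``scale``
    a global magnification applied to the whole point set (so doubling
    ``scale`` doubles every distance — speed, minimum required speed, and
    the per-dimension volume scale — exactly, at a fixed seed).  ``sorted``
    order follows the curve; ``shuffled`` permutes the interior points while
    keeping both endpoints, which changes speed and circuitousness but not
    the point set, hence not volume or minimum required speed.
    """

    T: int = 12
    d: int = 3
    scale: float = 1.0
    step: float = 1.0
    order_mode: str = "sorted"
    seed: int = 0
    curvature: float = 0.12  # rad-scale direction perturbation per step

    def __post_init__(self):
        if self.T < 3:
            raise ValueError("T must be >= 3")
        if self.scale <= 0 or self.step <= 0:
            raise ValueError("scale and step must be > 0")
        if self.order_mode not in ("sorted", "shuffled"):
            raise ValueError(f"unknown order_mode {self.order_mode!r}")


def generate_planted_path(spec: PlantedPathSpec) -> SemanticPath:
    """Generate the planted path for *spec* (see :class:`PlantedPathSpec`)."""
    rng = np.random.default_rng(spec.seed)
    T, d = spec.T, spec.d
    u = rng.standard_normal(d)
    u /= np.linalg.norm(u)
    pts = np.zeros((T, d))
    for t in range(1, T):
        pts[t] = pts[t - 1] + spec.step * u
        g = rng.standard_normal(d)
        g -= (g @ u) * u  # perpendicular perturbation: gentle turning
        ng = np.linalg.norm(g)
        if ng > 0:
            u = u + spec.curvature * g / ng
            u /= np.linalg.norm(u)
    offset = rng.standard_normal(d)
    perm = rng.permutation(T - 2)  # drawn unconditionally: same stream for both modes
    pts = spec.scale * pts + offset
    if spec.order_mode == "shuffled" and T > 3:
        interior = perm + 1
        if np.array_equal(interior, np.arange(1, T - 1)):
            interior = np.roll(interior, 1)
        order = np.concatenate([[0], interior, [T - 1]])
        pts = pts[order]
    return SemanticPath(doc_id=f"planted-{spec.order_mode}-{spec.seed}", points=pts)


# ---------------------------------------------------------------------------
# Synthetic corpora
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticCorpusSpec:
    """Study design of a synthetic corpus.

    Defaults mirror the emulated study: two documents per author, ~550
    tokens per document (22 chunks of 25), an author-level outcome that is a
    linear function of standardized log-volume and log-speed plus unit
    Gaussian noise.
    """

    n_authors: int = 200
    docs_per_author: int = 2
    tokens_per_doc: int = 550
    chunk_size: int = 25
    dim: int = 50
    beta_volume: float = 0.15
    beta_speed: float = -0.05
    noise_sd: float = 1.0
    target_sd: float = 0.15   # author-level spread of planted log features
    doc_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if min(self.n_authors, self.docs_per_author, self.tokens_per_doc,
               self.chunk_size, self.dim) < 1:
            raise ValueError("all counts must be positive")


@dataclass
class SyntheticCorpus:
    """Documents plus ground truth for recovery tests.

    ``truth`` has one row per author: the outcome and the standardized
    measured log features it was built from.  ``store`` is the hash-based
    embedding store covering the corpus vocabulary.
    """

    documents: list[RawDocument]
    truth: pd.DataFrame
    store: EmbeddingStore
    spec: SyntheticCorpusSpec
    vocabulary: list[str] = field(default_factory=list)


def _doc_chunk_counts(
    n_chunks: int, chunk_size: int, p: float, q: float
) -> np.ndarray:
    """Per-chunk token counts over the document's concept words.

    Concept columns: one fresh "topic" word per chunk (columns 0..n_chunks-1,
    the volume carrier, token share ~p), then an alternating pair (columns
    n_chunks, n_chunks+1, the speed carrier, share ~q), then the anchor word
    (last column, the remainder).  The fresh words push the cloud apart in
    ~T-1 independent directions; the alternating pair adds ~sqrt(2)*q to
    *every* consecutive step while occupying only two of the cloud's axes,
    so it moves speed while barely moving the per-dimension volume.
    """
    n_u = max(1, min(chunk_size - 2, round(chunk_size * p)))
    n_z = max(0, min(chunk_size - 1 - n_u, round(chunk_size * q)))
    counts = np.zeros((n_chunks, n_chunks + 3), dtype=int)
    for t in range(n_chunks):
        counts[t, t] = n_u
        counts[t, n_chunks + (t % 2)] = n_z
        counts[t, -1] = chunk_size - n_u - n_z
    return counts


def _measure_doc(
    counts: np.ndarray, vectors: np.ndarray, chunk_size: int
) -> tuple[float, float]:
    """(speed, dim-root volume) of the chunk-mean path implied by counts."""
    pts = counts @ vectors / chunk_size
    sp = speed(pts)
    projected, _, _ = project_to_affine_subspace(pts)
    ell = mvee(projected)
    vol = math.exp(ell.log_volume / ell.d) if ell.d > 0 else 0.0
    return sp, vol


def generate_corpus(spec: SyntheticCorpusSpec) -> SyntheticCorpus:
    """Generate a corpus whose texts realize planted volume/speed targets.

    Each document is assembled from an artificial vocabulary: an anchor word
    shared by all its chunks, one fresh "topic" word per chunk whose token
    share p sets how far apart the chunk points sit (volume), and an
    alternating pair of words whose share q lengthens every consecutive step
    while occupying only two of the cloud's axes (speed).  Author-level
    targets for log-volume and log-speed are drawn independently and
    inverted through the (p, q) response — speed^2 ~ 2(p^2 + q^2) per-step,
    per-dimension volume ~ p — so the two planted features vary
    near-orthogonally across authors.

    The outcome is built from the features *measured on the generated
    texts* (identical code path to the pipeline): per-document log features
    are z-scored across the corpus, averaged per author, and combined as
    ``beta_volume * z_vol + beta_speed * z_speed + noise``.
    """
    rng = np.random.default_rng(spec.seed)
    n_chunks = max(2, round(spec.tokens_per_doc / spec.chunk_size))
    p0 = 0.35  # baseline token share of each carrier; speed baseline = 2*p0

    documents: list[RawDocument] = []
    vocab: list[str] = []
    doc_author: list[str] = []
    doc_speed: list[float] = []
    doc_vol: list[float] = []

    for a in range(spec.n_authors):
        author_id = f"a{a:05d}"
        dv, ds = rng.normal(0.0, spec.target_sd, size=2)
        for k in range(spec.docs_per_author):
            lv = dv + rng.normal(0.0, spec.doc_jitter_sd)
            ls = ds + rng.normal(0.0, spec.doc_jitter_sd)
            # invert the knob response: dim-root volume ~ p, and
            # speed^2 ~ 2 p^2 + 2 q^2 (orthogonal concept vectors)
            p = float(np.clip(p0 * math.exp(lv), 0.10, 0.60))
            target_speed = 2.0 * p0 * math.exp(ls)
            q_sq = target_speed**2 / 2.0 - p**2
            q = float(np.clip(math.sqrt(max(q_sq, (0.08 * p0) ** 2)), 0.0, 0.88 - p))
            doc_id = f"{author_id}d{k}"
            counts = _doc_chunk_counts(n_chunks, spec.chunk_size, p, q)
            # word order matches count columns: topic words, zig/zag pair, anchor
            words = (
                [f"c-{doc_id}-{j:03d}" for j in range(n_chunks)]
                + [f"zig-{doc_id}", f"zag-{doc_id}", f"anchor-{doc_id}"]
            )
            store_part = hash_embedding_store(words, d=spec.dim, seed=spec.seed)
            vectors = np.stack([store_part.get(wd) for wd in words])
            sp, vol = _measure_doc(counts, vectors, spec.chunk_size)
            tokens: list[str] = []
            for t in range(n_chunks):
                chunk_tokens = []
                for j in np.nonzero(counts[t])[0]:
                    chunk_tokens.extend([words[j]] * counts[t, j])
                rng.shuffle(chunk_tokens)  # order within a chunk is irrelevant to the mean
                tokens.extend(chunk_tokens)
            documents.append(
                RawDocument(doc_id=doc_id, author_id=author_id, text=" ".join(tokens))
            )
            vocab.extend(words)
            doc_author.append(author_id)
            doc_speed.append(sp)
            doc_vol.append(vol)

    per_doc = pd.DataFrame(
        {"author_id": doc_author, "log_vol": np.log(doc_vol), "log_speed": np.log(doc_speed)}
    )
    for col in ("log_vol", "log_speed"):
        per_doc["z_" + col] = (per_doc[col] - per_doc[col].mean()) / per_doc[col].std(ddof=1)
    per_author = per_doc.groupby("author_id", sort=True)[["z_log_vol", "z_log_speed"]].mean()
    noise = rng.normal(0.0, spec.noise_sd, size=len(per_author))
    outcome = (
        spec.beta_volume * per_author["z_log_vol"].to_numpy()
        + spec.beta_speed * per_author["z_log_speed"].to_numpy()
        + noise
    )
    truth = per_author.reset_index().rename(
        columns={"z_log_vol": "z_log_volume_true", "z_log_speed": "z_log_speed_true"}
    )
    truth["outcome"] = outcome
    store = hash_embedding_store(vocab, d=spec.dim, seed=spec.seed)
    return SyntheticCorpus(
        documents=documents, truth=truth, store=store, spec=spec, vocabulary=vocab
    )


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def brute_force_min_path(points) -> PathSolution:
    """Exhaustive fixed-endpoint shortest path (T <= 9).

    Enumerates all (T-2)! interior orders in lexicographic order and keeps
    the first strict minimum, so ties resolve to the lexicographically
    smallest order.  Oracle for the Held–Karp solver; refuses T > 9.
    """
    pts = points.points if isinstance(points, SemanticPath) else np.asarray(points, float)
    T = pts.shape[0]
    if T < 2:
        raise ValueError("need at least 2 points")
    if T > 9:
        raise ValueError(f"brute force refuses T = {T} > 9")
    if T == 2:
        return PathSolution((0, 1), float(np.linalg.norm(pts[1] - pts[0])), "trivial")
    best_order: tuple[int, ...] | None = None
    best_len = math.inf
    for perm in itertools.permutations(range(1, T - 1)):
        order = (0,) + perm + (T - 1,)
        length = path_length(pts, order)
        if length < best_len:
            best_len = length
            best_order = order
    assert best_order is not None
    return PathSolution(best_order, best_len, "exact")


@dataclass
class MVEEOptimalityReport:
    """Outcome of the John-condition check for a claimed MVEE."""

    passed: bool
    containment_ok: bool
    support_ok: bool
    max_mahalanobis: float
    n_boundary: int
    weight_residual: float

    def __bool__(self) -> bool:
        return self.passed


def verify_mvee_optimality(points, ell: Ellipsoid, tol: float = 1e-3) -> MVEEOptimalityReport:
    """Check John's optimality conditions for an enclosing ellipsoid.

    The minimum-volume enclosing ellipsoid is characterized by (i)
    containment of every point and (ii) nonnegative weights, supported on
    boundary points (Mahalanobis value >= 1 - tol), that reproduce the
    center and, through the weighted scatter, the shape matrix.  The weight
    system is linear in the weights and solved by nonnegative least squares;
    the report fails when no such weights exist (e.g. for an inflated
    ellipsoid with no boundary contact) or containment is violated (a
    shrunken one).
    """
    pts = points.points if isinstance(points, SemanticPath) else np.asarray(points, float)
    d = ell.d
    m = ell.mahalanobis(pts)
    containment_ok = bool(m.max() <= 1.0 + tol)
    boundary = np.where(m >= 1.0 - tol)[0]
    if boundary.size == 0:
        return MVEEOptimalityReport(
            passed=False, containment_ok=containment_ok, support_ok=False,
            max_mahalanobis=float(m.max()), n_boundary=0, weight_residual=math.inf,
        )
    S = pts[boundary]
    target_scatter = np.linalg.inv(ell.shape) / d + np.outer(ell.center, ell.center)
    iu = np.triu_indices(d)
    # linear system in the weights u: sum u = 1, sum u x = c,
    # sum u x x^T = inv(dA) + c c^T   (upper triangle)
    rows = [np.ones(S.shape[0]), *S.T]
    rhs = [1.0, *ell.center]
    outer = np.einsum("ni,nj->nij", S, S)
    for i, j in zip(*iu):
        rows.append(outer[:, i, j])
        rhs.append(target_scatter[i, j])
    G = np.vstack(rows)
    h = np.asarray(rhs)
    scale = max(1.0, float(np.abs(h).max()))
    u, residual = nnls(G / scale, h / scale)
    support_ok = bool(residual <= tol)
    return MVEEOptimalityReport(
        passed=containment_ok and support_ok,
        containment_ok=containment_ok,
        support_ok=support_ok,
        max_mahalanobis=float(m.max()),
        n_boundary=int(boundary.size),
        weight_residual=float(residual),
    )
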