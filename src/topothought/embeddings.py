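"""Word-vector stores and document semantic paths.

A document's chunks are mapped to points in embedding space: each chunk becomes
the unweighted mean of its in-vocabulary token vectors, and the ordered chunk
points form the document's semantic path {x_1, ..., x_T}.  Chunks with no
in-vocabulary token are dropped (counted, never silently).

The store reads the word2vec interchange convention: a header line ``V D``
followed by one entry per word, either space-delimited text or the binary
layout (word, space, D little-endian float32 values).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .textproc import ChunkSequence

__all__ = [
    "EmbeddingStore",
    "SemanticPath",
    "load_word_vectors",
    "save_word_vectors",
    "embed_chunk",
    "embed_document",
    "FLAG_TOO_SHORT_FOR_SPEED",
    "FLAG_TOO_SHORT_FOR_CIRCUITOUSNESS",
    "FLAG_EMPTY",
]

logger = logging.getLogger(__name__)

# Document flags (reason codes); flagged documents are reported, not dropped.
FLAG_EMPTY = "empty_document"
FLAG_TOO_SHORT_FOR_SPEED = "too_short_for_speed"  # T < 2
FLAG_TOO_SHORT_FOR_CIRCUITOUSNESS = "too_short_for_circuitousness"  # T < 3


class EmbeddingStore:
    """Token -> D-vector lookup with a fixed dimension.

    Lookup of an absent token returns ``None`` (distinct from a zero vector).
    """

    def __init__(self, vectors: Mapping[str, np.ndarray], dim: int | None = None):
        self._table: dict[str, np.ndarray] = {}
        self.dim = dim
        for word, vec in vectors.items():
            v = np.asarray(vec, dtype=float)
            if v.ndim != 1:
                raise ValueError(f"vector for {word!r} is not 1-d")
            if self.dim is None:
                self.dim = v.shape[0]
            elif v.shape[0] != self.dim:
                raise ValueError(
                    f"vector for {word!r} has length {v.shape[0]}, expected {self.dim}"
                )
            self._table[word] = v
        if self.dim is None:
            raise ValueError("cannot build an EmbeddingStore with no vectors and no dim")

    def __contains__(self, token: str) -> bool:
        return token in self._table

    def __len__(self) -> int:
        return len(self._table)

    def get(self, token: str) -> np.ndarray | None:
        """Vector for *token*, or ``None`` when out of vocabulary."""
        return self._table.get(token)

    @property
    def vocabulary(self) -> list[str]:
        return list(self._table)

    def items(self):
        return self._table.items()


@dataclass
class SemanticPath:
    """Ordered points of one document in embedding space.

    ``points`` has shape (T, D); point order equals chunk order.  ``flags``
    carries reason codes for paths too short for downstream features.
    """

    doc_id: str
    points: np.ndarray
    dropped_chunks: int = 0
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def T(self) -> int:
        return int(self.points.shape[0])


def _parse_header(line: bytes) -> tuple[int, int]:
    try:
        v_str, d_str = line.split()
        vocab_size, dim = int(v_str), int(d_str)
    except ValueError as exc:
        raise ValueError(f"malformed word2vec header {line!r}") from exc
    if vocab_size < 0 or dim < 1:
        raise ValueError(f"malformed word2vec header {line!r}")
    return vocab_size, dim


def _load_text(path: Path) -> dict[str, np.ndarray]:
    with open(path, "rb") as fh:
        vocab_size, dim = _parse_header(fh.readline())
        table: dict[str, np.ndarray] = {}
        for lineno in range(vocab_size):
            line = fh.readline()
            if not line:
                raise ValueError(f"{path.name}: expected {vocab_size} entries, got {lineno}")
            parts = line.rstrip(b"\n").split(b" ")
            word = parts[0].decode("utf-8")
            values = [p for p in parts[1:] if p]
            if len(values) != dim:
                raise ValueError(
                    f"{path.name}: entry {word!r} has {len(values)} values, expected {dim}"
                )
            vec = np.array([float(v) for v in values], dtype=float)
            if word in table:
                logger.warning("duplicate word %r in %s; first vector retained", word, path.name)
                continue
            table[word] = vec
    return table


def _load_binary(path: Path) -> dict[str, np.ndarray]:
    with open(path, "rb") as fh:
        vocab_size, dim = _parse_header(fh.readline())
        table: dict[str, np.ndarray] = {}
        width = 4 * dim
        for _ in range(vocab_size):
            word_bytes = bytearray()
            while True:
                ch = fh.read(1)
                if not ch:
                    raise ValueError(f"{path.name}: truncated binary entry")
                if ch == b" ":
                    break
                if ch != b"\n":  # some writers pad entries with newlines
                    word_bytes.extend(ch)
            buf = fh.read(width)
            if len(buf) != width:
                raise ValueError(f"{path.name}: truncated vector for {word_bytes!r}")
            word = word_bytes.decode("utf-8")
            vec = np.array(struct.unpack(f"<{dim}f", buf), dtype=float)
            if word in table:
                logger.warning("duplicate word %r in %s; first vector retained", word, path.name)
                continue
            table[word] = vec
    return table


def load_word_vectors(path: str | Path, fmt: str = "text") -> EmbeddingStore:
    """Read a word2vec-format vector file into an :class:`EmbeddingStore`.

    ``fmt`` is ``"text"`` or ``"binary"``.  Duplicate words keep the first
    vector (with a logged warning); inconsistent vector lengths raise.
    """
    path = Path(path)
    if fmt == "text":
        table = _load_text(path)
    elif fmt == "binary":
        table = _load_binary(path)
    else:
        raise ValueError(f"unknown embeddings format {fmt!r}")
    return EmbeddingStore(table)


def save_word_vectors(store: EmbeddingStore, path: str | Path, fmt: str = "text") -> None:
    """Write a store in word2vec text or binary format (for synthetic stores)."""
    path = Path(path)
    items = list(store.items())
    if fmt == "text":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"{len(items)} {store.dim}\n")
            for word, vec in items:
                fh.write(word + " " + " ".join(repr(float(v)) for v in vec) + "\n")
    elif fmt == "binary":
        with open(path, "wb") as fh:
            fh.write(f"{len(items)} {store.dim}\n".encode())
            for word, vec in items:
                fh.write(word.encode("utf-8") + b" ")
                fh.write(struct.pack(f"<{store.dim}f", *np.asarray(vec, dtype=np.float32)))
    else:
        raise ValueError(f"unknown embeddings format {fmt!r}")


def embed_chunk(
    chunk: Sequence[str],
    store: EmbeddingStore,
    unit_norm: bool = False,
    token_weights: Mapping[str, float] | None = None,
) -> np.ndarray | None:
    """Mean vector of the chunk's in-vocabulary tokens; ``None`` if all OOV.

    ``unit_norm=True`` normalizes each token vector to unit length before
    averaging.  ``token_weights`` switches to a weighted mean (tokens absent
    from the mapping weigh 1; zero total weight counts as an empty chunk).
    """
    pairs = [(tok, v) for tok, v in ((t, store.get(t)) for t in chunk) if v is not None]
    if not pairs:
        return None
    arr = np.stack([v for _, v in pairs])
    if unit_norm:
        norms = np.linalg.norm(arr, axis=1, keepdims=True)
        keep = norms[:, 0] > 0
        pairs = [p for p, k in zip(pairs, keep) if k]
        arr = arr[keep] / norms[keep]
        if arr.shape[0] == 0:
            return None
    if token_weights is None:
        return arr.mean(axis=0)
    w = np.array([float(token_weights.get(tok, 1.0)) for tok, _ in pairs])
    total = w.sum()
    if total <= 0:
        return None
    return (w @ arr) / total


def embed_document(
    chunks: ChunkSequence,
    store: EmbeddingStore,
    unit_norm: bool = False,
    token_weights: Mapping[str, float] | None = None,
) -> SemanticPath:
    """Map a chunk sequence to its :class:`SemanticPath`.

    All-OOV chunks are dropped and counted; short paths are flagged (T < 2
    cannot support speed/volume, T < 3 makes circuitousness trivial), never
    raised, so whole corpora process to completion.
    """
    points = []
    dropped = 0
    for ch in chunks.chunks:
        vec = embed_chunk(ch, store, unit_norm=unit_norm, token_weights=token_weights)
        if vec is None:
            dropped += 1
        else:
            points.append(vec)
    pts = np.array(points, dtype=float).reshape(len(points), store.dim or 0)
    flags: list[str] = []
    if pts.shape[0] == 0:
        flags.append(FLAG_EMPTY)
    if pts.shape[0] < 2:
        flags.append(FLAG_TOO_SHORT_FOR_SPEED)
    if pts.shape[0] < 3:
        flags.append(FLAG_TOO_SHORT_FOR_CIRCUITOUSNESS)
    return SemanticPath(
        doc_id=chunks.doc_id, points=pts, dropped_chunks=dropped, flags=tuple(flags)
    )
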