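"""Tokenization, chunking, and corpus reading.

Documents are reduced to an ordered list of lowercase word tokens and then cut
into consecutive fixed-size chunks (default 25 tokens).  Each chunk later
becomes one point of the document's semantic path, so chunk boundaries — and in
particular the treatment of a short trailing remainder — directly shape the
trajectory geometry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "RawDocument",
    "ChunkSequence",
    "tokenize",
    "chunk_tokens",
    "chunk",
    "read_corpus",
    "DEFAULT_CHUNK_SIZE",
    "TOKEN_PATTERN",
]

DEFAULT_CHUNK_SIZE = 25

#: Maximal runs of letters/digits, allowing internal apostrophes and hyphens
#: ("state-of-the-art", "don't"); punctuation is discarded.  ``[^\W\d_]``-style
#: classes are avoided on purpose: digits are tokens too.
TOKEN_PATTERN = r"[^\W_]+(?:['’-][^\W_]+)*"

_TOKEN_RE = re.compile(TOKEN_PATTERN, re.UNICODE)

#: Reserved column names in corpus files; everything else is a covariate.
_CORE_COLUMNS = ("doc_id", "author_id", "text")


@dataclass(frozen=True)
class RawDocument:
    """One input document with its author and optional covariates."""

    doc_id: str
    author_id: str
    text: str
    covariates: Mapping[str, object] = field(default_factory=dict)


@dataclass(frozen=True)
class ChunkSequence:
    """Ordered token chunks for one document.

    Every token of the tokenized text appears in exactly one chunk, in the
    original order; all chunks except possibly the last have exactly
    ``chunk_size`` tokens (the last may be shorter or, when a short remainder
    was merged, longer).
    """

    doc_id: str
    chunks: tuple[tuple[str, ...], ...]
    chunk_size: int

    @property
    def n_tokens(self) -> int:
        return sum(len(c) for c in self.chunks)


def tokenize(
    text: str,
    pattern: str | None = None,
    stopwords: "frozenset[str] | set[str] | None" = None,
) -> list[str]:
    """Lowercase and split *text* into word tokens.

    Tokens are maximal runs of letters/digits with internal apostrophes or
    hyphens kept; everything else is discarded.  ``pattern`` overrides the
    default token regex; ``stopwords`` (already lowercased) are removed
    after tokenization (none are removed by default).
    """
    if not text:
        return []
    rx = _TOKEN_RE if pattern is None else re.compile(pattern, re.UNICODE)
    tokens = rx.findall(text.lower())
    if stopwords:
        tokens = [t for t in tokens if t not in stopwords]
    return tokens


def chunk_tokens(
    tokens: list[str],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    remainder: str = "merge",
) -> list[tuple[str, ...]]:
    """Cut *tokens* into consecutive non-overlapping chunks of ``chunk_size``.

    The trailing remainder of ``r`` tokens is handled by ``remainder``:

    - ``"merge"`` (default): a short remainder (r < chunk_size/2) is appended
      to the preceding chunk; r >= chunk_size/2 stands as its own chunk.  With
      no preceding chunk the remainder stands alone.
    - ``"keep"``: the remainder is always its own chunk.
    - ``"drop"``: a short remainder (r < chunk_size/2) is discarded entirely.
    """
    if chunk_size < 1:
        raise ValueError(f"chunk_size must be >= 1, got {chunk_size}")
    if remainder not in ("merge", "keep", "drop"):
        raise ValueError(f"unknown remainder rule {remainder!r}")
    n = len(tokens)
    chunks = [tuple(tokens[i : i + chunk_size]) for i in range(0, n, chunk_size)]
    if not chunks:
        return []
    r = len(chunks[-1])
    if r == chunk_size or remainder == "keep":
        return chunks
    if r >= chunk_size / 2:
        return chunks
    # short remainder
    if remainder == "drop":
        return chunks[:-1]
    if len(chunks) == 1:  # nothing to merge into
        return chunks
    tail = chunks.pop()
    chunks[-1] = chunks[-1] + tail
    return chunks


def chunk(
    doc: RawDocument,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    remainder: str = "merge",
    token_pattern: str | None = None,
    stopwords: "frozenset[str] | None" = None,
) -> ChunkSequence:
    """Tokenize a document and return its :class:`ChunkSequence`."""
    tokens = tokenize(doc.text, pattern=token_pattern, stopwords=stopwords)
    parts = chunk_tokens(tokens, chunk_size=chunk_size, remainder=remainder)
    return ChunkSequence(doc_id=doc.doc_id, chunks=tuple(parts), chunk_size=chunk_size)


def _records_to_documents(records: Iterable[Mapping[str, object]]) -> Iterator[RawDocument]:
    for i, rec in enumerate(records):
        missing = [c for c in _CORE_COLUMNS if c not in rec]
        if missing:
            raise ValueError(f"corpus record {i} is missing column(s) {missing}")
        cov = {k: v for k, v in rec.items() if k not in _CORE_COLUMNS}
        text = rec["text"]
        yield RawDocument(
            doc_id=str(rec["doc_id"]),
            author_id=str(rec["author_id"]),
            text="" if text is None or (isinstance(text, float) and pd.isna(text)) else str(text),
            covariates=cov,
        )


def read_corpus(path: str | Path, fmt: str | None = None) -> list[RawDocument]:
    """Read a corpus file into a list of :class:`RawDocument`.

    Supported formats: delimited text with a header row (``csv``/``tsv``,
    quoted fields, UTF-8) and record-per-line JSON (``jsonl``).  ``fmt`` is
    inferred from the file extension when not given.  Required columns:
    ``doc_id``, ``author_id``, ``text``; any other column is carried through
    as a covariate.
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = {".csv": "csv", ".tsv": "tsv", ".jsonl": "jsonl", ".ndjson": "jsonl"}.get(suffix)
        if fmt is None:
            raise ValueError(f"cannot infer corpus format from {path.name!r}; pass fmt=")
    if fmt == "jsonl":
        records = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line:
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path.name}:{lineno}: bad JSON record: {exc}") from exc
        frame_records = records
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", dtype={"doc_id": str, "author_id": str})
        frame_records = df.to_dict(orient="records")
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")
    docs = list(_records_to_documents(frame_records))
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise ValueError(f"duplicate doc_id {d.doc_id!r} in corpus")
        seen.add(d.doc_id)
    return docs
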