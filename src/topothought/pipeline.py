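"""Corpus-level orchestration.

Reads a corpus, computes per-document topography features, applies the
standard post-processing — natural-log transform of the positive features,
corpus-wide z-scoring, per-author averaging — and writes delimited feature
tables with a reproducibility header that serializes the full run
configuration.

Transform order (configurable via ``aggregate``): per-document features ->
log -> corpus standardization -> per-author mean of z-scores
(``mean_of_z``, default), or per-author mean of logs -> standardization
(``z_of_mean``).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import textproc
from .embeddings import EmbeddingStore, embed_document
from .textproc import RawDocument
from .topography import (
    DEFAULT_EXACT_MAX,
    DEFAULT_MVEE_TOL,
    DEFAULT_RANK_TOL,
    DEFAULT_RESTARTS,
    extract_features,
)

__all__ = [
    "RunConfig",
    "FEATURE_COLUMNS",
    "process_corpus",
    "log_standardize",
    "aggregate_by_author",
    "run_features",
    "write_table",
    "read_table",
]

logger = logging.getLogger(__name__)

#: Features that get log / z-scored variants downstream.
FEATURE_COLUMNS = ("speed", "norm_volume", "min_required_speed", "circuitousness")


@dataclass(frozen=True)
class RunConfig:
    """Every knob of a feature run; serialized into output headers."""

    chunk_size: int = textproc.DEFAULT_CHUNK_SIZE
    remainder: str = "merge"
    token_pattern: str | None = None
    stopword_file: str | None = None
    weight_file: str | None = None
    unit_norm: bool = False
    volume_mode: str = "dim_root"
    exact_max: int = DEFAULT_EXACT_MAX
    restarts: int = DEFAULT_RESTARTS
    seed: int = 42
    rank_tol: float = DEFAULT_RANK_TOL
    mvee_tol: float = DEFAULT_MVEE_TOL
    aggregate: str = "mean_of_z"
    compute_min_path: bool = True

    def to_header_lines(self) -> list[str]:
        return [
            f"# {f.name} = {getattr(self, f.name)!r}"
            for f in dataclasses.fields(self)
        ]

    @classmethod
    def from_mapping(cls, mapping: dict[str, str]) -> "RunConfig":
        """Build a config from flat key=value strings (config-file support)."""
        kwargs: dict[str, object] = {}
        for f in dataclasses.fields(cls):
            if f.name not in mapping:
                continue
            raw = mapping[f.name]
            if f.type in ("int",):
                kwargs[f.name] = int(raw)
            elif f.type in ("float",):
                kwargs[f.name] = float(raw)
            elif f.type in ("bool",):
                kwargs[f.name] = raw.lower() in ("1", "true", "yes")
            elif f.name in ("token_pattern", "stopword_file", "weight_file"):
                kwargs[f.name] = raw or None
            else:
                kwargs[f.name] = raw
        return cls(**kwargs)


def _load_stopwords(path: str | None) -> frozenset[str] | None:
    """One stopword per line, lowercased; blank lines and # comments skipped."""
    if path is None:
        return None
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        line = line.strip().lower()
        if line and not line.startswith("#"):
            words.add(line)
    return frozenset(words)


def _load_token_weights(path: str | None) -> dict[str, float] | None:
    """Token-weight file: ``token weight`` per line (e.g. inverse-frequency
    weights); tokens not listed weigh 1 in the chunk mean."""
    if path is None:
        return None
    weights: dict[str, float] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            token, value = line.split()
            weights[token] = float(value)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: expected 'token weight'") from exc
    return weights


def process_corpus(
    corpus: Iterable[RawDocument],
    store: EmbeddingStore,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-document feature table for a corpus.

    One row per input document, valid or flagged; flagged documents carry a
    reason code in the ``flag`` column and NaN features.  Per-document values
    do not depend on processing order.
    """
    config = config or RunConfig()
    stopwords = _load_stopwords(config.stopword_file)
    token_weights = _load_token_weights(config.weight_file)
    rows: list[dict[str, object]] = []
    n_flagged = 0
    n_dropped_chunks = 0
    for doc in corpus:
        chunks = textproc.chunk(
            doc,
            chunk_size=config.chunk_size,
            remainder=config.remainder,
            token_pattern=config.token_pattern,
            stopwords=stopwords,
        )
        path = embed_document(
            chunks, store, unit_norm=config.unit_norm, token_weights=token_weights
        )
        n_dropped_chunks += path.dropped_chunks
        row: dict[str, object] = {
            "doc_id": doc.doc_id,
            "author_id": doc.author_id,
            "n_tokens": chunks.n_tokens,
            "n_chunks": len(chunks.chunks),
            "dropped_chunks": path.dropped_chunks,
        }
        if path.T < 2:
            flag = path.flags[0] if path.flags else "too_short_for_speed"
            n_flagged += 1
            logger.info("document %s flagged: %s", doc.doc_id, flag)
            row.update(
                T=path.T, d=np.nan, speed=np.nan, raw_volume=np.nan,
                norm_volume=np.nan, min_required_speed=np.nan,
                circuitousness=np.nan, solver="", flag=flag,
            )
        else:
            feats = extract_features(
                path,
                volume_mode=config.volume_mode,
                exact_max=config.exact_max,
                restarts=config.restarts,
                seed=config.seed,
                rank_tol=config.rank_tol,
                mvee_tol=config.mvee_tol,
                compute_min_path=config.compute_min_path,
            )
            # a path whose chunks coincide has zero speed/volume; its logs are
            # undefined, so it is flagged out of the standardization
            degenerate = feats.speed <= 0.0 or feats.norm_volume <= 0.0
            if degenerate:
                n_flagged += 1
                logger.info("document %s flagged: degenerate_path", doc.doc_id)
            row.update(
                T=feats.T, d=feats.d, speed=feats.speed,
                raw_volume=feats.raw_volume, norm_volume=feats.norm_volume,
                min_required_speed=feats.min_required_speed,
                circuitousness=feats.circuitousness, solver=feats.solver,
                flag="degenerate_path" if degenerate else "",
            )
        for name, value in doc.covariates.items():
            row[name] = value
        rows.append(row)
    logger.info(
        "processed %d documents (%d flagged, %d all-OOV chunks dropped)",
        len(rows), n_flagged, n_dropped_chunks,
    )
    return pd.DataFrame(rows)


def log_standardize(
    table: pd.DataFrame, columns: Sequence[str] = FEATURE_COLUMNS
) -> pd.DataFrame:
    """Add ``log_X`` and ``z_log_X`` columns for the selected features.

    z = (ln x - mean) / sd over non-flagged rows, sample sd (denominator
    n-1).  A zero-variance column standardizes to zeros with a warning.
    Nonpositive values in a non-flagged row indicate an upstream bug and
    raise.
    """
    out = table.copy()
    valid = out["flag"] == "" if "flag" in out.columns else pd.Series(True, index=out.index)
    for col in columns:
        if col not in out.columns:
            continue
        vals = out.loc[valid, col].astype(float)
        vals = vals[~vals.isna()]
        if (vals <= 0).any():
            bad = vals[vals <= 0].index.tolist()
            raise ValueError(
                f"nonpositive {col!r} reached log_standardize at rows {bad}; "
                "degenerate documents must be flagged upstream"
            )
        logs = np.log(out[col].astype(float).where(valid))
        out[f"log_{col}"] = logs
        mean = logs.mean()
        sd = logs.std(ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            logger.warning("column %s has zero variance; z-scores set to 0", col)
            out[f"z_log_{col}"] = np.where(logs.notna(), 0.0, np.nan)
        else:
            out[f"z_log_{col}"] = (logs - mean) / sd
    return out


def aggregate_by_author(table: pd.DataFrame) -> pd.DataFrame:
    """Per-author means of the per-document feature columns.

    Means are taken over each author's non-flagged documents; authors with no
    valid document get a flagged row.  All numeric feature columns present
    (raw, log, and z variants) are averaged.
    """
    valid = table[table["flag"] == ""] if "flag" in table.columns else table
    numeric = [
        c for c in table.columns
        if c not in ("doc_id", "author_id", "solver", "flag")
        and pd.api.types.is_numeric_dtype(table[c])
    ]
    n_docs = table.groupby("author_id", sort=True).size().rename("n_docs")
    n_valid = valid.groupby("author_id").size().rename("n_valid_docs")
    means = valid.groupby("author_id")[numeric].mean()
    out = pd.concat([n_docs, n_valid, means], axis=1).reset_index()
    out["n_valid_docs"] = out["n_valid_docs"].fillna(0).astype(int)
    out.insert(3, "flag", np.where(out["n_valid_docs"] == 0, "no_valid_documents", ""))
    return out


def write_table(table: pd.DataFrame, path: str | Path, config: RunConfig | None = None) -> None:
    """Write a feature table as UTF-8 CSV with a ``#`` config header.

    Floats are written with ``repr`` round-trip precision,
    locale-independent; identical inputs produce byte-identical files.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config is not None:
            for line in config.to_header_lines():
                fh.write(line + "\n")
        table.to_csv(fh, index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_table`."""
    return pd.read_csv(path, comment="#")


def run_features(
    corpus: Iterable[RawDocument] | str | Path,
    store: EmbeddingStore,
    config: RunConfig | None = None,
    out: str | Path | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end feature run: documents -> (per-document, per-author) tables.

    With ``aggregate="mean_of_z"`` (default) documents are log-transformed and
    z-scored across the corpus before per-author averaging; ``"z_of_mean"``
    averages the logs per author first and standardizes across authors.
    When ``out`` is given, both tables are written (``out`` and
    ``out`` + ``.authors.csv``) with the config header.
    """
    config = config or RunConfig()
    if isinstance(corpus, (str, Path)):
        corpus = textproc.read_corpus(corpus)
    per_doc = process_corpus(corpus, store, config)
    feature_cols = [
        c for c in FEATURE_COLUMNS
        if c in per_doc.columns and not (config.compute_min_path is False and
                                         c in ("min_required_speed", "circuitousness"))
    ]
    if config.aggregate == "mean_of_z":
        per_doc = log_standardize(per_doc, feature_cols)
        per_author = aggregate_by_author(per_doc)
    elif config.aggregate == "z_of_mean":
        per_doc = log_standardize(per_doc, feature_cols)
        base = per_doc.drop(columns=[c for c in per_doc.columns if c.startswith("z_log_")])
        per_author = aggregate_by_author(base)
        # standardize the author-level mean logs
        for col in feature_cols:
            lcol = f"log_{col}"
            if lcol not in per_author.columns:
                continue
            vals = per_author.loc[per_author["flag"] == "", lcol]
            sd = vals.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                per_author[f"z_log_{col}"] = 0.0
            else:
                per_author[f"z_log_{col}"] = (per_author[lcol] - vals.mean()) / sd
    else:
        raise ValueError(f"unknown aggregate mode {config.aggregate!r}")
    if out is not None:
        out = Path(out)
        write_table(per_doc, out, config)
        write_table(per_author, out.with_suffix(out.suffix + ".authors.csv"), config)
    return per_doc, per_author
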