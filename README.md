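# topothought

Semantic-trajectory analytics for document corpora: measure how much
semantic ground a text covers and how it moves across that ground, then
relate those measures to an outcome.

Writing can be represented as a path through meaning space. Each document is
cut into consecutive 25-word chunks, each chunk is embedded as the mean of
its word vectors (word2vec-format embeddings, typically 300-d), and the
ordered chunk points `{x_1, …, x_T}` form the document's **semantic path**.
From that path the package computes, per document:

- **speed** — the average Euclidean distance between consecutive points,
  `(1/(T−1)) Σ_t ‖x_{t+1} − x_t‖`: how large the jumps between adjacent
  passages are;
- **volume** — the volume of the minimum-volume enclosing ellipsoid
  (Löwner–John ellipsoid) of the points, computed in the affine hull of the
  path (effective dimension `d ≤ T−1`) and reported as the per-dimension
  length scale `volume^(1/d)`: how much semantic ground the document covers;
- **minimum required speed** — the length of the shortest path that starts
  and ends at the document's actual endpoints and visits all its points (an
  open-path Traveling Salesperson optimum; Held–Karp exact up to 12 interior
  points, seeded 2-opt beyond), divided by `T−1`: the speed the content
  *forces*, given what it covers;
- **circuitousness** — `speed / minimum required speed` (≥ 1 with the exact
  solver): how suboptimally the content is ordered given what it covers.
  By construction `log(speed) = log(circuitousness) + log(min required speed)`.

Downstream, features are log-transformed, z-scored across the corpus,
averaged per author, and related to an outcome by standardized OLS (with
optional categorical fixed effects and pass-through covariates) or ridge
regression with cross-validated penalty.

The package is aimed at researchers in computational psycholinguistics and
behavioral text analytics who want these trajectory measures for their own
corpora; it ships a deterministic synthetic-data module so the whole
pipeline is testable without any pretrained embeddings or private text.

## Worked example

Generate a synthetic corpus with planted effects (volume +0.15, speed
−0.05 on a unit-noise outcome), extract features, and fit the association:

```
$ topothought synth corpus --n-authors 200 --seed 7 \
    --out-corpus corpus.csv --out-truth truth.csv --out-store vectors.txt
wrote 400 documents to corpus.csv
wrote 10000 vectors to vectors.txt

$ topothought features --corpus corpus.csv --embeddings vectors.txt \
    --out features.csv --seed 42 --restarts 2
wrote 400 document rows (0 flagged) to features.csv; 200 author rows to features.csv.authors.csv
```

`features.csv` holds one row per document — `T`, effective dimension `d`,
`speed`, `norm_volume`, `min_required_speed`, `circuitousness`, their logs
and corpus-standardized logs, a solver tag, and flags — under a `#` header
that serializes the full run configuration; `features.csv.authors.csv`
holds the per-author means. Joining the author table with the outcome and
regressing:

```
$ topothought regress --features merged.csv --outcome outcome \
    --predictors z_log_norm_volume,z_log_speed
method: ols   n = 200   parameters = 3
R^2 = 0.028620   adjusted R^2 = 0.018759
                       coef        se         t         p
z_log_norm_volume  0.129130  0.070661  1.827463  0.069143
z_log_speed       -0.124641  0.070661 -1.763931  0.079294
```

Both standardized coefficients land near their planted values (+0.15 and
−0.05) within one to two standard errors at this small corpus size:
authors who cover more ground score higher, authors who move faster score
lower. `--ridge` refits with a cross-validated ridge penalty as a
multicollinearity check.

The same operations are available as a library
(`topothought.extract_features`, `run_features`, `fit_standardized_ols`,
`decompose_speed_effect`, …) for use on real corpora: any delimited or
JSON-lines file with `doc_id`, `author_id`, `text` columns plus a word2vec
text/binary vector file.

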