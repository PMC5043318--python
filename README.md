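# songreg

Temporal-regularity analysis of animal vocal sequence performances.

A *performance* is an uninterrupted, ordered sequence of song phrases; each
phrase has a categorical type and carries a set of *motifs* (note groups that
may be shared across phrase types). `songreg` quantifies how regularly phrase
types and shared motifs recur, and how strongly a performer's phrase syntax
is optimized for motif regularity:

- **Regularity statistic (CV\*)** — recurrence intervals of every unit type
  (phrase type or motif) are counted in whole phrases, mean-normalized per
  unit, pooled, and summarized as the pooled coefficient of variation.
  Low CV\* = high temporal regularity.
- **Null / synthesis models** — a *shuffled* null (random phrase order), a
  *bigram Markov* model estimated from the observed phrase order, and
  *permuted Markov* models that relabel which phrase type sits on which
  transition role (phrase-level statistics are preserved; motif-level ones
  change).
- **Rank / effort estimate** — the bird's mean synthetic motif CV\* is
  ranked among 100 permuted-model means; `rank / 100` is a direct
  probability estimate of how optimized the observed syntax is.
- **Complexity** — number of nonzero entries in the bigram transition
  matrix (a minimal-description-length proxy).
- **Acoustic front end** — phrase segmentation by long pauses, syllable
  onset detection from the smoothed envelope derivative, binarization into
  1000 Hz point processes, Gaussian spike-train similarity, and
  modularity-based clustering into phrase types.
- **Synthetic data** — a seeded generator for motif-sharing inventories,
  irreducible transition matrices of controllable sparsity, label
  assignments optimized (or not) for motif regularity, and tone-burst audio
  renderings with ground-truth onsets.
- **Cohort statistics** — paired t-tests, a one-sided sign test on ranks,
  and Pearson correlations, plus an end-to-end pipeline runner.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the slower end-to-end statistical criteria
(several minutes); the rest of the suite runs in seconds.

## Command line

```sh
songreg simulate   --config gen.yaml --out outdir --audio   # synthetic bird (+WAV)
songreg detect     --audio song.wav --out onsets.tsv        # segment + onsets
songreg cluster    --onsets onsets.tsv --out types.tsv      # phrase types
songreg regularity --table perf.csv --level both            # CV* + shuffled null
songreg rank       --table perf.csv --n-perm 100            # permuted-Markov rank
songreg report     --config run.yaml --out outdir           # full cohort pipeline
songreg raster     --table perf.csv --out raster.png        # raster plot
```

Performance tables are UTF-8 delimited text with columns `index`,
`phrase_type`, `motifs` (";"-joined within the cell); `#` lines are
comments. A pipeline configuration is YAML with keys `seed`, `n_shuffles`,
`n_perm`, `n_reps`, `interval_mode`, `sd_mode` and one input source:
`groups` (synthetic generator settings), `performances` (table paths) or
`audio` (WAV paths).

## Library example

```python
from songreg import read_performance, extract_ipis, pooled_cv, rank_bird

perf = read_performance("bird01.csv")
cv_motif = pooled_cv(extract_ipis(perf, "motif")).cv_star
result = rank_bird(perf, n_perm=100, n_reps=100, seed=0)
print(cv_motif, result.rank, result.probability, result.complexity)
```
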