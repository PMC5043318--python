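"""End-to-end orchestration: per-bird analysis and cohort statistics.

A run is driven by a plain-text (YAML) configuration naming either
performance tables, audio recordings, or synthetic-generator groups.  Every
stochastic stage is seeded from the configuration, so a rerun with the same
configuration reproduces the same numbers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import markov, stats
from .clustering import build_similarity_matrix, cluster_phrases
from .datamodel import (
    MotifMap,
    Performance,
    PhraseRecord,
    TransitionMatrix,
    read_performance,
    write_performance,
)
from .frontend import detect_onsets, read_wav, segment_phrases, to_point_process
from .regularity import pooled_cv, extract_ipis, shuffled_null
from .synth import (
    GeneratorConfig,
    assign_labels,
    generate_performance,
    make_inventory,
    make_transition_matrix,
)

__all__ = [
    "BirdResult",
    "CohortResult",
    "analyze_performance",
    "simulate_bird",
    "performance_from_audio",
    "run_pipeline",
]


@dataclass
class BirdResult:
    """Per-bird regularity and rank summary."""

    bird_id: str
    n_phrases: int
    n_types: int
    cv_ph: float
    cv_ph_shuffled_mean: float
    cv_ph_shuffled_sd: float
    cv_m: float = float("nan")
    cv_m_shuffled_mean: float = float("nan")
    cv_m_shuffled_sd: float = float("nan")
    cv_synth_bird: float = float("nan")
    rank: float = float("nan")
    probability: float = float("nan")
    complexity: int = 0

    def as_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class CohortResult:
    """Cohort table plus the paired/sign/correlation test results."""

    birds: pd.DataFrame
    tests: dict[str, Any]


def analyze_performance(
    perf: Performance,
    n_shuffles: int = 100,
    n_perm: int = 100,
    n_reps: int = 100,
    seed: int | None = None,
    do_rank: bool = True,
    interval_mode: str = "positional",
    sd_mode: str = "population",
) -> BirdResult:
    """Observed and shuffled CV* at both levels, plus the rank estimate.

    Motif-level quantities are NaN when the performance carries no motif
    annotations; the rank is NaN when no motif is shared across types (or
    ``do_rank`` is false).
    """
    kw = dict(interval_mode=interval_mode, sd_mode=sd_mode)
    ss = np.random.SeedSequence(seed)
    s_shuf_ph, s_shuf_m, s_rank = ss.spawn(3)

    ph_sets = extract_ipis(perf, "phrase", interval_mode=interval_mode)
    cv_ph = pooled_cv(ph_sets, sd_mode=sd_mode).cv_star
    shuf_ph, shuf_ph_mean = shuffled_null(
        perf, "phrase", n_shuffles=n_shuffles,
        seed=int(s_shuf_ph.generate_state(1)[0]), **kw,
    )
    T = markov.estimate_bigram(perf) if len(perf) >= 2 else None

    res = BirdResult(
        bird_id=perf.bird_id,
        n_phrases=len(perf),
        n_types=len(perf.phrase_types()),
        cv_ph=cv_ph,
        cv_ph_shuffled_mean=shuf_ph_mean,
        cv_ph_shuffled_sd=float(np.std([s.cv_star for s in shuf_ph])),
        complexity=markov.kolmogorov_complexity(T) if T is not None else 0,
    )

    if perf.motif_alphabet():
        m_sets = extract_ipis(perf, "motif", interval_mode=interval_mode)
        if m_sets:
            res.cv_m = pooled_cv(m_sets, sd_mode=sd_mode).cv_star
            shuf_m, shuf_m_mean = shuffled_null(
                perf, "motif", n_shuffles=n_shuffles,
                seed=int(s_shuf_m.generate_state(1)[0]), **kw,
            )
            res.cv_m_shuffled_mean = shuf_m_mean
            res.cv_m_shuffled_sd = float(np.std([s.cv_star for s in shuf_m]))
        if do_rank:
            try:
                rk = markov.rank_bird(
                    perf, n_perm=n_perm, n_reps=n_reps, seed=s_rank,
                    interval_mode=interval_mode, sd_mode=sd_mode,
                )
            except ValueError:
                rk = None  # no shared motifs: rank undefined
            if rk is not None:
                res.cv_synth_bird = rk.cv_synth_bird
                res.rank = rk.rank
                res.probability = rk.probability
    return res


def simulate_bird(
    cfg: GeneratorConfig,
    bird_id: str = "synthetic",
    n_candidates: int = 100,
    assign_length: int | None = None,
    assign_reps: int = 10,
) -> tuple[Performance, TransitionMatrix, MotifMap]:
    """Build one synthetic bird: inventory, labeled matrix, performance."""
    templates, motif_map = make_inventory(cfg)
    T0 = make_transition_matrix(cfg)
    ss = np.random.SeedSequence(cfg.seed + 2)
    s_assign, s_gen = ss.spawn(2)
    perm = assign_labels(
        T0,
        motif_map,
        mode=cfg.optimization,
        n_candidates=n_candidates,
        seed=s_assign,
        length=assign_length or cfg.performance_length,
        n_reps=assign_reps,
    )
    T = markov.permute_labels(T0, perm)
    perf = generate_performance(
        T, motif_map, cfg.performance_length, seed=s_gen, bird_id=bird_id
    )
    return perf, T, motif_map


def performance_from_audio(
    path: str | Path,
    bird_id: str | None = None,
    sigma: float = 0.01,
    seed: int = 0,
    min_pause: float = 1.5,
    **onset_kwargs: Any,
) -> Performance:
    """Segment, detect onsets, cluster, and label a recording's phrases."""
    wave, sr = read_wav(path)
    segments = segment_phrases(wave, sr, min_pause=min_pause)
    if not segments:
        raise ValueError(f"{path}: no phrases found")
    trains = []
    for k, (s, e) in enumerate(segments, start=1):
        chunk = wave[int(s * sr) : int(e * sr)]
        onsets = detect_onsets(chunk, sr, **onset_kwargs)
        if len(onsets) == 0:
            raise ValueError(f"{path}: no onsets in segment {k}")
        trains.append(to_point_process(onsets, phrase_index=k))
    S = build_similarity_matrix(trains, sigma=sigma)
    assignment = cluster_phrases(S, seed=seed)
    records = [
        PhraseRecord(index=k + 1, phrase_type=f"C{assignment.labels[k]}")
        for k in range(len(trains))
    ]
    return Performance(
        bird_id=bird_id or Path(path).stem, phrases=records
    )


def _cohort_tests(df: pd.DataFrame, n_perm: int) -> dict[str, Any]:
    tests: dict[str, Any] = {}
    ok_m = df["cv_m"].notna() & df["cv_m_shuffled_mean"].notna()
    if ok_m.sum() >= 2:
        t, dfree, p = stats.paired_t_test(
            df.loc[ok_m, "cv_m"], df.loc[ok_m, "cv_m_shuffled_mean"]
        )
        tests["motif_shuffled_vs_observed_t"] = {"t": t, "df": dfree, "p": p}
    if len(df) >= 2:
        t, dfree, p = stats.paired_t_test(df["cv_ph"], df["cv_ph_shuffled_mean"])
        tests["phrase_shuffled_vs_observed_t"] = {"t": t, "df": dfree, "p": p}
    ranks = df["rank"].dropna()
    if len(ranks) >= 1:
        tests["rank_sign_test_p"] = stats.sign_test_below_median(ranks, n_perm)
        tests["mean_rank"] = float(ranks.mean())
        tests["sd_rank"] = float(ranks.std(ddof=1)) if len(ranks) > 1 else 0.0
    ok_r = df["rank"].notna() & df["cv_synth_bird"].notna()
    if ok_r.sum() >= 3:
        r, p, n = stats.pearson_correlation(
            df.loc[ok_r, "cv_synth_bird"], df.loc[ok_r, "rank"]
        )
        tests["corr_cv_synth_vs_rank"] = {"r": r, "p": p, "n": n}
        effort = n_perm + 1 - df.loc[ok_r, "rank"]
        if df.loc[ok_r, "complexity"].std() > 0 and effort.std() > 0:
            r, p, n = stats.pearson_correlation(df.loc[ok_r, "complexity"], effort)
            tests["corr_complexity_vs_effort"] = {"r": r, "p": p, "n": n}
    return tests


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            return yaml.safe_load(fh) or {}
    return dict(config)


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> CohortResult:
    """Run the full analysis described by a configuration.

    Configuration keys: ``seed``, ``n_shuffles``, ``n_perm``, ``n_reps``,
    ``interval_mode``, ``sd_mode``, and exactly one input source among
    ``groups`` (synthetic generator settings, each with ``n_birds``),
    ``performances`` (paths to performance tables) or ``audio`` (paths to
    WAV recordings).
    """
    cfg = _load_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    seed = int(cfg.get("seed", 0))
    n_shuffles = int(cfg.get("n_shuffles", 100))
    n_perm = int(cfg.get("n_perm", 100))
    n_reps = int(cfg.get("n_reps", 100))
    interval_mode = cfg.get("interval_mode", "positional")
    sd_mode = cfg.get("sd_mode", "population")

    rng = np.random.default_rng(seed)
    performances: list[tuple[str, Performance]] = []

    if "groups" in cfg:
        for group in cfg["groups"]:
            name = group.get("name", "group")
            n_birds = int(group["n_birds"])
            gen = dict(group.get("generator", {}))
            for b in range(n_birds):
                bird_seed = int(rng.integers(2**31))
                gcfg = GeneratorConfig(**{**gen, "seed": bird_seed})
                bird_id = f"{name}-{b + 1:02d}"
                perf, _, _ = simulate_bird(gcfg, bird_id=bird_id)
                performances.append((name, perf))
                write_performance(perf, out_dir / f"{bird_id}.csv")
    elif "performances" in cfg:
        for p in cfg["performances"]:
            performances.append(("tables", read_performance(p)))
    elif "audio" in cfg:
        for p in cfg["audio"]:
            performances.append(
                ("audio", performance_from_audio(p, seed=seed))
            )
    else:
        raise ValueError("config must name 'groups', 'performances' or 'audio'")

    rows = []
    for group_name, perf in performances:
        bird_seed = int(rng.integers(2**31))
        res = analyze_performance(
            perf,
            n_shuffles=n_shuffles,
            n_perm=n_perm,
            n_reps=n_reps,
            seed=bird_seed,
            interval_mode=interval_mode,
            sd_mode=sd_mode,
        )
        row = res.as_dict()
        row["group"] = group_name
        rows.append(row)

    df = pd.DataFrame(rows)
    tests = _cohort_tests(df, n_perm)

    df.to_csv(out_dir / "birds.tsv", sep="\t", index=False)
    summary = {
        "config": {
            "seed": seed,
            "n_shuffles": n_shuffles,
            "n_perm": n_perm,
            "n_reps": n_reps,
            "interval_mode": interval_mode,
            "sd_mode": sd_mode,
        },
        "n_birds": len(df),
        "tests": tests,
    }
    with open(out_dir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2)
    return CohortResult(birds=df, tests=tests)
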