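"""Synthetic performances, motif-sharing inventories and audio fixtures.

Everything downstream of field recordings is testable against this module:
it builds phrase-type inventories whose types share motifs to a controllable
degree, irreducible bigram transition matrices of controllable sparsity,
label assignments that are optimized (or anti-optimized) for motif
regularity, synthetic performances, and tone-burst audio renderings with
ground-truth onset tables for scoring the acoustic front end.

All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

from .datamodel import MotifMap, Performance, PhraseRecord, TransitionMatrix

__all__ = [
    "ConfigError",
    "PhraseTemplate",
    "GeneratorConfig",
    "make_inventory",
    "make_transition_matrix",
    "assign_labels",
    "generate_performance",
    "render_audio",
]

OptimizationMode = Literal["optimized", "random", "anti-optimized"]


class ConfigError(ValueError):
    """Generator configuration is infeasible or inconsistent."""


@dataclass(frozen=True)
class PhraseTemplate:
    """Stereotyped syllable-onset pattern of one phrase type."""

    phrase_type: str
    onset_times: tuple[float, ...]
    motifs: tuple[str, ...] = ()
    freqs: tuple[float, ...] = ()  # per-syllable tone frequency, Hz

    def __post_init__(self) -> None:
        t = np.asarray(self.onset_times, dtype=float)
        if len(t) == 0 or t[0] != 0.0:
            raise ValueError("first syllable onset must be at time 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("onset times must be strictly increasing")
        if t[-1] > 10.0:
            raise ValueError("phrase duration must not exceed 10 s")
        if self.freqs and len(self.freqs) != len(self.onset_times):
            raise ValueError("freqs must match onset_times in length")

    @property
    def duration(self) -> float:
        return float(self.onset_times[-1])


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-performance generator."""

    n_types: int = 5
    n_motifs: int = 6
    sharing_degree: float = 2.0
    density: float = 0.4
    performance_length: int = 200
    optimization: OptimizationMode = "random"
    jitter_sd: float = 0.005
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1:
            raise ConfigError("n_types must be >= 1")
        if self.n_motifs < 1:
            raise ConfigError("n_motifs must be >= 1")
        if self.performance_length < 2:
            raise ConfigError("performance_length must be >= 2")
        if not 0 < self.density <= 1:
            raise ConfigError("density must lie in (0, 1]")
        if self.density * self.n_types < 1:
            raise ConfigError(
                "density too low to give every phrase type an outgoing transition"
            )
        if self.sharing_degree < 1:
            raise ConfigError("sharing_degree must be >= 1")
        if self.sharing_degree > self.n_types:
            raise ConfigError("sharing_degree cannot exceed n_types")
        if self.optimization not in ("optimized", "random", "anti-optimized"):
            raise ConfigError(f"unknown optimization mode {self.optimization!r}")
        if self.jitter_sd < 0:
            raise ConfigError("jitter_sd must be nonnegative")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def type_labels(n: int) -> list[str]:
    """A, B, ... Z, then T27, T28, ..."""
    letters = string.ascii_uppercase
    return [letters[i] if i < 26 else f"T{i + 1}" for i in range(n)]


def make_inventory(
    cfg: GeneratorConfig,
) -> tuple[list[PhraseTemplate], MotifMap]:
    """Phrase-type templates plus a motif-sharing map.

    Each motif is assigned to ``k`` phrase types with ``E[k] =
    sharing_degree``; with ``sharing_degree == 1`` no motif is shared and,
    when ``n_motifs == n_types``, the assignment is a perfect matching (so
    motif-level statistics coincide exactly with phrase-level ones
    downstream).
    """
    rng = np.random.default_rng(cfg.seed)
    types = type_labels(cfg.n_types)
    motifs = [str(i + 1) for i in range(cfg.n_motifs)]

    mapping: dict[str, set[str]] = {t: set() for t in types}
    if cfg.sharing_degree == 1:
        hosts = list(rng.permutation(cfg.n_types))
        for j, m in enumerate(motifs):
            if j < cfg.n_types:
                mapping[types[hosts[j]]].add(m)
            else:
                mapping[types[int(rng.integers(cfg.n_types))]].add(m)
    else:
        p_extra = (cfg.sharing_degree - 1) / (cfg.n_types - 1)
        hosts_per_motif: list[np.ndarray] = []
        for m in motifs:
            k = 1 + int(rng.binomial(cfg.n_types - 1, p_extra))
            hosts_per_motif.append(rng.choice(cfg.n_types, size=k, replace=False))
        if not any(len(h) >= 2 for h in hosts_per_motif):
            # sharing_degree > 1 promises cross-type sharing; force one motif
            hosts_per_motif[0] = rng.choice(cfg.n_types, size=2, replace=False)
        for m, hosts in zip(motifs, hosts_per_motif):
            for t_idx in hosts:
                mapping[types[int(t_idx)]].add(m)

    from .clustering import spike_train_similarity

    templates: list[PhraseTemplate] = []
    patterns: list[np.ndarray] = []
    max_sim = 0.5  # keep onset patterns well separated across types
    for t in types:
        best: np.ndarray | None = None
        best_sim = np.inf
        for _ in range(200):
            n_syl = int(rng.integers(3, 9))
            gaps = rng.uniform(0.08, 0.35, size=n_syl - 1)
            onsets = np.concatenate([[0.0], np.cumsum(gaps)])
            sim = max(
                (spike_train_similarity(onsets, p, sigma=0.01) for p in patterns),
                default=0.0,
            )
            if sim < best_sim:
                best, best_sim = onsets, sim
            if sim < max_sim:
                break
        assert best is not None
        patterns.append(best)
        freqs = rng.uniform(600.0, 2800.0, size=len(best))
        templates.append(
            PhraseTemplate(
                phrase_type=t,
                onset_times=tuple(best),
                motifs=tuple(sorted(mapping[t])),
                freqs=tuple(freqs),
            )
        )
    return templates, MotifMap({t: frozenset(v) for t, v in mapping.items()})


def _stationary_distribution(probs: np.ndarray) -> np.ndarray:
    """Stationary distribution of an irreducible row-stochastic matrix."""
    n = probs.shape[0]
    a = np.vstack([probs.T - np.eye(n), np.ones(n)])
    b = np.concatenate([np.zeros(n), [1.0]])
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def make_transition_matrix(
    cfg: GeneratorConfig,
    states: Sequence[str] | None = None,
    allow_self_transitions: bool = False,
) -> TransitionMatrix:
    """Random irreducible row-stochastic bigram matrix of target density.

    The support is a random Hamiltonian cycle (guaranteeing a single
    recurrent class over all states) plus extra random entries up to
    ``round(density * n_types**2)`` nonzeros; probabilities within a row are
    Dirichlet(1) over its support.  Self-transitions are excluded by default:
    they make recurrence-interval distributions heavy-tailed (bursty), which
    real phrase sequences do not show.  Counts are filled in as scaled
    expected stationary bigram frequencies so that downstream
    token-frequency estimates approximate the stationary distribution.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    n = cfg.n_types
    states = list(states) if states is not None else type_labels(n)
    if len(states) != n:
        raise ConfigError("states must match n_types")

    target = int(round(cfg.density * n * n))
    if target < n:
        raise ConfigError(
            f"density {cfg.density} gives only {target} entries; need >= {n} "
            "for one outgoing edge per state"
        )
    support = np.zeros((n, n), dtype=bool)
    if n == 1:
        support[0, 0] = True
    else:
        cycle = rng.permutation(n)
        for a, b in zip(cycle, np.roll(cycle, -1)):
            support[a, b] = True
    off_diag = ~np.eye(n, dtype=bool).ravel()
    free_mask = ~support.ravel()
    if not allow_self_transitions and n > 1:
        free_mask &= off_diag
    free = np.flatnonzero(free_mask)
    extra = target - int(support.sum())
    if extra > 0:
        chosen = rng.choice(free, size=min(extra, len(free)), replace=False)
        support.ravel()[chosen] = True

    probs = np.zeros((n, n))
    for i in range(n):
        cols = np.flatnonzero(support[i])
        if len(cols) == 1:
            probs[i, cols] = 1.0
        else:
            probs[i, cols] = rng.dirichlet(np.ones(len(cols)))
    # a Dirichlet draw can in principle produce an exact 0; nudge support
    zero_on_support = support & (probs == 0)
    if np.any(zero_on_support):
        probs[zero_on_support] = 1e-9
        probs /= probs.sum(axis=1, keepdims=True)

    pi = _stationary_distribution(probs)
    expected = pi[:, None] * probs * 1000.0
    counts = np.where(support, np.ceil(expected).astype(np.int64), 0)
    counts[support & (counts == 0)] = 1
    return TransitionMatrix(states=states, counts=counts, probs=probs)


def generate_performance(
    T: TransitionMatrix,
    motif_map: MotifMap,
    length: int,
    seed: int | np.random.SeedSequence | None = None,
    bird_id: str = "synthetic",
) -> Performance:
    """Sample a performance of exactly ``length`` phrases from the chain.

    The initial phrase is drawn from the token-frequency distribution implied
    by the count matrix; dead-end states restart from the same distribution.
    Motif lists are filled in from ``motif_map``.
    """
    from .markov import simulate_states

    rng = np.random.default_rng(seed)
    seq = simulate_states(T, length, rng, n_seq=1)[0]
    records = [
        PhraseRecord(
            index=i + 1,
            phrase_type=T.states[s],
            motifs=tuple(sorted(motif_map[T.states[s]])),
        )
        for i, s in enumerate(seq)
    ]
    return Performance(bird_id=bird_id, phrases=records)


def assign_labels(
    T: TransitionMatrix,
    motif_map: MotifMap,
    mode: OptimizationMode = "random",
    n_candidates: int = 100,
    seed: int | None = None,
    length: int = 200,
    n_reps: int = 10,
) -> np.ndarray:
    """Choose a state permutation by its synthetic motif-level CV*.

    ``optimized`` returns, among ``n_candidates`` uniformly random
    permutations, the one minimizing the mean synthetic motif CV* of the
    relabeled matrix; ``anti-optimized`` the maximizer; ``random`` the first
    candidate unevaluated (so ``n_candidates=1`` makes all modes coincide).
    Candidates are scored with common random numbers to sharpen comparisons.
    """
    from .markov import cv_synth, permute_labels

    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    if len(motif_map) != T.n_states:
        raise ValueError("motif map domain must match the states of T")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_perm, seed_eval = ss.spawn(2)
    rng = np.random.default_rng(seed_perm)
    candidates = [rng.permutation(T.n_states) for _ in range(n_candidates)]
    if mode == "random" or n_candidates == 1:
        return candidates[0]
    scores = np.empty(n_candidates)
    for k, p in enumerate(candidates):
        scores[k], _ = cv_synth(
            permute_labels(T, p), motif_map, length, n_reps=n_reps, seed=seed_eval
        )
    if mode == "optimized":
        return candidates[int(np.argmin(scores))]
    if mode == "anti-optimized":
        return candidates[int(np.argmax(scores))]
    raise ValueError(f"unknown mode {mode!r}")


def render_audio(
    templates: Sequence[PhraseTemplate],
    perf: Performance,
    jitter_sd: float = 0.005,
    sample_rate: int = 44100,
    seed: int | None = None,
    gap_range: tuple[float, float] = (2.0, 3.0),
    syllable_duration: float = 0.08,
    ramp: float = 0.005,
    noise_sd: float = 0.0,
    amplitude: float = 0.8,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Tone-burst rendering of a performance with ground-truth onsets.

    Each syllable becomes a constant-frequency sinusoid burst with cosine
    on/off ramps; phrases are separated by silences drawn uniformly from
    ``gap_range`` (seconds).  Gaussian jitter of s.d. ``jitter_sd`` is added
    to every within-phrase onset; jitter large enough to reorder onsets is an
    error.  Returns the mono waveform and a table with columns
    ``phrase_index`` and ``onset_seconds`` (absolute times).
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    if not templates:
        raise ValueError("template list is empty; nothing to render")
    by_type = {t.phrase_type: t for t in templates}
    missing = [p.phrase_type for p in perf.phrases if p.phrase_type not in by_type]
    if missing:
        raise KeyError(f"no template for phrase type(s) {sorted(set(missing))}")

    rng = np.random.default_rng(seed)
    cursor = float(rng.uniform(*gap_range))  # leading silence
    events: list[tuple[int, float, float]] = []  # (phrase_index, time, freq)
    truth: list[tuple[int, float]] = []
    for rec in perf.phrases:
        tpl = by_type[rec.phrase_type]
        base = np.asarray(tpl.onset_times)
        onsets = base + rng.normal(0.0, jitter_sd, size=len(base))
        onsets -= onsets[0]  # phrase start defined by its first syllable
        if np.any(np.diff(onsets) <= 0):
            raise ValueError(
                f"jitter_sd={jitter_sd} reordered onsets in phrase {rec.index}"
            )
        freqs = tpl.freqs or tuple(
            600.0 + 200.0 * ((7 * i) % 11) for i in range(len(base))
        )
        for k, (t, f) in enumerate(zip(onsets, freqs)):
            events.append((rec.index, cursor + t, float(f)))
            truth.append((rec.index, cursor + float(t)))
        cursor += float(onsets[-1]) + syllable_duration + float(rng.uniform(*gap_range))

    total = int(np.ceil((cursor + 0.5) * sample_rate))
    wave = np.zeros(total)
    burst_n = int(round(syllable_duration * sample_rate))
    ramp_n = max(1, int(round(ramp * sample_rate)))
    env = np.ones(burst_n)
    r = 0.5 * (1 - np.cos(np.linspace(0, np.pi, ramp_n)))
    env[:ramp_n] = r
    env[-ramp_n:] = r[::-1]
    tt = np.arange(burst_n) / sample_rate
    for _, t0, f in events:
        i0 = int(round(t0 * sample_rate))
        burst = amplitude * env * np.sin(2 * np.pi * f * tt)
        wave[i0 : i0 + burst_n] += burst[: max(0, total - i0)]
    if noise_sd > 0:
        wave += rng.normal(0.0, noise_sd, size=total)

    table = pd.DataFrame(truth, columns=["phrase_index", "onset_seconds"])
    return wave, table
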