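"""Pooled normalized-interval regularity statistics.

For every unit type (a phrase type, or a motif that may recur across phrase
types) we collect the recurrence intervals measured in whole phrases: the
positional difference between consecutive occurrences (a strictly periodic
ABCD... performance therefore yields intervals of 4 for every type).  Each
unit's intervals are divided by their own mean, the normalized values of all
units are pooled, and the pooled coefficient of variation (population
s.d. / mean; the pooled mean is 1 by construction) is the scalar regularity
score CV*.  Low CV* means high temporal regularity.

The shuffled null permutes whole phrases (type and motifs move together) and
recomputes CV* per replicate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .datamodel import Performance

__all__ = [
    "IntervalSet",
    "PooledIntervalSet",
    "RegularityScore",
    "extract_ipis",
    "normalize_ipis",
    "pool_normalized",
    "pooled_cv",
    "shuffled_null",
    "occurrence_positions",
]

Level = Literal["phrase", "motif"]
IntervalMode = Literal["positional", "exclusive"]
SdMode = Literal["population", "sample"]


@dataclass(frozen=True)
class IntervalSet:
    """Recurrence intervals (in phrases) of one unit type."""

    unit_label: str
    level: Level
    intervals: tuple[int, ...]

    def __post_init__(self) -> None:
        # positional intervals are always >= 1; the exclusive convention can
        # legally produce 0 for adjacent occurrences
        if any(i < 0 for i in self.intervals):
            raise ValueError(
                f"intervals must be nonnegative (unit {self.unit_label!r})"
            )
        object.__setattr__(self, "intervals", tuple(int(i) for i in self.intervals))

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass(frozen=True)
class PooledIntervalSet:
    """Mean-normalized intervals pooled over unit types."""

    values: tuple[float, ...]
    contributing_units: tuple[str, ...]


@dataclass(frozen=True)
class RegularityScore:
    """Scalar CV* with level and provenance tags."""

    cv_star: float
    level: Level
    provenance: str
    n_units: int
    n_intervals: int

    def __post_init__(self) -> None:
        if self.cv_star < 0:
            raise ValueError("cv_star must be nonnegative")


def occurrence_positions(perf: Performance, level: Level) -> dict[str, np.ndarray]:
    """1-based occurrence positions of each unit type, in performance order.

    At the motif level a motif appearing several times within one phrase
    still counts once for that phrase: intervals are whole-phrase counts.
    """
    out: dict[str, list[int]] = {}
    if level == "phrase":
        for rec in perf.phrases:
            out.setdefault(rec.phrase_type, []).append(rec.index)
    elif level == "motif":
        for rec in perf.phrases:
            for m in dict.fromkeys(rec.motifs):
                out.setdefault(m, []).append(rec.index)
    else:
        raise ValueError(f"unknown level {level!r}")
    return {k: np.asarray(v, dtype=np.int64) for k, v in out.items()}


def _intervals_from_positions(
    pos: np.ndarray, interval_mode: IntervalMode
) -> np.ndarray:
    d = np.diff(pos)
    if interval_mode == "exclusive":
        d = d - 1
    elif interval_mode != "positional":
        raise ValueError(f"unknown interval_mode {interval_mode!r}")
    return d


def extract_ipis(
    perf: Performance,
    level: Level = "phrase",
    interval_mode: IntervalMode = "positional",
) -> list[IntervalSet]:
    """Per-unit recurrence intervals; units occurring once are dropped.

    ``interval_mode='positional'`` (default) measures the difference of
    occurrence positions; ``'exclusive'`` counts only the phrases strictly
    in between (positional minus one).
    """
    sets: list[IntervalSet] = []
    for label, pos in occurrence_positions(perf, level).items():
        if len(pos) < 2:
            continue
        d = _intervals_from_positions(pos, interval_mode)
        sets.append(IntervalSet(unit_label=label, level=level, intervals=tuple(d)))
    return sets


def normalize_ipis(s: IntervalSet) -> np.ndarray:
    """Divide each interval by the unit's mean interval (output mean is 1)."""
    if len(s) == 0:
        raise ValueError(f"cannot normalize empty interval set {s.unit_label!r}")
    vals = np.asarray(s.intervals, dtype=float)
    m = vals.mean()
    if m == 0:
        raise ValueError(
            f"zero mean interval for unit {s.unit_label!r}; cannot normalize"
        )
    return vals / m


def pool_normalized(
    sets: Sequence[IntervalSet], include_singletons: bool = True
) -> PooledIntervalSet:
    """Pool mean-normalized intervals across unit types.

    A unit with exactly one interval contributes the single value 1.0 unless
    ``include_singletons`` is false.
    """
    values: list[float] = []
    units: list[str] = []
    for s in sets:
        if len(s) == 0:
            continue
        if len(s) == 1 and not include_singletons:
            continue
        values.extend(normalize_ipis(s))
        units.append(s.unit_label)
    if not values:
        raise ValueError("no non-empty interval sets to pool")
    return PooledIntervalSet(values=tuple(values), contributing_units=tuple(units))


def _cv_of_pool(values: np.ndarray, sd_mode: SdMode) -> float:
    mean = values.mean()
    ddof = 0 if sd_mode == "population" else 1
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    if len(values) <= ddof:
        return 0.0
    return float(values.std(ddof=ddof) / mean)


def pooled_cv(
    sets: Sequence[IntervalSet],
    provenance: str = "observed",
    sd_mode: SdMode = "population",
    include_singletons: bool = True,
) -> RegularityScore:
    """Pooled CV* (s.d./mean of the pooled normalized intervals)."""
    pool = pool_normalized(sets, include_singletons=include_singletons)
    values = np.asarray(pool.values)
    level = sets[0].level if sets else "phrase"
    return RegularityScore(
        cv_star=_cv_of_pool(values, sd_mode),
        level=level,
        provenance=provenance,
        n_units=len(pool.contributing_units),
        n_intervals=len(values),
    )


def cv_star_from_position_lists(
    positions: Iterable[np.ndarray],
    interval_mode: IntervalMode = "positional",
    sd_mode: SdMode = "population",
    include_singletons: bool = True,
) -> float:
    """CV* straight from per-unit occurrence-position arrays.

    Fast path shared by the shuffled null and the Markov simulators; returns
    NaN when no unit recurs.
    """
    values: list[np.ndarray] = []
    for pos in positions:
        if len(pos) < 2:
            continue
        d = _intervals_from_positions(np.asarray(pos), interval_mode).astype(float)
        if len(d) == 1 and not include_singletons:
            continue
        values.append(d / d.mean())
    if not values:
        return float("nan")
    pooled = np.concatenate(values)
    return _cv_of_pool(pooled, sd_mode)


def shuffled_null(
    perf: Performance,
    level: Level = "phrase",
    n_shuffles: int = 100,
    seed: int | None = None,
    interval_mode: IntervalMode = "positional",
    sd_mode: SdMode = "population",
    include_singletons: bool = True,
) -> tuple[list[RegularityScore], float]:
    """CV* distribution under uniform random permutation of phrase order.

    Whole phrase records move as atomic units, so motif annotations ride
    along with their phrase.  Returns the per-replicate scores and their
    mean.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(perf)

    # unit membership as boolean rows over phrase positions (0-based)
    pos_map = occurrence_positions(perf, level)
    labels = list(pos_map)
    membership = np.zeros((len(labels), n), dtype=bool)
    for u, lab in enumerate(labels):
        membership[u, pos_map[lab] - 1] = True

    scores: list[RegularityScore] = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        shuffled = membership[:, perm]
        positions = [np.flatnonzero(row) for row in shuffled]
        n_units = sum(1 for p in positions if len(p) >= 2)
        n_intervals = sum(len(p) - 1 for p in positions if len(p) >= 2)
        cv = cv_star_from_position_lists(
            positions,
            interval_mode=interval_mode,
            sd_mode=sd_mode,
            include_singletons=include_singletons,
        )
        if np.isnan(cv):
            raise ValueError("no recurring unit in shuffled performance")
        scores.append(
            RegularityScore(
                cv_star=cv,
                level=level,
                provenance="shuffled",
                n_units=n_units,
                n_intervals=n_intervals,
            )
        )
    mean = float(np.mean([s.cv_star for s in scores]))
    return scores, mean
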