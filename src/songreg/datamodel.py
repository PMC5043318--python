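"""Core domain types for annotated singing performances.

A *performance* is an ordered sequence of phrases.  Each phrase carries a
categorical type label and an ordered list of the motif labels it contains.
Performances are serialized as UTF-8 delimited text with columns
``index`` (1-based integer), ``phrase_type`` (string) and ``motifs``
(within-cell ";"-joined list of strings).  Lines starting with ``#`` are
comments.

Transition matrices over phrase types keep both raw bigram counts and
row-normalized probabilities; rows whose type never transitions anywhere
(observed only as the final phrase, or never observed) are flagged as
dead ends and carry an all-zero probability row.
"""

from __future__ import annotations

import csv
import io
import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "FormatError",
    "ValidationError",
    "ConsistencyError",
    "PhraseRecord",
    "Performance",
    "TransitionMatrix",
    "MotifMap",
    "read_performance",
    "write_performance",
    "derive_motif_map",
    "read_transition_matrix",
    "write_transition_matrix",
]

MOTIF_DELIM = ";"
_ESC = "\\"


class FormatError(ValueError):
    """A file does not follow the performance-table format."""


class ValidationError(ValueError):
    """A structural invariant of a domain object is violated."""


class ConsistencyError(ValueError):
    """Records of the same phrase type disagree about motif content."""


# ---------------------------------------------------------------------------
# motif-cell escaping: motif labels may legally contain the within-cell
# delimiter; we backslash-escape it so the round trip is lossless.

def _escape_motif(label: str) -> str:
    return label.replace(_ESC, _ESC + _ESC).replace(MOTIF_DELIM, _ESC + MOTIF_DELIM)


def _split_motif_cell(cell: str) -> list[str]:
    if cell == "":
        return []
    out: list[str] = []
    cur: list[str] = []
    it = iter(cell)
    for ch in it:
        if ch == _ESC:
            nxt = next(it, "")
            cur.append(nxt)
        elif ch == MOTIF_DELIM:
            out.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
    out.append("".join(cur))
    return out


def _join_motif_cell(motifs: Sequence[str]) -> str:
    return MOTIF_DELIM.join(_escape_motif(m) for m in motifs)


@dataclass(frozen=True)
class PhraseRecord:
    """One row of a performance table: a phrase in performance order."""

    index: int
    phrase_type: str
    motifs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"phrase index must be >= 1, got {self.index}")
        if not self.phrase_type:
            raise ValidationError("phrase_type must be non-empty")
        if any(m == "" for m in self.motifs):
            raise ValidationError(
                f"empty motif label in phrase at index {self.index}"
            )
        object.__setattr__(self, "motifs", tuple(self.motifs))


@dataclass
class Performance:
    """An ordered, uninterrupted sequence of annotated phrases from one bird."""

    bird_id: str
    phrases: list[PhraseRecord]

    def __post_init__(self) -> None:
        if len(self.phrases) < 1:
            raise ValidationError("a performance must contain at least one phrase")
        for row, rec in enumerate(self.phrases, start=1):
            if rec.index != row:
                raise ValidationError(
                    f"non-consecutive phrase indices: expected {row} at row {row}, "
                    f"got {rec.index}"
                )

    def __len__(self) -> int:
        return len(self.phrases)

    def type_sequence(self) -> list[str]:
        return [p.phrase_type for p in self.phrases]

    def phrase_types(self) -> list[str]:
        """Distinct phrase types in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.phrases:
            seen.setdefault(p.phrase_type, None)
        return list(seen)

    def motif_alphabet(self) -> set[str]:
        out: set[str] = set()
        for p in self.phrases:
            out.update(p.motifs)
        return out


@dataclass
class MotifMap:
    """Mapping from phrase-type label to the set of motif labels it carries."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.mapping = {k: frozenset(v) for k, v in self.mapping.items()}

    def __getitem__(self, phrase_type: str) -> frozenset[str]:
        return self.mapping[phrase_type]

    def __contains__(self, phrase_type: str) -> bool:
        return phrase_type in self.mapping

    def __len__(self) -> int:
        return len(self.mapping)

    def motifs(self) -> list[str]:
        """All motif labels, sorted."""
        out: set[str] = set()
        for v in self.mapping.values():
            out.update(v)
        return sorted(out)

    def shared_motifs(self) -> list[str]:
        """Motifs carried by two or more phrase types, sorted."""
        count: dict[str, int] = {}
        for v in self.mapping.values():
            for m in v:
                count[m] = count.get(m, 0) + 1
        return sorted(m for m, c in count.items() if c >= 2)

    def types_carrying(self, motif: str) -> list[str]:
        return sorted(t for t, v in self.mapping.items() if motif in v)


@dataclass
class TransitionMatrix:
    """First-order (bigram) transition structure over phrase types."""

    states: list[str]
    counts: np.ndarray
    probs: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.states)
        if self.counts.shape != (n, n):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match {n} states"
            )
        if np.any(self.counts < 0):
            raise ValidationError("counts must be nonnegative")
        if self.probs is None:
            self.probs = _row_normalize(self.counts)
        else:
            self.probs = np.asarray(self.probs, dtype=float)
            if self.probs.shape != (n, n):
                raise ValidationError("probs shape does not match states")
            rowsum = self.probs.sum(axis=1)
            alive = ~self.dead_ends
            if np.any(np.abs(rowsum[alive] - 1.0) > 1e-12):
                raise ValidationError("live probability rows must sum to 1")
            if np.any((self.probs > 0) != (self.counts > 0)):
                raise ValidationError("probs and counts must share the zero pattern")

    @property
    def dead_ends(self) -> np.ndarray:
        """Boolean mask of rows with no observed outgoing transition."""
        return self.counts.sum(axis=1) == 0

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, label: str) -> int:
        return self.states.index(label)


def _row_normalize(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    rowsum = counts.sum(axis=1, keepdims=True)
    probs = np.zeros_like(counts)
    alive = rowsum[:, 0] > 0
    probs[alive] = counts[alive] / rowsum[alive]
    return probs


# ---------------------------------------------------------------------------
# performance table IO

_REQUIRED_COLUMNS = ("index", "phrase_type", "motifs")


def read_performance(
    path: str | os.PathLike,
    delimiter: str = ",",
    bird_id: str | None = None,
) -> Performance:
    """Read a performance table.

    Parameters
    ----------
    path:
        UTF-8 delimited text file with a header naming at least
        ``index``, ``phrase_type`` and ``motifs``.
    delimiter:
        Cell delimiter (default comma).
    bird_id:
        Identifier for the returned performance; defaults to the file stem.
    """
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        lines = [ln for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.reader(lines, delimiter=delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise FormatError(f"{path}: empty file") from None
    header = [h.strip() for h in header]
    missing = [c for c in _REQUIRED_COLUMNS if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    col = {c: header.index(c) for c in _REQUIRED_COLUMNS}

    records: list[PhraseRecord] = []
    for row_no, row in enumerate(reader, start=1):
        try:
            idx = int(row[col["index"]])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}: bad index at data row {row_no}") from exc
        ptype = row[col["phrase_type"]]
        motifs = _split_motif_cell(row[col["motifs"]])
        if idx != row_no:
            raise ValidationError(
                f"{path}: non-consecutive index at data row {row_no}: "
                f"expected {row_no}, got {idx}"
            )
        records.append(PhraseRecord(index=idx, phrase_type=ptype, motifs=tuple(motifs)))
    return Performance(bird_id=bird_id or path.stem, phrases=records)


def write_performance(
    perf: Performance, path: str | os.PathLike, delimiter: str = ","
) -> Path:
    """Write a performance table re-readable by :func:`read_performance`."""
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(_REQUIRED_COLUMNS)
        for rec in perf.phrases:
            writer.writerow([rec.index, rec.phrase_type, _join_motif_cell(rec.motifs)])
    return path


def derive_motif_map(perf: Performance) -> MotifMap:
    """Build the phrase-type -> motif-set mapping of a performance.

    Every record of a given phrase type must carry the same motif set;
    otherwise a :class:`ConsistencyError` lists the offending indices.
    """
    mapping: dict[str, frozenset[str]] = {}
    first_seen: dict[str, int] = {}
    for rec in perf.phrases:
        mset = frozenset(rec.motifs)
        if rec.phrase_type not in mapping:
            mapping[rec.phrase_type] = mset
            first_seen[rec.phrase_type] = rec.index
        elif mapping[rec.phrase_type] != mset:
            raise ConsistencyError(
                f"phrase type {rec.phrase_type!r} has motif set "
                f"{sorted(mapping[rec.phrase_type])} at index "
                f"{first_seen[rec.phrase_type]} but {sorted(mset)} at index {rec.index}"
            )
    return MotifMap(mapping)


# ---------------------------------------------------------------------------
# transition matrix IO: probability table with the states as header
# row/column, followed by a counts block.


def write_transition_matrix(T: TransitionMatrix, path: str | os.PathLike) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["# probabilities"])
        writer.writerow(["state"] + list(T.states))
        for i, s in enumerate(T.states):
            writer.writerow([s] + [repr(float(x)) for x in T.probs[i]])
        writer.writerow(["# counts"])
        writer.writerow(["state"] + list(T.states))
        for i, s in enumerate(T.states):
            writer.writerow([s] + [int(x) for x in T.counts[i]])
    return path


def read_transition_matrix(path: str | os.PathLike) -> TransitionMatrix:
    path = Path(path)
    with open(path, encoding="utf-8", newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    blocks: dict[str, list[list[str]]] = {}
    current: str | None = None
    for row in rows:
        if not row:
            continue
        if row[0].startswith("#"):
            current = row[0].lstrip("# ").strip()
            blocks[current] = []
        elif current is not None:
            blocks[current].append(row)
    if "probabilities" not in blocks or "counts" not in blocks:
        raise FormatError(f"{path}: expected 'probabilities' and 'counts' blocks")

    def parse(block: list[list[str]], cast):
        header = block[0][1:]
        mat = np.array([[cast(x) for x in r[1:]] for r in block[1:]])
        labels = [r[0] for r in block[1:]]
        if labels != header:
            raise FormatError(f"{path}: row labels do not match header")
        return header, mat

    states_p, probs = parse(blocks["probabilities"], float)
    states_c, counts = parse(blocks["counts"], int)
    if states_p != states_c:
        raise FormatError(f"{path}: state order differs between blocks")
    return TransitionMatrix(states=states_p, counts=counts, probs=probs)
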