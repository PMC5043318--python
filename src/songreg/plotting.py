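"""Minimal raster plots of performances (one row per phrase)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .datamodel import Performance

__all__ = ["raster_rows", "plot_raster"]

SortMode = Literal["performance-order", "by-type"]


def raster_rows(perf: Performance, sort: SortMode = "performance-order") -> list[str]:
    """Row order of the raster: phrase-type labels, optionally grouped by type."""
    types = perf.type_sequence()
    if sort == "performance-order":
        return types
    if sort == "by-type":
        order = {t: i for i, t in enumerate(perf.phrase_types())}
        return sorted(types, key=lambda t: order[t])
    raise ValueError(f"unknown sort mode {sort!r}")


def plot_raster(
    perf: Performance,
    path: str | Path,
    pitch_traces: Sequence[np.ndarray] | None = None,
    sort: SortMode = "performance-order",
) -> Path:
    """One row per phrase, first-onset aligned.

    With ``pitch_traces`` (one frequency vector per phrase, in performance
    order) rows are colored by pitch; otherwise each row is a solid bar
    colored by phrase type.
    """
    path = Path(path)
    n = len(perf)
    fig, ax = plt.subplots(figsize=(6, max(1.5, 0.08 * n)))

    if sort == "by-type":
        order = {t: i for i, t in enumerate(perf.phrase_types())}
        idx = sorted(range(n), key=lambda i: order[perf.phrases[i].phrase_type])
    else:
        idx = list(range(n))

    if pitch_traces is not None:
        if len(pitch_traces) != n:
            raise ValueError("need one pitch trace per phrase")
        width = max(len(np.atleast_1d(t)) for t in pitch_traces)
        img = np.full((n, width), np.nan)
        for row, i in enumerate(idx):
            tr = np.atleast_1d(pitch_traces[i])
            img[row, : len(tr)] = tr
        ax.imshow(img, aspect="auto", interpolation="nearest", cmap="viridis")
    else:
        types = perf.phrase_types()
        cmap = plt.get_cmap("tab20")
        color = {t: cmap(k % 20) for k, t in enumerate(types)}
        for row, i in enumerate(idx):
            ax.barh(row, 1.0, color=color[perf.phrases[i].phrase_type], height=0.9)
        ax.set_xlim(0, 1)
        ax.set_xticks([])
    ax.set_ylabel("phrase")
    ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
    return path
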