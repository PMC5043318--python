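from __future__ import annotations

import numpy as np
import pytest

from songreg.datamodel import Performance, PhraseRecord


def make_perf(seq, motif_types=(), bird_id="test", motif="i"):
    """Performance from a type-label string/list; ``motif`` rides on the
    listed types."""
    recs = [
        PhraseRecord(
            index=i + 1,
            phrase_type=t,
            motifs=(motif,) if t in motif_types else (),
        )
        for i, t in enumerate(seq)
    ]
    return Performance(bird_id=bird_id, phrases=recs)


def brute_pooled_cv(unit_positions):
    """Independent plain-Python pooled CV* oracle.

    ``unit_positions``: iterable of occurrence-position lists (1-based),
    one per unit type.  Positional intervals, per-unit mean normalization,
    population s.d. over the pooled values divided by the pooled mean.
    """
    normalized = []
    for ps in unit_positions:
        if len(ps) < 2:
            continue
        ds = [b - a for a, b in zip(ps, ps[1:])]
        m = sum(ds) / len(ds)
        normalized.extend(d / m for d in ds)
    if not normalized:
        raise ValueError("no recurring unit")
    mean = sum(normalized) / len(normalized)
    var = sum((x - mean) ** 2 for x in normalized) / len(normalized)
    return (var**0.5) / mean


def positions_of(seq, members):
    """1-based positions at which the phrase label belongs to ``members``."""
    return [i + 1 for i, t in enumerate(seq) if t in members]


@pytest.fixture
def periodic_perf():
    """ABCD repeated 25x plus a final A; motif shared by A and B.

    The 4k+1 length gives the shared motif equal counts of the alternating
    1- and 3-phrase intervals, the idealized stream behind the 0.5 value.
    """
    return make_perf("ABCD" * 25 + "A", motif_types="AB")


@pytest.fixture
def printed_perf():
    """The 12-phrase irregular example with a motif shared by A and B."""
    return make_perf("ACADBDADBCBD", motif_types="AB")


@pytest.fixture(scope="session")
def rendered_audio():
    """A 60-phrase, 5-type performance rendered as audio with ground truth."""
    from songreg import markov as mk
    from songreg.synth import (
        GeneratorConfig,
        generate_performance,
        make_inventory,
        make_transition_matrix,
    )
    from songreg.synth import render_audio

    sr = 22050
    cfg = GeneratorConfig(
        n_types=5, n_motifs=6, sharing_degree=2.0, density=0.4,
        performance_length=60, seed=3,
    )
    templates, motif_map = make_inventory(cfg)
    T = make_transition_matrix(cfg)
    perf = generate_performance(T, motif_map, 60, seed=7)
    wave, truth = render_audio(
        templates, perf, jitter_sd=0.002, sample_rate=sr, seed=5
    )
    return {
        "wave": wave,
        "sr": sr,
        "truth": truth,
        "perf": perf,
        "templates": templates,
    }
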