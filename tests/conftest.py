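"""Shared synthetic datasets, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from chromstate import simulate


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic genome with chromatin tracks and ground truth."""
    spec = simulate.SyntheticSpec(seed=11)
    ann, truth = simulate.generate_genome(spec)
    simulate.plant_enhancers(ann, truth, spec)
    tracks, input_track = simulate.simulate_chromatin(ann, truth, spec)
    pooled = {m: reps[0] + reps[1] for m, reps in tracks.items()}
    return {
        "spec": spec,
        "ann": ann,
        "truth": truth,
        "tracks": tracks,
        "pooled": pooled,
        "input": input_track,
    }


@pytest.fixture(scope="session")
def expression_dataset():
    spec = simulate.SyntheticSpec(seed=23)
    ann, truth = simulate.generate_genome(spec)
    expr = simulate.simulate_expression(ann, truth, spec)
    return {"spec": spec, "ann": ann, "truth": truth, "expr": expr}


def make_interval_case(rng: np.random.Generator, n: int = 200, size: int = 10_000):
    """Random interval set on a toy scaffold for oracle comparisons."""
    from chromstate.intervals import GenomicInterval, IntervalSet

    starts = rng.integers(0, size - 2, size=n)
    lengths = rng.integers(1, 400, size=n)
    ivs = [
        GenomicInterval("s", int(a), int(min(size, a + ln)))
        for a, ln in zip(starts, lengths)
    ]
    return IntervalSet(ivs)


def coverage_mask(intervals, size: int = 10_000) -> np.ndarray:
    mask = np.zeros(size, dtype=bool)
    for iv in intervals:
        mask[iv.start : min(size, iv.end)] = True
    return mask
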