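"""Shared fixtures.

The long AF runs (5000 analyzed beats at 50 and 130 bpm, and the scaled-down
500-beat sweep) are expensive, so they are computed once per session and
shared; each fixture returns the per-beat summary table plus the trace-level
conservation metric measured before the dense trace is released.
"""

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from afsim.rr import sample_rr
from afsim.model import simulate
from afsim.indices import aggregate, summarize
from afsim.sweep import SweepConfig, run_sweep

#: Seed for the long acceptance-grade runs.
LONG_RUN_SEED = 1234
LONG_RUN_BEATS = 5000


@dataclass
class AFRun:
    hr: float
    summary: pd.DataFrame
    agg: pd.DataFrame
    volume_drift: float
    n_non_ejecting: int


def _af_run(hr: float, beats: int, seed: int) -> AFRun:
    seq = sample_rr(beats, hr, cv=0.24, seed=seed)
    trace = simulate(seq)
    drift = trace.volume_drift
    df = summarize(trace)
    agg = aggregate(df)
    return AFRun(
        hr=hr,
        summary=df,
        agg=agg,
        volume_drift=drift,
        n_non_ejecting=agg.attrs.get("n_non_ejecting", 0),
    )


@pytest.fixture(scope="session")
def af_run_50() -> AFRun:
    return _af_run(50.0, LONG_RUN_BEATS, LONG_RUN_SEED)


@pytest.fixture(scope="session")
def af_run_130() -> AFRun:
    return _af_run(130.0, LONG_RUN_BEATS, LONG_RUN_SEED + 1)


@pytest.fixture(scope="session")
def sweep_500():
    """Scaled-down full sweep: 500 beats per HR at the five studied rates."""
    cfg = SweepConfig(beats_per_hr=500, seed=LONG_RUN_SEED)
    return run_sweep(cfg)


@pytest.fixture(scope="session")
def short_regular_trace():
    """A short regular-rhythm (cv=0) run at 70 bpm for morphology tests."""
    seq = sample_rr(60, 70, cv=0.0)
    return simulate(seq)
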