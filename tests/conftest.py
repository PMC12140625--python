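"""Shared fixtures and table-building helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from selhist import COLORS, LOCATIONS, GeneratorParams, TrialTable, generate


def make_table(colors, locations=None, correct=None, pts=None,
               sessions=None, gap=50):
    """Build a valid TrialTable from explicit per-trial values.

    ``colors``/``locations`` may be given as labels or indices; ``correct``
    decides the choice (the target itself, or the next location clockwise);
    ``pts`` sets processing times (rt = pt + gap); ``sessions`` is an
    optional parallel list of session ids (default: one session).
    """
    n = len(colors)
    colors = [c if isinstance(c, str) else COLORS[c] for c in colors]
    if locations is None:
        locations = ["right"] * n
    locations = [l if isinstance(l, str) else LOCATIONS[l] for l in locations]
    if correct is None:
        correct = [True] * n
    if pts is None:
        pts = [200.0] * n
    if sessions is None:
        sessions = ["s1"] * n
    choice = [loc if ok else LOCATIONS[(LOCATIONS.index(loc) + 1) % 4]
              for loc, ok in zip(locations, correct)]
    # trial_index restarts at each session change
    tix, counter, prev = [], 0, None
    for s in sessions:
        if s != prev:
            counter, prev = 0, s
        tix.append(counter)
        counter += 1
    df = pd.DataFrame({
        "session_id": sessions,
        "trial_index": tix,
        "gap_ms": gap,
        "rt_ms": [pt + gap for pt in pts],
        "pt_ms": pts,
        "target_color": colors,
        "target_location": locations,
        "choice_location": choice,
        "correct": correct,
    })
    return TrialTable(df, {"source": "test"})


@pytest.fixture(scope="session")
def unbiased_table():
    """10^5 trials with all bias gains zero (chance guessing, clean ramp)."""
    params = GeneratorParams.unbiased(n_trials_per_session=1000,
                                      n_sessions=100, seed=42)
    return generate(params)


@pytest.fixture(scope="session")
def biased_table():
    """10^5 trials from the default (outcome-gated) generator."""
    params = GeneratorParams(n_trials_per_session=1000, n_sessions=100,
                             seed=43)
    return generate(params)


@pytest.fixture(scope="session")
def small_biased_table():
    """2 x 10^4 trials from the default generator, for cheaper checks."""
    params = GeneratorParams(n_trials_per_session=500, n_sessions=40,
                             seed=44)
    return generate(params)
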