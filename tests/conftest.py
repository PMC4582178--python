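"""Shared fixtures and ground-truth matching helpers."""

from __future__ import annotations

from collections import defaultdict

import numpy as np
import pytest

from cortexnet import (
    EventTrain,
    KernelConfig,
    ScenarioConfig,
    generate_events,
    render_traces,
)


def match_events(true_pairs, detected_pairs, tol_s: float = 0.3):
    """Greedy per-cell matching of detected onsets to ground-truth times.

    Returns (n_matched, n_true, n_detected); recall = matched/true,
    precision = matched/detected.
    """
    t_by = defaultdict(list)
    d_by = defaultdict(list)
    for c, t in true_pairs:
        t_by[c].append(t)
    for c, t in detected_pairs:
        d_by[c].append(t)
    matched = 0
    for c in t_by:
        dd = sorted(d_by.get(c, []))
        used = [False] * len(dd)
        for t in sorted(t_by[c]):
            for i, d in enumerate(dd):
                if not used[i] and abs(d - t) <= tol_s:
                    used[i] = True
                    matched += 1
                    break
    return matched, len(true_pairs), len(detected_pairs)


def event_pairs(train: EventTrain):
    return [(c, t) for c, t, _ in train.all_events()]


def detected_pairs(table):
    return list(zip(table.events["cell_id"], table.events["onset_time_s"]))


@pytest.fixture(scope="session")
def noiseless_async():
    """Asynchronous 100-cell, 1000 s noiseless recording with ground truth."""
    config = ScenarioConfig("asynchronous", n_cells=100, duration_s=1000.0, seed=5)
    events = generate_events(config)
    traces = render_traces(events, KernelConfig(noise_sd=0.0), seed=6)
    return events, traces


@pytest.fixture(scope="session")
def synchronized_long():
    """Synchronized 0.18 Hz, 100-cell, 1000 s recording with ground truth."""
    config = ScenarioConfig(
        "synchronized",
        n_cells=100,
        duration_s=1000.0,
        burst_frequency_hz=0.18,
        participation_fraction=0.9,
        seed=1,
    )
    events = generate_events(config)
    traces = render_traces(events, KernelConfig(noise_sd=0.02), seed=2)
    return events, traces
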