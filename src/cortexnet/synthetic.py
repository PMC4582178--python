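"""Synthetic calcium-imaging data with known ground truth.

This module emulates the kinds of recordings made in developing cortical
cultures: spontaneous per-cell calcium transients, synchronised network
bursts, replayed activation-order motifs, and pharmacological blockade
regimes.  Every generator is seeded and returns ground-truth event times,
so detection, recurrence and fitting stages can all be validated against
known answers.

Scenarios
---------
``asynchronous``
    Independent homogeneous Poisson event trains per cell.
``synchronized``
    Network bursts at a target frequency; each burst recruits a random
    subset of cells within a short recruitment window, on top of sparse
    background events.
``complex_recurrent``
    A fixed activation-order motif replayed cyclically, optionally
    corrupted symbol-by-symbol with random cell IDs.
``ttx``
    Sodium-channel blockade: no events at all.
``cnqx_apv``
    Glutamatergic blockade: synchrony abolished, asynchronous events
    persist (identical to ``asynchronous``).
``gaba_agonist``
    GABA-A/GABA-B agonists: all activity suppressed (no events).
``bicuculline``
    GABA-A antagonist: no change relative to ``synchronized`` -- the
    output is bit-identical to the synchronized scenario for the same
    seed, reflecting a purely excitatory network.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .transients import TraceSet

__all__ = [
    "SCENARIOS",
    "DEGREE_MODELS",
    "ScenarioConfig",
    "KernelConfig",
    "EventTrain",
    "cell_labels",
    "generate_events",
    "render_traces",
    "generate_degree_sequence",
]

SCENARIOS = (
    "asynchronous",
    "synchronized",
    "complex_recurrent",
    "ttx",
    "cnqx_apv",
    "gaba_agonist",
    "bicuculline",
)

DEGREE_MODELS = ("poisson", "binomial", "powerlaw", "hub_mix")

#: Per-cell background event rates (Hz) used when ``baseline_rate_hz`` is
#: left unset.  Asynchronous regimes show a transient every tens of
#: seconds per cell; during strong synchrony, background activity between
#: bursts is sparse.
_DEFAULT_BASELINE_RATE = {
    "asynchronous": 0.02,
    "cnqx_apv": 0.02,
    "synchronized": 0.005,
    "bicuculline": 0.005,
    "complex_recurrent": 0.0,
    "ttx": 0.0,
    "gaba_agonist": 0.0,
}


def cell_labels(n_cells: int) -> list[str]:
    """Zero-padded cell IDs (``c000`` ...) whose lexicographic order matches
    numeric order, so tie-breaking on IDs is well defined."""
    width = max(3, len(str(max(n_cells - 1, 0))))
    return [f"c{i:0{width}d}" for i in range(n_cells)]


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one simulated recording.

    Parameters
    ----------
    scenario_name
        One of :data:`SCENARIOS`.
    n_cells
        Number of cells in the field of view (recordings typically sample
        50-100 cells).
    duration_s
        Recording length in seconds (2-minute recordings by default).
    burst_frequency_hz
        Expected network-burst rate for synchronized scenarios.  Observed
        values span ~5e-4 Hz in nascent networks up to 0.18 Hz at the
        synchrony peak.
    participation_fraction
        Probability that a given cell joins a given burst.
    baseline_rate_hz
        Per-cell background (asynchronous) event rate; ``None`` selects a
        per-scenario default.
    motif_length
        Number of distinct cells in the replayed activation-order motif
        (``complex_recurrent`` only).
    motif_noise
        Per-symbol probability of replacing a motif entry with a random
        cell ID (``complex_recurrent`` only).
    event_interval_s
        Spacing between successive motif events (``complex_recurrent``).
    recruitment_window_s
        Length of the window over which cells join a burst.
    burst_min_separation_s
        Hard minimum spacing between burst onsets (network refractoriness;
        bursts remain Poisson-timed subject to this dead time).
    seed
        Seed for the single random generator used by the call.
    """

    scenario_name: str
    n_cells: int = 100
    duration_s: float = 120.0
    burst_frequency_hz: float = 0.18
    participation_fraction: float = 0.9
    baseline_rate_hz: float | None = None
    motif_length: int = 10
    motif_noise: float = 0.0
    event_interval_s: float = 0.5
    recruitment_window_s: float = 0.5
    burst_min_separation_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_name not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario_name!r}; expected one of {SCENARIOS}"
            )
        if self.n_cells < 1:
            raise ValueError("n_cells must be a positive integer")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.burst_frequency_hz < 0:
            raise ValueError("burst_frequency_hz must be >= 0")
        if not 0.0 <= self.participation_fraction <= 1.0:
            raise ValueError("participation_fraction must lie in [0, 1]")
        if self.baseline_rate_hz is not None and self.baseline_rate_hz < 0:
            raise ValueError("baseline_rate_hz must be >= 0")
        if not 0.0 <= self.motif_noise <= 1.0:
            raise ValueError("motif_noise must lie in [0, 1]")
        if self.motif_length < 1:
            raise ValueError("motif_length must be >= 1")
        if self.scenario_name == "complex_recurrent" and self.motif_length > self.n_cells:
            raise ValueError("motif_length cannot exceed n_cells")
        if self.event_interval_s <= 0:
            raise ValueError("event_interval_s must be > 0")
        if self.recruitment_window_s <= 0:
            raise ValueError("recruitment_window_s must be > 0")
        if self.burst_min_separation_s < 0:
            raise ValueError("burst_min_separation_s must be >= 0")

    @property
    def resolved_baseline_rate_hz(self) -> float:
        if self.baseline_rate_hz is not None:
            return self.baseline_rate_hz
        return _DEFAULT_BASELINE_RATE[self.scenario_name]


@dataclass(frozen=True)
class KernelConfig:
    """Forward model of the calcium indicator response to one firing event.

    A transient rises linearly over ``rise_s`` (onset is fast, under
    0.6 s) and decays exponentially with time constant ``decay_s``
    (slow, of order 1-8 s).  Fluorescence is reported as
    ``F = f0 * (1 + dF/F)`` with additive Gaussian noise of standard
    deviation ``noise_sd`` on the dF/F scale.
    """

    rise_s: float = 0.4
    decay_s: float = 3.0
    amplitude_per_event: float = 0.5
    noise_sd: float = 0.02
    fps: float = 10.0
    f0: float = 100.0

    def __post_init__(self) -> None:
        if not 0.0 < self.rise_s < 0.6:
            raise ValueError("rise_s must lie in (0, 0.6) seconds")
        if self.decay_s <= 0:
            raise ValueError("decay_s must be > 0")
        if self.amplitude_per_event <= 0:
            raise ValueError("amplitude_per_event must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.f0 <= 0:
            raise ValueError("f0 must be > 0")


@dataclass
class EventTrain:
    """Ground-truth events: per-cell times (s) and integer spike-count weights.

    The weight models the number of action potentials underlying a
    transient; rendered transient amplitude scales linearly with it.
    """

    cell_ids: list[str]
    times: dict[str, np.ndarray]
    weights: dict[str, np.ndarray]
    duration_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid in self.cell_ids:
            t = np.asarray(self.times.get(cid, np.empty(0)), dtype=float)
            w = np.asarray(self.weights.get(cid, np.empty(0)), dtype=int)
            if t.size != w.size:
                raise ValueError(f"cell {cid}: times and weights differ in length")
            if t.size and (t.min() < 0 or t.max() >= self.duration_s):
                raise ValueError(
                    f"cell {cid}: event times must lie in [0, duration_s)"
                )
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"cell {cid}: event times must be strictly increasing")
            if w.size and w.min() < 1:
                raise ValueError(f"cell {cid}: weights must be >= 1")
            self.times[cid] = t
            self.weights[cid] = w

    @property
    def n_events(self) -> int:
        return int(sum(len(self.times[c]) for c in self.cell_ids))

    def all_events(self) -> list[tuple[str, float, int]]:
        """Flattened (cell_id, time, weight) records sorted by time then ID."""
        recs = [
            (cid, float(t), int(w))
            for cid in self.cell_ids
            for t, w in zip(self.times[cid], self.weights[cid])
        ]
        recs.sort(key=lambda r: (r[1], r[0]))
        return recs


def _empty_train(config: ScenarioConfig, ids: list[str]) -> tuple[dict, dict]:
    return (
        {c: np.empty(0) for c in ids},
        {c: np.empty(0, dtype=int) for c in ids},
    )


def _poisson_trains(
    rng: np.random.Generator, ids: list[str], rate_hz: float, duration_s: float
) -> dict[str, np.ndarray]:
    out = {}
    for cid in ids:
        n = rng.poisson(rate_hz * duration_s)
        out[cid] = np.sort(rng.uniform(0.0, duration_s, size=n))
    return out


def _burst_times(rng: np.random.Generator, config: ScenarioConfig) -> np.ndarray:
    """Poisson-distributed burst count with a hard-core minimum separation.

    The expected count equals ``burst_frequency_hz * duration_s``; times
    are uniform conditional on the count, subject to the dead time.
    """
    usable = config.duration_s - config.recruitment_window_s
    if usable <= 0:
        return np.empty(0)
    n = rng.poisson(config.burst_frequency_hz * config.duration_s)
    sep = config.burst_min_separation_s
    if sep > 0:
        n = min(n, int(usable // sep))
    if n == 0:
        return np.empty(0)
    slack = usable - (n - 1) * sep
    starts = np.sort(rng.uniform(0.0, slack, size=n)) + np.arange(n) * sep
    return starts


def _synchronized_events(
    rng: np.random.Generator, config: ScenarioConfig, ids: list[str]
) -> tuple[dict, np.ndarray]:
    starts = _burst_times(rng, config)
    per_cell: dict[str, list] = {c: [] for c in ids}
    for t0 in starts:
        mask = rng.random(config.n_cells) < config.participation_fraction
        offs = rng.uniform(0.0, config.recruitment_window_s, size=int(mask.sum()))
        for cid, off in zip(np.asarray(ids)[mask], offs):
            per_cell[cid].append(t0 + off)
    rate = config.resolved_baseline_rate_hz
    baseline = _poisson_trains(rng, ids, rate, config.duration_s)
    times = {}
    for cid in ids:
        t = np.concatenate([np.asarray(per_cell[cid]), baseline[cid]])
        times[cid] = np.unique(t)
    return times, starts


def _complex_recurrent_events(
    rng: np.random.Generator, config: ScenarioConfig, ids: list[str]
) -> tuple[dict, np.ndarray]:
    motif_idx = rng.choice(config.n_cells, size=config.motif_length, replace=False)
    interval = config.event_interval_s
    n_events = int(np.floor((config.duration_s - interval / 2.0) / interval)) + 1
    n_events = max(n_events, 0)
    event_times = (np.arange(n_events) + 0.5) * interval
    event_times = event_times[event_times < config.duration_s]
    n_events = event_times.size
    symbols = np.resize(motif_idx, n_events)
    if config.motif_noise > 0 and n_events:
        noise_mask = rng.random(n_events) < config.motif_noise
        symbols = symbols.copy()
        symbols[noise_mask] = rng.integers(0, config.n_cells, size=int(noise_mask.sum()))
    times = {c: [] for c in ids}
    for t, s in zip(event_times, symbols):
        times[ids[int(s)]].append(t)
    return (
        {c: np.asarray(times[c]) for c in ids},
        motif_idx,
    )


def generate_events(config: ScenarioConfig) -> EventTrain:
    """Draw a ground-truth event train for the configured scenario.

    All randomness flows through a single ``numpy`` generator seeded with
    ``config.seed``; the seed and scenario are recorded in the output
    metadata.  ``bicuculline`` runs the exact same code path as
    ``synchronized``, so equal seeds give bit-identical trains.
    """
    rng = np.random.default_rng(config.seed)
    ids = cell_labels(config.n_cells)
    meta: dict = {"scenario": config.scenario_name, "seed": config.seed}

    scenario = config.scenario_name
    if scenario in ("ttx", "gaba_agonist"):
        times, _ = _empty_train(config, ids), None
        times = times[0]
    elif scenario in ("asynchronous", "cnqx_apv"):
        times = _poisson_trains(
            rng, ids, config.resolved_baseline_rate_hz, config.duration_s
        )
    elif scenario in ("synchronized", "bicuculline"):
        times, starts = _synchronized_events(rng, config, ids)
        meta["burst_times"] = starts
    elif scenario == "complex_recurrent":
        times, motif_idx = _complex_recurrent_events(rng, config, ids)
        meta["motif"] = [ids[int(i)] for i in motif_idx]
    else:  # pragma: no cover - guarded by ScenarioConfig
        raise ValueError(f"unknown scenario {scenario!r}")

    weights = {
        cid: rng.integers(1, 6, size=len(times[cid])) for cid in ids
    }
    return EventTrain(
        cell_ids=ids,
        times=times,
        weights=weights,
        duration_s=config.duration_s,
        meta=meta,
    )


def _kernel_curve(t_rel: np.ndarray, kernel: KernelConfig) -> np.ndarray:
    """Unit-amplitude indicator response at times ``t_rel >= 0`` after onset."""
    rising = t_rel < kernel.rise_s
    out = np.where(
        rising,
        t_rel / kernel.rise_s,
        np.exp(-(t_rel - kernel.rise_s) / kernel.decay_s),
    )
    return out


def render_traces(
    events: EventTrain, kernel: KernelConfig, seed: int = 0
) -> TraceSet:
    """Render raw fluorescence traces from an event train.

    Each event contributes ``amplitude_per_event * weight`` times the
    rise/decay kernel by linear superposition; Gaussian noise of standard
    deviation ``noise_sd`` is added on the dF/F scale, and the output is
    raw fluorescence ``F = f0 * (1 + dF/F)``.
    """
    n_frames = int(round(events.duration_s * kernel.fps))
    t = np.arange(n_frames) / kernel.fps
    n_cells = len(events.cell_ids)
    dff = np.zeros((n_cells, n_frames))
    for i, cid in enumerate(events.cell_ids):
        for t0, w in zip(events.times[cid], events.weights[cid]):
            if not 0.0 <= t0 < events.duration_s:
                raise ValueError(
                    f"cell {cid}: event at {t0} s outside [0, {events.duration_s}) s"
                )
            start = int(np.ceil(t0 * kernel.fps - 1e-9))
            t_rel = t[start:] - t0
            dff[i, start:] += kernel.amplitude_per_event * w * _kernel_curve(
                t_rel, kernel
            )
    if kernel.noise_sd > 0:
        rng = np.random.default_rng(seed)
        dff = dff + rng.normal(0.0, kernel.noise_sd, size=dff.shape)
    F = kernel.f0 * (1.0 + dff)
    meta = dict(events.meta)
    meta.update(
        {
            "render_seed": seed,
            "kernel": {
                "rise_s": kernel.rise_s,
                "decay_s": kernel.decay_s,
                "amplitude_per_event": kernel.amplitude_per_event,
                "noise_sd": kernel.noise_sd,
                "fps": kernel.fps,
                "f0": kernel.f0,
            },
        }
    )
    return TraceSet(
        cell_ids=list(events.cell_ids),
        F=F,
        fps=kernel.fps,
        duration_s=events.duration_s,
        meta=meta,
    )


def _powerlaw_probs(exponent: float, k_min: int, k_max: int) -> tuple[np.ndarray, np.ndarray]:
    ks = np.arange(k_min, k_max + 1)
    p = ks.astype(float) ** exponent
    return ks, p / p.sum()


def generate_degree_sequence(
    model: str,
    params: Mapping | None = None,
    n_neurons: int = 69,
    seed: int = 0,
) -> np.ndarray:
    """Draw a sequence of per-neuron presynaptic input counts.

    Models
    ------
    ``poisson``
        i.i.d. Poisson(``lam``) -- random connection to a large pool.
    ``binomial``
        i.i.d. Binomial(``n``, ``p``) -- connection with probability ``p``
        to each of ``n`` candidate partners.
    ``powerlaw``
        Discrete truncated power law ``P(k) ~ k**exponent`` on
        ``[k_min, k_max]`` -- a scale-free network.
    ``hub_mix``
        A hub-dominated mixture patterned on tracing data from cultured
        cortical networks: the body of the sample (all but the hubs)
        draws 0-8 inputs from a zero-inflated truncated power law, and a
        small set of explicit hub values (default 14, 17 and 43) is
        appended.  Defaults give an overall mean of ~2.25 inputs per
        neuron over 69 neurons.
    """
    if model not in DEGREE_MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {DEGREE_MODELS}")
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    p = dict(params or {})
    rng = np.random.default_rng(seed)

    if model == "poisson":
        lam = float(p.pop("lam", 2.25))
        if p:
            raise ValueError(f"unexpected poisson params: {sorted(p)}")
        if lam <= 0:
            raise ValueError("poisson lam must be > 0")
        return rng.poisson(lam, size=n_neurons)

    if model == "binomial":
        n = int(p.pop("n", 735))
        prob = float(p.pop("p", 0.0031))
        if p:
            raise ValueError(f"unexpected binomial params: {sorted(p)}")
        if n < 1:
            raise ValueError("binomial n must be >= 1")
        if not 0.0 <= prob <= 1.0:
            raise ValueError("binomial p must lie in [0, 1]")
        return rng.binomial(n, prob, size=n_neurons)

    if model == "powerlaw":
        exponent = float(p.pop("exponent", -2.0))
        k_min = int(p.pop("k_min", 1))
        k_max = int(p.pop("k_max", 50))
        if p:
            raise ValueError(f"unexpected powerlaw params: {sorted(p)}")
        if exponent >= 0:
            raise ValueError("powerlaw exponent must be < 0")
        if k_min < 1 or k_max < k_min:
            raise ValueError("require 1 <= k_min <= k_max")
        ks, probs = _powerlaw_probs(exponent, k_min, k_max)
        return rng.choice(ks, size=n_neurons, p=probs)

    # hub_mix
    hubs = list(p.pop("hubs", [14, 17, 43]))
    body_k_max = int(p.pop("body_k_max", 8))
    body_exponent = float(p.pop("body_exponent", -2.0))
    body_zero_prob = float(p.pop("body_zero_prob", 0.31))
    if p:
        raise ValueError(f"unexpected hub_mix params: {sorted(p)}")
    if len(hubs) >= n_neurons:
        raise ValueError("need more neurons than hubs")
    if not 0.0 <= body_zero_prob <= 1.0:
        raise ValueError("body_zero_prob must lie in [0, 1]")
    n_body = n_neurons - len(hubs)
    ks, probs = _powerlaw_probs(body_exponent, 1, body_k_max)
    body = rng.choice(ks, size=n_body, p=probs)
    body[rng.random(n_body) < body_zero_prob] = 0
    return np.concatenate([body, np.asarray(hubs, dtype=int)])
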