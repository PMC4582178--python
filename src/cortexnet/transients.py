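"""Transient and network-burst detection on per-cell fluorescence traces.

The pipeline entry point is a :class:`TraceSet` of raw fluorescence
(cells x frames).  :func:`compute_dff` converts it to dF/F against a
rolling-percentile baseline, :func:`detect_transients` locates per-cell
calcium transients (fast rise, slow decay), :func:`detect_network_bursts`
groups onsets across cells into synchronised network bursts and reports
burst frequency and participation, and :func:`activation_sequence`
compiles the temporally ordered sequence of activated cell IDs that the
recurrence analysis consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import median_abs_deviation

from .recurrence import ActivationSequence

__all__ = [
    "TraceSet",
    "EventTable",
    "BurstTable",
    "compute_dff",
    "detect_transients",
    "detect_network_bursts",
    "activation_sequence",
]

EVENT_COLUMNS = ("cell_id", "onset_time_s", "peak_dff")
BURST_COLUMNS = (
    "burst_start_s",
    "burst_end_s",
    "n_participating_cells",
    "participation_fraction",
)


@dataclass
class TraceSet:
    """Per-cell fluorescence time series with sampling metadata.

    ``F`` is a (cells x frames) matrix in arbitrary fluorescence units
    (or dF/F after :func:`compute_dff`; see ``meta['units']``).
    """

    cell_ids: list[str]
    F: np.ndarray
    fps: float
    duration_s: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.F.ndim != 2 or self.F.shape[0] != len(self.cell_ids):
            raise ValueError("F must be a (cells x frames) matrix")
        expected = int(round(self.duration_s * self.fps))
        if self.F.shape[1] != expected:
            raise ValueError(
                f"frame count {self.F.shape[1]} != round(duration_s * fps) = {expected}"
            )

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def n_frames(self) -> int:
        return int(self.F.shape[1])

    @property
    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class EventTable:
    """Detected calcium-transient onsets.

    ``events`` has columns ``cell_id``, ``onset_time_s`` and ``peak_dff``,
    sorted by onset time (ties broken by cell ID).
    """

    events: pd.DataFrame
    duration_s: float
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.events, columns=list(EVENT_COLUMNS))
        if len(df):
            if df["onset_time_s"].min() < 0 or df["onset_time_s"].max() >= self.duration_s:
                raise ValueError("onset times must lie in [0, duration_s)")
            if (df["peak_dff"] <= 0).any():
                raise ValueError("peak_dff must be > 0")
            df = df.sort_values(["onset_time_s", "cell_id"], kind="stable")
            for cid, grp in df.groupby("cell_id"):
                if not grp["onset_time_s"].is_monotonic_increasing or grp[
                    "onset_time_s"
                ].duplicated().any():
                    raise ValueError(
                        f"cell {cid}: per-cell onsets must be strictly increasing"
                    )
        self.events = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class BurstTable:
    """Detected network bursts plus summary statistics.

    ``bursts`` has one row per burst (start, end, number and fraction of
    participating cells).  ``burst_frequency_hz`` is the number of
    bursting events per unit time, i.e. burst count / recording duration.
    ``mean_burst_amplitude`` is the mean transient peak dF/F over onsets
    that fall inside bursts (NaN when there are none).
    """

    bursts: pd.DataFrame
    duration_s: float
    n_cells: int
    mean_burst_amplitude: float = float("nan")

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.bursts, columns=list(BURST_COLUMNS))
        if len(df):
            if (df["burst_end_s"] < df["burst_start_s"]).any():
                raise ValueError("burst_end_s must be >= burst_start_s")
            starts = df["burst_start_s"].to_numpy()
            ends = df["burst_end_s"].to_numpy()
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError("bursts must be non-overlapping and ordered")
        self.bursts = df.reset_index(drop=True)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def burst_frequency_hz(self) -> float:
        return self.n_bursts / self.duration_s


def compute_dff(
    traces: TraceSet,
    baseline_percentile: float = 20.0,
    baseline_window_s: float = 30.0,
) -> TraceSet:
    """Convert raw fluorescence to dF/F = (F - F0) / F0.

    F0 is a per-cell rolling percentile of the raw trace (centred window),
    smoothed with a rolling mean of the same width so that discrete
    percentile-rank changes cannot introduce step artefacts into the
    baseline.  On a constant trace F0 equals the trace and dF/F is
    identically zero.
    """
    if not 0.0 < baseline_percentile <= 50.0:
        raise ValueError("baseline_percentile must lie in (0, 50]")
    window = int(round(baseline_window_s * traces.fps))
    if window < 10:
        raise ValueError("baseline window must span at least 10 frames")
    nonpos = (traces.F <= 0).any(axis=1)
    if nonpos.any():
        offender = traces.cell_ids[int(np.flatnonzero(nonpos)[0])]
        raise ValueError(
            f"cell {offender}: non-positive raw fluorescence; dF/F undefined"
        )
    df = pd.DataFrame(traces.F.T, columns=traces.cell_ids)
    roll = df.rolling(window, center=True, min_periods=1)
    f0 = roll.quantile(baseline_percentile / 100.0)
    f0 = f0.rolling(window, center=True, min_periods=1).mean()
    bad = (f0 <= 0).any(axis=0)
    if bad.any():
        offender = bad.index[bad.to_numpy()][0]
        raise ValueError(
            f"cell {offender}: baseline fluorescence F0 <= 0; dF/F undefined"
        )
    dff = (df - f0) / f0
    meta = dict(traces.meta)
    meta["units"] = "dff"
    meta["baseline"] = {
        "percentile": baseline_percentile,
        "window_s": baseline_window_s,
    }
    return TraceSet(
        cell_ids=list(traces.cell_ids),
        F=dff.to_numpy().T,
        fps=traces.fps,
        duration_s=traces.duration_s,
        meta=meta,
    )


def _noise_sigma(x: np.ndarray, floor: float) -> float:
    # Successive-difference MAD estimator: insensitive to the slow transient
    # waveform itself, so the threshold tracks the noise even in recordings
    # dominated by signal.
    if x.size < 2:
        return floor
    sigma = median_abs_deviation(np.diff(x), scale="normal") / np.sqrt(2.0)
    return float(max(sigma, floor))


def detect_transients(
    dff: TraceSet,
    threshold_mads: float = 4.0,
    min_rise_s: float = 0.6,
    refractory_s: float = 1.0,
    sigma_floor: float = 0.01,
) -> EventTable:
    """Detect per-cell calcium transients in dF/F traces.

    A candidate transient is a local maximum whose prominence and absolute
    height both exceed ``threshold_mads`` robust noise SDs, whose rise
    from the preceding local minimum reaches threshold within
    ``min_rise_s`` (transients have fast onsets), and which remains
    elevated immediately after the peak (transients have slow decays;
    single-frame noise spikes do not).  Successive onsets on one cell must
    be at least ``refractory_s`` after the previous accepted peak.
    ``sigma_floor`` bounds the noise estimate from below (dF/F units) so
    that near-noiseless recordings do not trigger on numerical ripple.
    """
    if threshold_mads <= 0:
        raise ValueError("threshold_mads must be > 0")
    if not 0 < min_rise_s <= 0.6:
        raise ValueError("min_rise_s must lie in (0, 0.6] seconds")
    if refractory_s < 0:
        raise ValueError("refractory_s must be >= 0")
    if np.isnan(dff.F).any():
        raise ValueError("traces contain NaN frames")

    records: list[tuple[str, float, float]] = []
    fps = dff.fps
    post_frames = max(int(round(0.5 * fps)), 1)
    rise_frames = int(round(min_rise_s * fps)) + 2
    for i, cid in enumerate(dff.cell_ids):
        x = dff.F[i]
        sigma = _noise_sigma(x, sigma_floor)
        height = threshold_mads * sigma
        floor = float(np.quantile(x, 0.2))
        peaks, _ = find_peaks(x, prominence=height, height=floor + height)
        last_peak_t = -np.inf
        for p in peaks:
            t_peak = p / fps
            if t_peak - last_peak_t < refractory_s:
                continue
            # onset: the last near-baseline frame in the rise window before
            # the peak ("baseline" = the window minimum, noise-tolerant)
            lo = max(p - rise_frames, 0)
            base = float(x[lo : p + 1].min())
            below = np.flatnonzero(x[lo : p + 1] <= base + 2.0 * sigma)
            onset = lo + int(below[-1]) if below.size else lo
            # fast-onset criterion: threshold reached within min_rise_s
            rise_target = x[onset] + height
            crossing = onset
            while crossing < p and x[crossing] < rise_target:
                crossing += 1
            if (crossing - onset) / fps > min_rise_s:
                continue
            # slow-decay criterion: the mean over the next ~0.5 s stays well
            # above the onset level (true transients decay over >= 1 s;
            # single-frame noise excursions do not)
            tail = x[p + 1 : p + 1 + post_frames]
            if tail.size >= 2 and tail.mean() < x[onset] + 0.7 * (x[p] - x[onset]):
                continue
            records.append((cid, onset / fps, float(x[p])))
            last_peak_t = t_peak

    df = pd.DataFrame(records, columns=list(EVENT_COLUMNS))
    return EventTable(events=df, duration_s=dff.duration_s, cell_ids=list(dff.cell_ids))


def detect_network_bursts(
    events: EventTable,
    n_cells: int | None = None,
    sync_window_s: float = 1.0,
    min_participation: float = 0.5,
) -> BurstTable:
    """Group transient onsets into synchronised network bursts.

    A burst is a maximal chain of onsets in which each onset lies within
    ``sync_window_s`` of the next, provided the chain recruits at least
    ``min_participation * n_cells`` distinct cells.  Burst frequency is
    the number of bursts divided by the recording duration.
    """
    if n_cells is None:
        n_cells = len(events.cell_ids)
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if sync_window_s <= 0:
        raise ValueError("sync_window_s must be > 0")
    if not 0.0 < min_participation <= 1.0:
        raise ValueError("min_participation must lie in (0, 1]")

    df = events.events
    rows = []
    in_burst = np.zeros(len(df), dtype=bool)
    if len(df):
        t = df["onset_time_s"].to_numpy()
        cells = df["cell_id"].to_numpy()
        breaks = np.flatnonzero(np.diff(t) > sync_window_s)
        bounds = np.concatenate([[0], breaks + 1, [len(t)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            distinct = np.unique(cells[a:b]).size
            if distinct >= min_participation * n_cells:
                rows.append(
                    (float(t[a]), float(t[b - 1]), int(distinct), distinct / n_cells)
                )
                in_burst[a:b] = True
    bursts = pd.DataFrame(rows, columns=list(BURST_COLUMNS))
    amp = (
        float(df.loc[in_burst, "peak_dff"].mean()) if in_burst.any() else float("nan")
    )
    return BurstTable(
        bursts=bursts,
        duration_s=events.duration_s,
        n_cells=n_cells,
        mean_burst_amplitude=amp,
    )


def activation_sequence(events: EventTable) -> ActivationSequence:
    """Compile the temporally ordered sequence of activated cell IDs.

    Simultaneous onsets are ordered lexicographically by cell ID; the
    tie-break rule is recorded in the sequence metadata.
    """
    if len(events) == 0:
        raise ValueError("cannot build an activation sequence from an empty EventTable")
    df = events.events.sort_values(["onset_time_s", "cell_id"], kind="stable")
    return ActivationSequence(
        symbols=df["cell_id"].to_numpy(),
        meta={"tie_break": "cell_id lexicographic"},
    )
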