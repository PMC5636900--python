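"""Spike-train metrics and peristimulus time histograms (PSTHs).

All times are in milliseconds relative to stimulus onset (t = 0). The
standard recording window is [-200, 1100) ms around a 700 ms whisker
air-puff stimulus: ongoing activity is measured in the 200 ms before onset,
the "onset" response in the first 100 ms of the stimulus, and the
"sustained" response in the remaining 100-700 ms. Evoked rates are reported
as elevations above the ongoing rate and are not clamped at zero.

Interval conventions are half-open [t, t+dt): a spike exactly at 0 belongs
to the evoked period. Bursts are runs of spikes at short inter-spike
intervals (<= 10 ms for the 100 Hz criterion, <= 5 ms for 200 Hz) within a
single trial's ongoing window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "PSTH",
    "ActivityMetrics",
    "compute_psth",
    "pooled_rate",
    "ongoing_rate",
    "burst_fraction",
    "evoked_metrics",
    "activity_metrics",
    "DEFAULT_WINDOW",
    "ONGOING_WINDOW",
    "ONSET_WINDOW",
    "SUSTAINED_WINDOW",
]

DEFAULT_WINDOW = (-200.0, 1100.0)
ONGOING_WINDOW = (-200.0, 0.0)
ONSET_WINDOW = (0.0, 100.0)
SUSTAINED_WINDOW = (100.0, 700.0)


@dataclass
class SpikeTrainSet:
    """Per-trial sorted spike times (ms, stimulus onset = 0)."""

    trials: list[np.ndarray]
    window: tuple[float, float] = DEFAULT_WINDOW
    stimulus_duration: float = 700.0

    def __post_init__(self) -> None:
        if len(self.trials) < 1:
            raise ValueError("need at least one trial")
        self.trials = [np.asarray(t, dtype=float) for t in self.trials]
        lo, hi = self.window
        for i, t in enumerate(self.trials):
            if t.size and (t[0] < lo or t[-1] > hi):
                raise ValueError(f"trial {i}: spike outside window {self.window}")
            if t.size > 1 and np.any(np.diff(t) <= 0):
                raise ValueError(f"trial {i}: spike times not strictly increasing")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def total_spikes(self) -> int:
        return int(sum(t.size for t in self.trials))


@dataclass
class PSTH:
    """Trial-pooled spike rate per time bin (Hz)."""

    edges: np.ndarray       # (n_bins + 1,) ms
    rate: np.ndarray        # (n_bins,) Hz
    n_trials: int
    bin_width: float        # ms

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def total_count(self) -> float:
        """Total spike count implied by the rates (exact by construction)."""
        return float(np.sum(self.rate) * self.bin_width / 1000.0 * self.n_trials)


@dataclass
class ActivityMetrics:
    """Per-cell spiking summary matching the reported group statistics."""

    ongoing_rate: float      # Hz
    burst100_pct: float      # % of ongoing APs in >= 100 Hz bursts
    burst200_pct: float      # % of ongoing APs in >= 200 Hz bursts
    onset_rate: float        # Hz elevation, [0, 100) ms
    onset_prob: float        # fraction of trials with >= 1 spike in [0, 100)
    sustained_rate: float    # Hz elevation, [100, 700) ms
    no_ongoing_spikes: bool = False


def compute_psth(trains: SpikeTrainSet, bin_width: float = 5.0) -> PSTH:
    """Pool spikes over trials into [t, t+bin) bins and convert to Hz.

    The last bin is closed so a spike exactly at the window end is counted.
    """
    lo, hi = trains.window
    span = hi - lo
    n_bins = span / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError(f"bin width {bin_width} does not divide window span {span}")
    edges = lo + bin_width * np.arange(round(n_bins) + 1)
    if trains.total_spikes():
        counts, _ = np.histogram(np.concatenate(trains.trials), bins=edges)
    else:
        counts = np.zeros(len(edges) - 1)
    rate = counts / (trains.n_trials * bin_width / 1000.0)
    return PSTH(edges=edges, rate=rate, n_trials=trains.n_trials, bin_width=bin_width)


def _pooled_rate(trains: SpikeTrainSet, window: tuple[float, float]) -> float:
    lo, hi = window
    count = sum(int(np.sum((t >= lo) & (t < hi))) for t in trains.trials)
    return count / (trains.n_trials * (hi - lo) / 1000.0)


def pooled_rate(trains: SpikeTrainSet, window: tuple[float, float]) -> float:
    """Trial-pooled absolute spike rate (Hz) in an arbitrary [lo, hi) window."""
    return _pooled_rate(trains, window)


def ongoing_rate(trains: SpikeTrainSet, window: tuple[float, float] = ONGOING_WINDOW) -> float:
    """Trial-pooled spike rate (Hz) in the pre-stimulus window [-200, 0)."""
    return _pooled_rate(trains, window)


def burst_fraction(
    trains: SpikeTrainSet,
    threshold_hz: float,
    window: tuple[float, float] = ONGOING_WINDOW,
) -> float:
    """Percentage of ongoing-window spikes that participate in a burst.

    A spike is "in a burst" if at least one of its inter-spike intervals to a
    neighbouring spike in the same trial's ongoing window is
    <= 1000/threshold_hz ms. Returns 0 when there are no ongoing spikes.
    """
    if threshold_hz <= 0:
        raise ValueError("threshold must be positive")
    max_isi = 1000.0 / threshold_hz
    lo, hi = window
    n_spikes = 0
    n_burst = 0
    for t in trains.trials:
        tt = t[(t >= lo) & (t < hi)]
        n_spikes += tt.size
        if tt.size < 2:
            continue
        isi_short = np.diff(tt) <= max_isi
        in_burst = np.zeros(tt.size, dtype=bool)
        in_burst[:-1] |= isi_short
        in_burst[1:] |= isi_short
        n_burst += int(np.sum(in_burst))
    if n_spikes == 0:
        return 0.0
    return 100.0 * n_burst / n_spikes


def evoked_metrics(
    trains: SpikeTrainSet,
    onset_window: tuple[float, float] = ONSET_WINDOW,
    sustained_window: tuple[float, float] = SUSTAINED_WINDOW,
) -> tuple[float, float, float]:
    """(onset_rate, onset_prob, sustained_rate).

    Onset and sustained rates are elevations above the ongoing rate (negative
    values reported as-is); onset probability is the fraction of trials with
    at least one spike in the onset window.
    """
    base = ongoing_rate(trains)
    onset = _pooled_rate(trains, onset_window) - base
    sustained = _pooled_rate(trains, sustained_window) - base
    lo, hi = onset_window
    prob = float(
        np.mean([np.any((t >= lo) & (t < hi)) for t in trains.trials])
    )
    return onset, prob, sustained


def activity_metrics(trains: SpikeTrainSet) -> ActivityMetrics:
    """All per-cell spiking metrics in one pass."""
    base = ongoing_rate(trains)
    onset, prob, sustained = evoked_metrics(trains)
    n_ongoing = sum(
        int(np.sum((t >= ONGOING_WINDOW[0]) & (t < ONGOING_WINDOW[1]))) for t in trains.trials
    )
    return ActivityMetrics(
        ongoing_rate=base,
        burst100_pct=burst_fraction(trains, 100.0),
        burst200_pct=burst_fraction(trains, 200.0),
        onset_rate=onset,
        onset_prob=prob,
        sustained_rate=sustained,
        no_ongoing_spikes=(n_ongoing == 0),
    )
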