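"""Spike detection, interspike intervals, and firing-pattern classification.

A spike is an upward crossing of a voltage threshold (-15 mV by default),
with the crossing time linearly interpolated between grid points.  Firing
patterns are summarized by a small integer code:

===== =======================================================
code  meaning
===== =======================================================
0     no oscillations (quiescent)
1     sub-threshold oscillations, no (or almost no) spikes
2     oscillations and spikes with skipping / polymodal firing
3     regular tonic spiking
4     burst firing (with a modal spikes-per-burst count)
5     tonic firing at 20-50 spikes/s
6     firing rate above 50 spikes/s
===== =======================================================

The published material defines these categories visually; the decision
tree implemented in :func:`classify_pattern` operationalizes them (see
``docs/methods.md`` for the exact rules and rationale).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrate import Trajectory

__all__ = [
    "SpikeTrain",
    "PatternCode",
    "detect_spikes",
    "isi",
    "firing_rate",
    "classify_pattern",
    "interpolated_crossings",
    "isi_histogram",
]


@dataclass
class SpikeTrain:
    """Spike times in ms (strictly increasing) over a recorded span."""

    spike_times: np.ndarray
    threshold: float
    duration: float  # recorded span the train was measured over, ms

    def __len__(self) -> int:
        return len(self.spike_times)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s."""
        return 1000.0 * len(self.spike_times) / self.duration if self.duration else 0.0


@dataclass(frozen=True)
class PatternCode:
    code: int
    spikes_per_burst: int | None = None  # modal value, code 4 only

    def __int__(self) -> int:
        return self.code


def interpolated_crossings(times: np.ndarray, values: np.ndarray,
                           threshold: float) -> np.ndarray:
    """Upward threshold crossings of a sampled signal, linearly interpolated."""
    v = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.flatnonzero(below & above)
    if len(idx) == 0:
        return np.empty(0)
    frac = (threshold - v[idx]) / (v[idx + 1] - v[idx])
    return t[idx] + frac * (t[idx + 1] - t[idx])


def detect_spikes(trajectory: Trajectory, threshold: float | None = None) -> SpikeTrain:
    """Extract the spike train from a trajectory.

    If the trajectory carries full-resolution crossing times for the
    requested threshold (the integrator records them during the run),
    those are used; otherwise crossings are recomputed from the recorded
    samples.  Spike counts are therefore independent of the recording
    stride whenever detection ran inside the integrator.
    """
    if len(trajectory.times) == 0:
        raise ValueError("empty trajectory")
    if threshold is None:
        threshold = trajectory.params.spike_threshold
    if (
        trajectory.crossing_threshold is not None
        and threshold == trajectory.crossing_threshold
    ):
        times = trajectory.crossing_times
    else:
        times = interpolated_crossings(trajectory.times, trajectory.V, threshold)
    return SpikeTrain(
        spike_times=np.asarray(times, dtype=float),
        threshold=threshold,
        duration=trajectory.duration,
    )


def isi(train: SpikeTrain) -> np.ndarray:
    """Successive interspike intervals in ms (empty for < 2 spikes)."""
    return np.diff(train.spike_times)


def firing_rate(train: SpikeTrain) -> float:
    return train.rate


def isi_histogram(intervals, bin_width: float = 5.0):
    """Interval histogram on a fixed-width grid (for reports/plots; the
    classifier does not use it).  Returns ``(edges, counts)``."""
    x = np.asarray(intervals, dtype=float)
    if len(x) == 0:
        return np.array([0.0, bin_width]), np.zeros(1, dtype=int)
    edges = np.arange(0.0, x.max() + 2 * bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return edges, counts


def _burst_structure(intervals: np.ndarray):
    """Split ISIs into intra-burst and inter-burst at the geometric-mean
    gap; return (spikes_per_burst array, median short ISI) or None if the
    split is degenerate."""
    gap = float(np.sqrt(intervals.max() * intervals.min()))
    long_mask = intervals >= gap
    if not long_mask.any() or long_mask.all():
        return None
    # groups of consecutive spikes separated by long intervals
    sizes = []
    current = 1
    for is_long in long_mask:
        if is_long:
            sizes.append(current + 1)
            current = 0
        else:
            current += 1
    sizes.append(current + 1)
    short = intervals[~long_mask]
    return np.asarray(sizes), float(np.median(short))


def classify_pattern(
    trajectory: Trajectory,
    train: SpikeTrain | None = None,
    min_duration: float = 30_000.0,
) -> PatternCode:
    """Classify the firing pattern of a (long) post-equilibration trajectory.

    Decision tree: quiescence vs sub-threshold oscillation when there are
    (almost) no spikes; fast-tonic codes 5/6 straight from the rate; then
    regular tonic (low ISI coefficient of variation), bursting (regular
    short runs below 100 ms separated by long gaps), or skipping/polymodal
    (everything else irregular).
    """
    if trajectory.duration < min_duration:
        raise ValueError(
            f"trajectory spans {trajectory.duration:.0f} ms; "
            f"need >= {min_duration:.0f} ms for classification"
        )
    if train is None:
        train = detect_spikes(trajectory)
    n = len(train)
    if n < 5:
        # quiescent or subthreshold-oscillating (a stray spike or two allowed)
        tail = trajectory.times >= trajectory.times[-1] - 10_000.0
        vpp = float(np.ptp(trajectory.V[tail]))
        if vpp < 2.0 and n == 0:
            return PatternCode(0)
        return PatternCode(1)
    rate = train.rate
    if rate > 50.0:
        return PatternCode(6)
    if rate > 20.0:
        return PatternCode(5)
    intervals = isi(train)
    cv = float(np.std(intervals) / np.mean(intervals))
    if cv < 0.05:
        return PatternCode(3)
    split = _burst_structure(intervals)
    if split is not None:
        sizes, median_short = split
        if len(sizes) >= 2 and median_short < 100.0:
            modal = int(np.bincount(sizes).argmax())
            regular = np.abs(sizes - modal) <= 1
            if modal >= 2 and regular.mean() >= 0.9:
                return PatternCode(4, spikes_per_burst=modal)
    return PatternCode(2)
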