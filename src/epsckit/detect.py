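"""Threshold-crossing event detection, screening, alignment and averaging.

Detection follows the conventional amplitude-threshold rule: the threshold
is ``k`` times the baseline noise SD (read as SD, not variance, for
dimensional consistency with a pA-scale threshold) applied to the inward
(negative) excursions of the baseline-subtracted trace.  The threshold is
evaluated on a lightly boxcar-smoothed copy of the trace so that the
false-positive rate on pure noise stays below the Gaussian upcrossing
bound; amplitudes and kinetics are always measured on the raw trace.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io import SweepRecording

logger = logging.getLogger(__name__)


@dataclass
class Event:
    """A detected synaptic event (times in ms, amplitudes in pA, signed)."""

    sweep_index: int
    onset_time: float
    peak_time: float
    peak_amplitude: float
    local_baseline: float
    rise_10_90: Optional[float] = None
    monotonic_rise: bool = False
    clean_decay: bool = False
    post_stimulus_ok: bool = True

    def __post_init__(self) -> None:
        if self.peak_time < self.onset_time:
            raise ValueError("peak_time must be >= onset_time")


@dataclass
class EventEnsemble:
    """Peak-aligned waveform matrix of screened events.

    ``matrix`` rows are baseline-subtracted event waveforms (pA) aligned at
    column ``align_index`` (the point of steepest rise); ``mean`` and
    ``sem`` are per-column statistics.
    """

    matrix: np.ndarray
    align_index: int
    dt: float
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.matrix.mean(axis=0)

    @property
    def sem(self) -> np.ndarray:
        if self.n_events < 2:
            return np.zeros(self.matrix.shape[1])
        return self.matrix.std(axis=0, ddof=1) / np.sqrt(self.n_events)

    @property
    def time(self) -> np.ndarray:
        """Time axis in ms, zero at the alignment point."""
        return (np.arange(self.matrix.shape[1]) - self.align_index) * self.dt


def _boxcar(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    kernel = np.ones(width) / width
    # reflect-pad so the ends are not biased toward zero
    pad = width // 2
    xp = np.pad(x, pad, mode="reflect")
    return np.convolve(xp, kernel, mode="same")[pad: pad + x.size]


def estimate_baseline_noise(
    recording: SweepRecording, window: Optional[float] = None
) -> tuple[float, float]:
    """Robust baseline level and noise SD (pA).

    Uses the median and the Gaussian-scaled median absolute deviation over
    either the first ``window`` ms of every sweep (which must be event- and
    stimulus-free) or, when ``window`` is None, over all samples; the MAD
    makes the estimate insensitive to sparse events.
    """
    if window is None:
        seg = recording.sweeps.ravel()
    else:
        n = int(round(window / recording.sampling_interval))
        if n < 20:
            raise ValueError("baseline window must span at least 20 samples")
        if recording.stimulus_times is not None:
            for stims in recording.stimulus_times:
                if np.any(stims < window):
                    raise ValueError("baseline window contains a stimulus")
        seg = recording.sweeps[:, :n].ravel()
    med = float(np.median(seg))
    mad = float(np.median(np.abs(seg - med)))
    return med, 1.4826 * mad


def detect_events(
    recording: SweepRecording,
    k: float = 3.0,
    noise_sd: Optional[float] = None,
    merge_ms: float = 1.0,
    smoothing_ms: float = 0.5,
) -> list[Event]:
    """Detect inward events by amplitude threshold crossing.

    The threshold is ``-k * noise_sd`` on the baseline-subtracted trace
    (baseline = per-sweep median).  One event is produced per contiguous
    supra-threshold excursion of the smoothed trace; excursions separated
    by less than ``merge_ms`` are merged.  The peak is the signed extremum
    of the raw excursion; the onset is the last pre-peak sample within one
    noise SD of baseline.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if noise_sd is None:
        _, noise_sd = estimate_baseline_noise(recording)
    if k < 2:
        warnings.warn("threshold below 2x noise SD: high false-positive regime",
                      stacklevel=2)
    dt = recording.sampling_interval
    width = max(1, int(round(smoothing_ms / dt)))
    merge_n = max(1, int(round(merge_ms / dt)))
    thr = -k * noise_sd
    events: list[Event] = []
    for s in range(recording.n_sweeps):
        raw = recording.sweeps[s]
        baseline = float(np.median(raw))
        x = raw - baseline
        xs = _boxcar(x, width)
        below = xs < thr
        if not below.any():
            continue
        idx = np.flatnonzero(below)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.r_[idx[0], idx[breaks + 1]]
        run_stops = np.r_[idx[breaks], idx[-1]] + 1
        # refractory merge of runs closer than merge_n
        merged = [[run_starts[0], run_stops[0]]]
        for a, b in zip(run_starts[1:], run_stops[1:]):
            if a - merged[-1][1] < merge_n:
                merged[-1][1] = b
            else:
                merged.append([a, b])
        for a, b in merged:
            # peak = signed extremum of the raw excursion (exact in the
            # low-noise limit; carries an ~+1 SD extremum bias when noisy)
            pk = a + int(np.argmin(x[a:b]))
            peak_amp = float(x[pk])
            # onset: last pre-peak sample within 1 SD of baseline
            onset = pk
            while onset > 0 and x[onset - 1] < -noise_sd:
                onset -= 1
            events.append(Event(
                sweep_index=s,
                onset_time=onset * dt,
                peak_time=pk * dt,
                peak_amplitude=peak_amp,
                local_baseline=baseline,
            ))
    return events


def screen_events(
    events: Sequence[Event],
    recording: SweepRecording,
    noise_sd: Optional[float] = None,
    k: float = 3.0,
    decay_window_ms: float = 10.0,
    boxcar: int = 3,
) -> list[Event]:
    """Set the ``monotonic_rise`` and ``clean_decay`` screening flags.

    monotonic_rise: the 3-sample-boxcar-smoothed trace has no slope sign
    reversal between onset and peak.  clean_decay: no further event onset
    occurs within ``decay_window_ms`` after the peak.
    """
    if noise_sd is None:
        _, noise_sd = estimate_baseline_noise(recording)
    dt = recording.sampling_interval
    by_sweep: dict[int, list[Event]] = {}
    for ev in events:
        by_sweep.setdefault(ev.sweep_index, []).append(ev)
    for s, evs in by_sweep.items():
        evs.sort(key=lambda e: e.peak_time)
        x = recording.sweeps[s] - evs[0].local_baseline
        xs = _boxcar(x, boxcar)
        for j, ev in enumerate(evs):
            i0 = int(round(ev.onset_time / dt))
            i1 = int(round(ev.peak_time / dt))
            seg = xs[i0: i1 + 1]
            # inward event: rising limb goes monotonically negative
            ev.monotonic_rise = bool(seg.size < 3 or np.all(np.diff(seg) <= 0))
            nxt = evs[j + 1] if j + 1 < len(evs) else None
            ev.clean_decay = not (
                nxt is not None
                and nxt.onset_time - ev.peak_time < decay_window_ms)
    return list(events)


def align_and_average(
    events: Sequence[Event],
    recording: SweepRecording,
    pre_ms: float = 2.0,
    post_ms: float = 12.0,
    screened_only: bool = True,
) -> EventEnsemble:
    """Align events at their point of steepest rise and average.

    Each event waveform is baseline-subtracted (median of the 1 ms before
    onset, falling back to the sweep baseline) and aligned at the sample of
    maximum |dI/dt| between onset and peak; events whose extraction window
    would leave the sweep are dropped.
    """
    use = [e for e in events
           if not screened_only or (e.monotonic_rise and e.clean_decay)]
    if not use:
        raise ValueError("no (screened) events to align")
    dt = recording.sampling_interval
    n_pre = int(round(pre_ms / dt))
    n_post = int(round(post_ms / dt))
    rows, kept = [], []
    for ev in use:
        x = recording.sweeps[ev.sweep_index] - ev.local_baseline
        i0 = int(round(ev.onset_time / dt))
        i1 = int(round(ev.peak_time / dt))
        if i1 <= i0:
            align = i1
        else:
            d = np.diff(_boxcar(x, 3)[i0: i1 + 1])
            align = i0 + int(np.argmin(d))  # steepest inward slope
        a, b = align - n_pre, align + n_post
        if a < 0 or b > x.size:
            continue
        base_lo = max(0, i0 - int(round(1.0 / dt)))
        local = float(np.median(x[base_lo: i0 + 1])) if i0 > base_lo else 0.0
        rows.append(x[a:b] - local)
        kept.append(ev)
    if not rows:
        raise ValueError("all events fell too close to sweep edges to align")
    return EventEnsemble(np.vstack(rows), align_index=n_pre, dt=dt, events=kept)
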