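"""Sr2+ quantal analysis, evoked-train analysis and the exact rank-sum test.

Replacing extracellular Ca2+ with Sr2+ desynchronises vesicle release, so
single quanta can be counted after each stimulus.  To avoid multiquantal
contamination only events peaking more than an exclusion window (10 ms by
default) after the stimulus are counted; event counting admits any distinct
peak, whereas amplitude statistics require a monotonic rise (overlapping
decays allowed) — two deliberately separate screening predicates.

Evoked trains are summarised by per-pulse amplitudes (with the preceding
pulse's extrapolated single-exponential decay subtracted), normalised to a
reference condition's first-pulse mean, and by the paired-pulse ratio
PPR = amplitude_2 / amplitude_1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy.stats import mannwhitneyu

from .detect import Event
from .io import SweepRecording
from .kinetics import ExponentialDecayModel


@dataclass
class QuantalSummary:
    """Per-session Sr2+ quantal-release summary."""

    per_sweep_counts: np.ndarray       # qEPSCs per sweep, post-exclusion
    initial_epsc_amplitude: float      # pA, mean synchronous peak, non-failure sweeps
    initial_epsc_amplitude_all: float  # pA, same but averaged over all sweeps
    failure_rate: float                # fraction of sweeps with no response
    qepsc_amplitudes: np.ndarray       # pA, monotonic-rise events
    mean_qepsc_amplitude: float        # pA
    n_sweeps: int = 0

    def summary(self) -> str:
        return "\n".join([
            "Sr2+ quantal-release analysis",
            "=" * 40,
            f"sweeps                  {self.n_sweeps:7d}",
            f"mean qEPSCs per sweep   {self.per_sweep_counts.mean():10.2f}",
            f"failure rate            {self.failure_rate:10.3f}",
            f"initial EPSC (non-fail) {self.initial_epsc_amplitude:10.2f} pA",
            f"mean qEPSC amplitude    {self.mean_qepsc_amplitude:10.2f} pA",
        ])


@dataclass
class TrainResult:
    """Per-condition evoked-train summary."""

    condition: str
    per_pulse_amplitudes: np.ndarray    # pA, mean over sweeps
    normalized_amplitudes: np.ndarray   # / reference first-pulse amplitude
    ppr_2_1: float
    reference_condition: str

    def summary(self) -> str:
        amps = ", ".join(f"{a:.2f}" for a in self.per_pulse_amplitudes)
        norm = ", ".join(f"{a:.3f}" for a in self.normalized_amplitudes)
        return "\n".join([
            f"Evoked train: {self.condition} "
            f"(normalised to {self.reference_condition})",
            "=" * 50,
            f"amplitudes (pA)  {amps}",
            f"normalised       {norm}",
            f"PPR 2/1          {self.ppr_2_1:8.3f}",
        ])


def analyze_sr2_session(
    recording: SweepRecording,
    events: Sequence[Event],
    exclusion_ms: float = 10.0,
) -> QuantalSummary:
    """Count and size asynchronous quanta in a Sr2+ session.

    Requires exactly one stimulus time per sweep.  Counts use every
    detected event peaking > ``exclusion_ms`` after the stimulus;
    amplitudes additionally require the monotonic-rise flag; a failure
    sweep has no detected post-stimulus event at all.  Also sets each
    event's ``post_stimulus_ok`` flag.
    """
    if recording.stimulus_times is None:
        raise ValueError("recording has no stimulus times")
    stims = []
    for s, st in enumerate(recording.stimulus_times):
        if st.size != 1:
            raise ValueError(f"sweep {s}: expected exactly one stimulus")
        stims.append(float(st[0]))
    n_sweeps = recording.n_sweeps
    counts = np.zeros(n_sweeps, dtype=int)
    responded = np.zeros(n_sweeps, dtype=bool)
    initial: dict[int, float] = {}
    q_amps = []
    for ev in events:
        t0 = stims[ev.sweep_index]
        if ev.peak_time <= t0:
            continue
        responded[ev.sweep_index] = True
        lag = ev.peak_time - t0
        ev.post_stimulus_ok = lag > exclusion_ms
        if ev.post_stimulus_ok:
            counts[ev.sweep_index] += 1
            if ev.monotonic_rise:
                q_amps.append(ev.peak_amplitude)
        else:
            # synchronous window: keep the largest-magnitude peak
            prev = initial.get(ev.sweep_index)
            if prev is None or abs(ev.peak_amplitude) > abs(prev):
                initial[ev.sweep_index] = ev.peak_amplitude
    failure_rate = float(1.0 - responded.mean())
    init_vals = np.array(list(initial.values()), dtype=float)
    init_nonfail = float(init_vals.mean()) if init_vals.size else np.nan
    init_all = float(init_vals.sum() / n_sweeps) if n_sweeps else np.nan
    q_amps = np.asarray(q_amps, dtype=float)
    return QuantalSummary(
        per_sweep_counts=counts,
        initial_epsc_amplitude=init_nonfail,
        initial_epsc_amplitude_all=init_all,
        failure_rate=failure_rate,
        qepsc_amplitudes=q_amps,
        mean_qepsc_amplitude=float(q_amps.mean()) if q_amps.size else np.nan,
        n_sweeps=n_sweeps,
    )


def _pulse_amplitudes(
    recording: SweepRecording,
    n_pulses: int,
    window_ms: float,
) -> np.ndarray:
    """Per-pulse mean amplitudes (pA) with prior-decay subtraction.

    The condition-mean trace supplies a single-exponential extrapolation of
    each pulse's decay, which is subtracted before the next pulse's peak is
    measured on every sweep; per-pulse amplitude is the mean over sweeps of
    the baseline-subtracted corrected peak.
    """
    dt = recording.sampling_interval
    stims = recording.stimulus_times[0]
    if any(not np.array_equal(st, stims) for st in recording.stimulus_times):
        raise ValueError("all sweeps must share the same stimulus times")
    if stims.size < n_pulses:
        raise ValueError("fewer stimulus times than pulses requested")
    base_n = max(1, int(round(stims[0] / dt)))
    mean_trace = recording.sweeps.mean(axis=0)
    baseline = float(np.median(mean_trace[:base_n]))
    mean_trace = mean_trace - baseline
    sweeps = recording.sweeps - baseline
    # per-pulse correction trace accumulated from extrapolated decays
    correction = np.zeros(mean_trace.size)
    amps = np.empty(n_pulses)
    t_all = np.arange(mean_trace.size) * dt
    for j in range(n_pulses):
        a = int(round(stims[j] / dt))
        b = int(round((stims[j] + window_ms) / dt)) if j + 1 >= stims.size else \
            int(round(stims[j + 1] / dt))
        b = min(b, mean_trace.size)
        corrected_mean = mean_trace[a:b] - correction[a:b]
        pk_rel = int(np.argmin(corrected_mean))
        pk = a + pk_rel
        sweep_peaks = sweeps[:, pk] - correction[pk]
        amps[j] = float(sweep_peaks.mean())
        # fit this pulse's decay on the corrected mean trace, extrapolate
        decay = corrected_mean[pk_rel:]
        if decay.size >= 20:
            try:
                fitres = ExponentialDecayModel(decay, dt).fit(model="single")
                t_rel = t_all[pk:] - t_all[pk]
                correction[pk:] += fitres.amplitude * np.exp(
                    -t_rel / fitres.tau_fast)
            except Exception:   # short/degenerate decays: skip correction
                pass
    return amps


def analyze_train(
    recordings: dict[str, SweepRecording],
    n_pulses: int = 5,
    reference: str = "",
    window_ms: float = 8.0,
    min_sweeps: int = 5,
) -> dict[str, TrainResult]:
    """Analyse evoked trains per condition, normalised to ``reference``.

    Each recording must carry identical stimulus times on every sweep and
    at least ``min_sweeps`` sweeps.  Amplitudes are normalised to the mean
    first-pulse amplitude of the reference condition; PPR is computed
    within condition.
    """
    if reference not in recordings:
        raise ValueError(f"reference condition {reference!r} absent")
    for name, rec in recordings.items():
        if rec.stimulus_times is None:
            raise ValueError(f"condition {name!r} has no stimulus times")
        if rec.n_sweeps < min_sweeps:
            raise ValueError(f"condition {name!r} has fewer than "
                             f"{min_sweeps} sweeps")
    amps = {name: _pulse_amplitudes(rec, n_pulses, window_ms)
            for name, rec in recordings.items()}
    ref_amp = amps[reference][0]
    if ref_amp == 0:
        raise ValueError("reference first-pulse amplitude is zero")
    out = {}
    for name, a in amps.items():
        out[name] = TrainResult(
            condition=name,
            per_pulse_amplitudes=a,
            normalized_amplitudes=a / ref_amp,
            ppr_2_1=float(a[1] / a[0]),
            reference_condition=reference,
        )
    return out


class RankSumResult(NamedTuple):
    statistic: float   # Mann-Whitney count of (x_i > y_j) pairs, +1/2 per tie
    pvalue: float      # two-sided; exact when n_x*n_y <= 10,000 and no ties


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The exact permutation null is used when ``n_x * n_y <= 10,000`` and the
    pooled sample has no ties; otherwise a mid-rank normal approximation
    with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size * y.size <= 10_000 and no_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method,
                       use_continuity=True)
    return RankSumResult(statistic=float(res.statistic),
                         pvalue=float(res.pvalue))


def minimal_stimulation_ok(
    failure_rate: float,
    latencies_ms: Sequence[float],
    amplitudes_pa: Sequence[float],
    target_failure: float = 0.3,
    failure_tol: float = 0.15,
    latency_cv_max: float = 0.25,
    amplitude_cv_max: float = 0.5,
) -> bool:
    """Data-screening predicate for minimal (single-fiber) stimulation.

    Accepts a cell when the initial failure rate is near ~30% and the
    evoked latency and amplitude are invariant (coefficient of variation
    under the stated tolerances).  This is a screen, not an analysis stage.
    """
    lat = np.asarray(latencies_ms, dtype=float)
    amp = np.abs(np.asarray(amplitudes_pa, dtype=float))
    if lat.size < 2 or amp.size < 2:
        return False
    if abs(failure_rate - target_failure) > failure_tol:
        return False
    if lat.mean() <= 0 or amp.mean() <= 0:
        return False
    if lat.std(ddof=1) / lat.mean() > latency_cv_max:
        return False
    return amp.std(ddof=1) / amp.mean() <= amplitude_cv_max
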