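"""Synthetic-data generators with known ground truth.

Every analysis stage in the package has a generator here that produces its
input together with a ground-truth table, so parameter recovery can be
tested end to end.  The central piece is a stochastic channel-gating model
of a quantal synaptic current: all ``n_channels`` channels open at event
onset (scaled by a deterministic rise envelope ``1 - exp(-t/tau_rise)``)
and each closes after an independent exponential lifetime ``tau_decay``.
The instantaneous current is ``unitary_current`` times the number of
channels still open, so at any decay time the open count is binomial and
the ensemble peak-scaled variance follows the parabola

    sigma^2(I) = i*I - I^2/N_p

exactly, which is the analytic oracle the fluctuation analysis is tested
against.  No channel reopening, multi-state gating, temperature dependence
or dendritic filtering is modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import IVRamp, SweepRecording

logger = logging.getLogger(__name__)

DIAMETER_FLOOR_NM = 10.0  # hard lower bound for truncated-normal diameters


@dataclass
class QuantalModel:
    """Channel-gating model of a single quantal event.

    Parameters
    ----------
    n_channels : int
        Channels open at the event peak (N_p >= 1).
    unitary_current : float
        Single-channel current at the holding potential, pA (inward
        negative at negative potentials).
    tau_rise : float
        Activation envelope time constant, ms.
    tau_decay : float
        Mean channel open lifetime, ms; also the ensemble decay constant.
    e_rev : float
        Reversal potential, mV.
    """

    n_channels: int = 20
    unitary_current: float = -0.69
    tau_rise: float = 0.15
    tau_decay: float = 1.3
    e_rev: float = 0.0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not (self.tau_rise > 0 and self.tau_decay > 0):
            raise ValueError("tau_rise and tau_decay must be positive")
        if self.unitary_current == 0:
            raise ValueError("unitary_current must be nonzero")

    @property
    def peak_current(self) -> float:
        """Nominal peak current i*N_p in pA."""
        return self.unitary_current * self.n_channels

    def check_sign(self, holding_potential: float) -> None:
        """Check the unitary current sign against the driving force."""
        drive = holding_potential - self.e_rev
        if drive != 0 and np.sign(self.unitary_current) != np.sign(drive):
            raise ValueError(
                "unitary_current sign inconsistent with holding potential "
                f"({holding_potential} mV) relative to E_rev ({self.e_rev} mV)")


@dataclass
class Depletion:
    """Vesicle-depletion parameters: release fraction f and recovery tau (ms)."""

    release_fraction: float
    tau_recovery: float

    def __post_init__(self) -> None:
        if not (0 < self.release_fraction <= 1):
            raise ValueError("release_fraction must be in (0, 1]")
        if self.tau_recovery < 0:
            raise ValueError("tau_recovery must be >= 0")


@dataclass
class Sr2Release:
    """Sr2+-like release profile: a synchronous EPSC at the stimulus followed
    by asynchronous quanta with an exponentially decaying rate."""

    sync_amplitude: float = -50.0   # pA, synchronous component peak
    async_rate: float = 100.0       # Hz, asynchronous rate just after stimulus
    async_tau: float = 50.0         # ms, decay of the asynchronous rate
    failure_prob: float = 0.0       # per-sweep probability of complete failure
    stim_time: float = 20.0         # ms, stimulus time within each sweep

    def __post_init__(self) -> None:
        if self.async_rate < 0 or self.async_tau <= 0:
            raise ValueError("async rate must be >= 0 and tau > 0")
        if not (0 <= self.failure_prob <= 1):
            raise ValueError("failure_prob must be in [0, 1]")

    def expected_async_count(self, duration_after_stim: float) -> float:
        """Integral of the rate profile over the post-stimulus window."""
        return (self.async_rate / 1000.0) * self.async_tau * (
            1.0 - np.exp(-duration_after_stim / self.async_tau))


@dataclass
class SessionModel:
    """Recording-session parameters for the waveform generators."""

    event_rate: float = 3.0         # Hz, mean spontaneous event rate
    noise_sd: float = 1.0           # pA, Gaussian baseline noise SD
    sweep_duration: float = 1000.0  # ms
    n_sweeps: int = 60
    depletion: Optional[Depletion] = None
    sr2_release: Optional[Sr2Release] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.event_rate < 0 or self.noise_sd < 0:
            raise ValueError("event_rate and noise_sd must be >= 0")
        if self.sweep_duration <= 0 or self.n_sweeps < 1:
            raise ValueError("sweep_duration and n_sweeps must be positive")


# ---------------------------------------------------------------------------
# Quantal event and mEPSC recordings
# ---------------------------------------------------------------------------

def quantal_event_support_ms(model: QuantalModel) -> float:
    """Practical event span: rise plus ~8 decay lifetimes."""
    return 5.0 * model.tau_rise + 8.0 * model.tau_decay


def simulate_quantal_event(
    model: QuantalModel,
    dt: float,
    rng: np.random.Generator,
    duration: Optional[float] = None,
) -> np.ndarray:
    """Simulate one stochastic quantal event waveform (pA).

    All channels are assigned independent exponential lifetimes at onset;
    the current is ``unitary_current * n_open(t)`` scaled by the rise
    envelope.  Returns the sampled waveform starting at onset (t=0).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration is None:
        duration = quantal_event_support_ms(model)
    t = np.arange(int(round(duration / dt))) * dt
    lifetimes = np.sort(rng.exponential(model.tau_decay, size=model.n_channels))
    n_open = model.n_channels - np.searchsorted(lifetimes, t, side="right")
    envelope = 1.0 - np.exp(-t / model.tau_rise)
    return model.unitary_current * envelope * n_open


def mean_event_waveform(model: QuantalModel, dt: float,
                        duration: Optional[float] = None) -> np.ndarray:
    """Ensemble-mean event waveform i*N_p*(1-exp(-t/tau_r))*exp(-t/tau_d)."""
    if duration is None:
        duration = quantal_event_support_ms(model)
    t = np.arange(int(round(duration / dt))) * dt
    return (model.peak_current * (1.0 - np.exp(-t / model.tau_rise))
            * np.exp(-t / model.tau_decay))


def _add_event(trace: np.ndarray, start: int, wave: np.ndarray) -> None:
    stop = min(start + wave.size, trace.size)
    if stop > start >= 0:
        trace[start:stop] += wave[: stop - start]


def simulate_mepsc_recording(
    model: QuantalModel,
    session: SessionModel,
    dt: float = 0.05,
    holding_potential: float = -60.0,
) -> tuple[SweepRecording, pd.DataFrame]:
    """Simulate a spontaneous mEPSC recording.

    Events occur as a homogeneous Poisson process at ``session.event_rate``
    on Gaussian baseline noise.  Returns the recording and a ground-truth
    table with columns ``sweep, onset_ms, peak_pA, overlapping``.

    A warning is logged if more than half of the events overlap a
    neighbour within one event support.
    """
    model.check_sign(holding_potential)
    rng = np.random.default_rng(session.seed)
    n_samples = int(round(session.sweep_duration / dt))
    support = quantal_event_support_ms(model)
    sweeps = rng.normal(0.0, session.noise_sd,
                        size=(session.n_sweeps, n_samples))
    rows = []
    for s in range(session.n_sweeps):
        n_ev = rng.poisson(session.event_rate * session.sweep_duration / 1000.0)
        onsets = np.sort(rng.uniform(0.0, session.sweep_duration, size=n_ev))
        for onset in onsets:
            wave = simulate_quantal_event(model, dt, rng)
            start = int(round(onset / dt))
            _add_event(sweeps[s], start, wave)
            peak = wave.min() if model.unitary_current < 0 else wave.max()
            rows.append((s, onset, peak))
    truth = pd.DataFrame(rows, columns=["sweep", "onset_ms", "peak_pA"])
    overlap = np.zeros(len(truth), dtype=bool)
    for s, grp in truth.groupby("sweep"):
        o = grp["onset_ms"].to_numpy()
        close = np.zeros(o.size, dtype=bool)
        if o.size > 1:
            gaps = np.diff(o)
            close[:-1] |= gaps < support
            close[1:] |= gaps < support
        overlap[grp.index] = close
    truth["overlapping"] = overlap
    if len(truth) and overlap.mean() > 0.5:
        logger.warning("event rate %.3g Hz: %.0f%% of events overlap",
                       session.event_rate, 100 * overlap.mean())
    rec = SweepRecording(dt, sweeps, holding_potential=holding_potential,
                         label="simulated mEPSC recording")
    return rec, truth


# ---------------------------------------------------------------------------
# I-V ramps
# ---------------------------------------------------------------------------

def simulate_iv_ramp(
    g_neg: float,
    g_pos: float,
    v_range: tuple[float, float] = (-90.0, 60.0),
    noise_sd: float = 0.0,
    n_points: int = 751,
    blend_mv: float = 20.0,
    seed: int = 0,
) -> IVRamp:
    """Simulate a leak-subtracted I-V ramp with configurable rectification.

    The chord conductance is ``g_neg`` (nS) for V <= -blend_mv and ``g_pos``
    for V >= +blend_mv, joined by a C1 cubic Hermite blend between, with
    E_rev = 0; so the slope conductances measured strictly outside the blend
    are exact and the ground-truth rectification index is ``g_pos/g_neg``.
    """
    if g_neg < 0 or g_pos < 0:
        raise ValueError("conductances must be >= 0")
    v = np.linspace(v_range[0], v_range[1], n_points)
    i = np.where(v <= -blend_mv, g_neg * v, g_pos * v)
    mid = (v > -blend_mv) & (v < blend_mv)
    if mid.any():
        # Hermite blend matching value and slope at +/- blend_mv
        x = (v[mid] + blend_mv) / (2 * blend_mv)
        h = x * x * (3 - 2 * x)
        y0, y1 = -g_neg * blend_mv, g_pos * blend_mv
        m0, m1 = g_neg * 2 * blend_mv, g_pos * 2 * blend_mv
        h00 = 2 * x**3 - 3 * x**2 + 1
        h10 = x**3 - 2 * x**2 + x
        h01 = -2 * x**3 + 3 * x**2
        h11 = x**3 - x**2
        i[mid] = h00 * y0 + h10 * m0 + h01 * y1 + h11 * m1
    if noise_sd > 0:
        i = i + np.random.default_rng(seed).normal(0.0, noise_sd, size=v.size)
    return IVRamp(v, i, leak_subtracted=True)


# ---------------------------------------------------------------------------
# Sr2+ asynchronous-release sessions
# ---------------------------------------------------------------------------

def simulate_sr2_session(
    model: QuantalModel,
    session: SessionModel,
    dt: float = 0.05,
    holding_potential: float = -70.0,
) -> tuple[SweepRecording, pd.DataFrame]:
    """Simulate a Sr2+-substitution quantal-release session.

    Each sweep carries one stimulus.  On non-failure sweeps a synchronous
    EPSC (the scaled mean quantal waveform) occurs at the stimulus, followed
    by asynchronous single quanta timed by an inhomogeneous Poisson process
    with rate ``async_rate * exp(-(t - t_stim)/async_tau)``.  Returns the
    recording (with stimulus times) and a truth table with columns
    ``sweep, time_ms, kind in {sync, async}, failure``.
    """
    if session.sr2_release is None:
        raise ValueError("session.sr2_release must be configured")
    model.check_sign(holding_potential)
    sr2 = session.sr2_release
    rng = np.random.default_rng(session.seed)
    n_samples = int(round(session.sweep_duration / dt))
    sweeps = rng.normal(0.0, session.noise_sd,
                        size=(session.n_sweeps, n_samples))
    t_stim = sr2.stim_time
    tail = session.sweep_duration - t_stim
    mean_wave = mean_event_waveform(model, dt)
    mean_peak = mean_wave.min() if model.unitary_current < 0 else mean_wave.max()
    rows = []
    for s in range(session.n_sweeps):
        if rng.uniform() < sr2.failure_prob:
            rows.append((s, np.nan, "none", True))
            continue
        if sr2.sync_amplitude != 0:
            sync = mean_wave * (sr2.sync_amplitude / mean_peak)
            _add_event(sweeps[s], int(round(t_stim / dt)), sync)
            rows.append((s, t_stim, "sync", False))
        n_async = rng.poisson(sr2.expected_async_count(tail))
        # inverse-CDF sampling of the truncated exponential rate profile
        u = rng.uniform(size=n_async)
        cmax = 1.0 - np.exp(-tail / sr2.async_tau)
        times = t_stim - sr2.async_tau * np.log1p(-u * cmax)
        for t_ev in np.sort(times):
            wave = simulate_quantal_event(model, dt, rng)
            _add_event(sweeps[s], int(round(t_ev / dt)), wave)
            rows.append((s, t_ev, "async", False))
    truth = pd.DataFrame(rows, columns=["sweep", "time_ms", "kind", "failure"])
    rec = SweepRecording(
        dt, sweeps, holding_potential=holding_potential,
        stimulus_times=[np.array([t_stim])] * session.n_sweeps,
        label="simulated Sr2+ session")
    return rec, truth


# ---------------------------------------------------------------------------
# Stimulus trains with vesicle depletion
# ---------------------------------------------------------------------------

def depletion_resources(n_pulses: int, f: float, tau_rec: float,
                        dt_ms: float) -> np.ndarray:
    """Readily-releasable resource fraction R_n before each pulse.

    R_1 = 1 and R_{n+1} = R_n(1-f) + (1 - R_n(1-f)) * (1 - exp(-dt/tau_rec)),
    i.e. a fraction f of resources is spent per pulse and the deficit
    recovers exponentially between pulses.  0 < R_n <= 1 for all n.
    """
    if n_pulses < 1:
        raise ValueError("n_pulses must be >= 1")
    r = np.empty(n_pulses)
    r[0] = 1.0
    recov = 1.0 - np.exp(-dt_ms / tau_rec) if tau_rec > 0 else 1.0
    for n in range(1, n_pulses):
        left = r[n - 1] * (1.0 - f)
        r[n] = left + (1.0 - left) * recov
    return r


def simulate_train(
    model: QuantalModel,
    n_pulses: int = 5,
    freq: float = 100.0,
    depletion: Depletion = Depletion(0.5, 200.0),
    n_sweeps: int = 20,
    noise_sd: float = 1.0,
    first_amplitude: float = -100.0,
    dt: float = 0.05,
    pre_ms: float = 10.0,
    tail_ms: float = 30.0,
    holding_potential: float = -70.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SweepRecording]:
    """Simulate evoked-EPSC trains with vesicle-depletion depression.

    Per-pulse amplitudes are proportional to ``f * R_n`` with R_n from
    :func:`depletion_resources`, scaled so pulse 1 has ``first_amplitude``
    (pA).  Each sweep superimposes the deterministic train on Gaussian
    noise.  Returns (truth table with pulse, time_ms, amplitude_pA and the
    ground-truth PPR, recording with per-sweep stimulus times).
    """
    if n_pulses < 2:
        raise ValueError("n_pulses must be >= 2")
    isi = 1000.0 / freq
    r = depletion_resources(n_pulses, depletion.release_fraction,
                            depletion.tau_recovery, isi)
    amps = first_amplitude * (r * depletion.release_fraction) / (
        depletion.release_fraction * r[0])
    stim_times = pre_ms + np.arange(n_pulses) * isi
    duration = pre_ms + (n_pulses - 1) * isi + tail_ms
    rng = np.random.default_rng(seed)
    n_samples = int(round(duration / dt))
    mean_wave = mean_event_waveform(model, dt)
    mean_peak = mean_wave.min() if model.unitary_current < 0 else mean_wave.max()
    sweeps = rng.normal(0.0, noise_sd, size=(n_sweeps, n_samples))
    for s in range(n_sweeps):
        for a, t0 in zip(amps, stim_times):
            _add_event(sweeps[s], int(round(t0 / dt)), mean_wave * (a / mean_peak))
    truth = pd.DataFrame({
        "pulse": np.arange(1, n_pulses + 1),
        "time_ms": stim_times,
        "amplitude_pA": amps,
    })
    truth.attrs["ppr_2_1"] = float(amps[1] / amps[0])
    rec = SweepRecording(
        dt, sweeps, holding_potential=holding_potential,
        stimulus_times=[stim_times.copy() for _ in range(n_sweeps)],
        label="simulated train")
    return truth, rec


# ---------------------------------------------------------------------------
# EM terminal annotations
# ---------------------------------------------------------------------------

def simulate_terminal(
    density_per_um2: float = 131.7,
    diameter_mean_nm: float = 33.5,
    diameter_sd_nm: float = 3.0,
    terminal_polygon: Optional[Sequence[tuple[float, float]]] = None,
    organelle_polygons: Sequence[Sequence[tuple[float, float]]] = (),
    az_polylines: Sequence[Sequence[tuple[float, float]]] = (),
    proximal_enrichment: float = 0.0,
    proximity_nm: float = 100.0,
    seed: int = 0,
):
    """Simulate a 2-D annotated presynaptic terminal.

    Vesicle centres form a homogeneous Poisson pattern of intensity
    ``density_per_um2`` inside the terminal polygon and outside organelles;
    diameters are truncated-normal with a hard floor of 10 nm.  If
    ``proximal_enrichment`` > 0, that many extra vesicles per 50 nm of
    active-zone length are added uniformly in the <``proximity_nm`` band
    around each active zone.  Default geometry is a square terminal of
    10 μm².  Returns a :class:`~epsckit.em.TerminalAnnotation`.
    """
    from shapely.geometry import LineString, Point, Polygon

    from .em import TerminalAnnotation

    if density_per_um2 < 0:
        raise ValueError("density must be >= 0")
    rng = np.random.default_rng(seed)
    if terminal_polygon is None:
        side = np.sqrt(10.0) * 1000.0  # 10 um^2 square, nm
        terminal_polygon = [(0, 0), (side, 0), (side, side), (0, side)]
    term = Polygon(terminal_polygon)
    if not term.is_valid or term.area == 0:
        raise ValueError("degenerate terminal polygon")
    organelles = [Polygon(p) for p in organelle_polygons]
    for org in organelles:
        if not org.is_valid or org.area == 0:
            raise ValueError("degenerate organelle polygon")
    azs = [LineString(a) for a in az_polylines]

    free = term
    for org in organelles:
        free = free.difference(org)
    n = rng.poisson(density_per_um2 * free.area / 1e6)  # nm^2 -> um^2
    xs, ys = [], []
    minx, miny, maxx, maxy = term.bounds
    while len(xs) < n:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(2 * (n - len(xs)) + 8, 2))
        for x, y in cand:
            if free.contains(Point(x, y)):
                xs.append(x)
                ys.append(y)
                if len(xs) == n:
                    break
    if proximal_enrichment > 0 and azs:
        for az in azs:
            target = int(round(proximal_enrichment * az.length / 50.0))
            band = az.buffer(proximity_nm * 0.999).intersection(free)
            bminx, bminy, bmaxx, bmaxy = band.bounds
            added = 0
            while added < target:
                x = rng.uniform(bminx, bmaxx)
                y = rng.uniform(bminy, bmaxy)
                if band.contains(Point(x, y)):
                    xs.append(x)
                    ys.append(y)
                    added += 1
    a, b = ((DIAMETER_FLOOR_NM - diameter_mean_nm) / diameter_sd_nm, np.inf)
    diam = sps.truncnorm.rvs(a, b, loc=diameter_mean_nm, scale=diameter_sd_nm,
                             size=len(xs), random_state=rng)
    return TerminalAnnotation(
        terminal=list(term.exterior.coords),
        organelles=[list(o.exterior.coords) for o in organelles],
        active_zones=[list(a_.coords) for a_ in azs],
        vesicles=pd.DataFrame({"x_nm": xs, "y_nm": ys, "diameter_nm": diam}),
        scale_nm_per_px=1.0,
        label="synthetic terminal",
    )
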