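"""End-to-end parameter-recovery experiments on synthetic data.

Each function sets up the generator at its documented reference condition
(the wild-type cultured-granule-cell working point: 11.5 pS unitary chord
conductance at -60 mV from 20 channels, 1.27 ms weighted decay, 131.7
vesicles per μm², 33.5 nm mean vesicle diameter), runs the full measurement
chain and returns the recovered quantity.  They back both the acceptance
checks and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import detect as _detect
from . import em as _em
from . import kinetics as _kinetics
from . import psnsfa as _psnsfa
from . import simulate as _sim

#: Reference (wild-type-like) working point used by the recovery runs.
REFERENCE = {
    "gamma_pS": 11.5,          # unitary chord conductance at -60 mV
    "unitary_pA": -0.69,       # = 11.5 pS * 60 mV
    "n_channels": 20,
    "tau_decay_ms": 1.3,
    "tau_w_ms": 1.27,          # weighted decay of the averaged mEPSC
    "density_per_um2": 131.7,  # vesicles per um^2
    "diameter_nm": 33.5,
}


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, 2**31 - 1, size=n)


def recover_gamma_once(seed: int, n_events: int = 500,
                       noise_sd: float = 1.0) -> float:
    """One detection + ps-NSFA chain on a simulated mEPSC session.

    Simulates ~``n_events`` quantal events at the reference working point
    on Gaussian noise, detects and screens them, aligns at the steepest
    rise and fits the 30-bin peak-scaled parabola.  Returns the recovered
    chord conductance in pS.
    """
    model = _sim.QuantalModel(
        n_channels=REFERENCE["n_channels"],
        unitary_current=REFERENCE["unitary_pA"],
        tau_rise=0.15, tau_decay=REFERENCE["tau_decay_ms"])
    rate = 4.0  # Hz; sized so the session yields ~n_events events
    session = _sim.SessionModel(
        event_rate=rate, noise_sd=noise_sd, sweep_duration=1000.0,
        n_sweeps=int(round(n_events / rate)), seed=seed)
    rec, _ = _sim.simulate_mepsc_recording(model, session)
    _, sd = _detect.estimate_baseline_noise(rec)
    events = _detect.detect_events(rec, k=3.0, noise_sd=sd)
    _detect.screen_events(events, rec, noise_sd=sd)
    ensemble = _detect.align_and_average(events, rec)
    result = _psnsfa.peak_scaled_nsfa(ensemble, n_bins=30, voltage=-60.0)
    return result.gamma


def recover_gamma(seed: int = 1, n_seeds: int = 20,
                  n_events: int = 500) -> float:
    """Median recovered chord conductance (pS) over ``n_seeds`` sessions."""
    gammas = [recover_gamma_once(int(s), n_events=n_events)
              for s in _spawn_seeds(seed, n_seeds)]
    return float(np.median(gammas))


def recover_tau_w(frac_fast: float = 0.75, tau_fast: float = 0.9,
                  dt: float = 0.02) -> float:
    """Fit a noiseless biexponential whose analytic weighted decay equals
    the reference 1.27 ms; returns the fitted tau_w (ms).

    With fractions 0.75/0.25 and tau_fast 0.9 ms the slow constant is
    chosen so frac_fast*tau_fast + frac_slow*tau_slow = 1.27 ms exactly.
    """
    frac_slow = 1.0 - frac_fast
    tau_slow = (REFERENCE["tau_w_ms"] - frac_fast * tau_fast) / frac_slow
    t = np.arange(0.0, 20.0, dt)
    y = -10.0 * (frac_fast * np.exp(-t / tau_fast)
                 + frac_slow * np.exp(-t / tau_slow))
    return _kinetics.fit_decay(y, dt, model="double").tau_w


def recover_density(seed: int = 1, n_seeds: int = 20) -> float:
    """Mean grid-based vesicle density (per μm²) over synthetic terminals
    generated at the reference density in a 10 μm² terminal."""
    densities = []
    for s in _spawn_seeds(seed, n_seeds):
        ann = _sim.simulate_terminal(
            density_per_um2=REFERENCE["density_per_um2"], seed=int(s))
        d, _ = _em.grid_density(ann, square_area_um2=0.1)
        densities.append(d)
    return float(np.mean(densities))


def recover_diameter(seed: int = 1) -> float:
    """Per-terminal mean vesicle diameter (nm) from ~1,000 truncated-normal
    diameters generated at the reference mean (SD 3 nm, floor 10 nm)."""
    ann = _sim.simulate_terminal(
        density_per_um2=100.0,  # ~1,000 vesicles in the 10 um^2 terminal
        diameter_mean_nm=REFERENCE["diameter_nm"], diameter_sd_nm=3.0,
        seed=seed)
    mean, _, _ = _em.diameter_stats(ann)
    return mean
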