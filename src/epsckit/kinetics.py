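"""Event kinetics: 10-90% rise time, exponential decay fits, conductance.

The decay of an averaged event is fitted with a double exponential
``A_f exp(-t/tau_f) + A_s exp(-t/tau_s)`` and summarised by the weighted
time constant ``tau_w = (A_f tau_f + A_s tau_s)/(A_f + A_s)``; when a
single exponential describes the data adequately (by BIC) it is preferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge from any start."""


@dataclass
class DecayFit:
    """Results of an exponential decay fit.

    ``tau_fast <= tau_slow``; ``frac_fast + frac_slow = 1``; for a single
    exponential ``tau_w == tau_fast`` and ``frac_fast == 1``.
    """

    tau_fast: float
    tau_slow: float
    frac_fast: float
    frac_slow: float
    tau_w: float
    model: str            # "single" or "double"
    rss: float            # residual sum of squares, pA^2
    amplitude: float      # fitted amplitude at t=0, pA (signed)
    n_samples: int = 0

    def summary(self) -> str:
        lines = [
            "Exponential decay fit",
            "=" * 42,
            f"model            {self.model}",
            f"tau_fast         {self.tau_fast:10.4f} ms",
        ]
        if self.model == "double":
            lines += [
                f"tau_slow         {self.tau_slow:10.4f} ms",
                f"frac_fast        {self.frac_fast:10.4f}",
                f"frac_slow        {self.frac_slow:10.4f}",
            ]
        lines += [
            f"tau_w            {self.tau_w:10.4f} ms",
            f"amplitude        {self.amplitude:10.4f} pA",
            f"rss              {self.rss:10.6g} pA^2",
            f"n                {self.n_samples:7d}",
        ]
        return "\n".join(lines)


def _bic(rss: float, n: int, k: int, scale: float) -> float:
    # guard the noiseless case: floor rss at numerical precision of the data
    floor = n * (1e-12 * max(scale, 1.0)) ** 2
    return n * np.log(max(rss, floor) / n) + k * np.log(n)


class ExponentialDecayModel:
    """Single/double exponential decay model for a post-peak waveform.

    Parameters
    ----------
    y : ndarray
        Decay-phase samples (pA, signed; first sample is the peak).
    dt : float
        Sample interval, ms.

    ``fit()`` performs multistart nonlinear least squares and selects
    single vs double exponential by BIC (ties favour the simpler model).
    """

    def __init__(self, y: np.ndarray, dt: float):
        y = np.asarray(y, dtype=float)
        if dt <= 0:
            raise ValueError("dt must be positive")
        if y.size < 20:
            raise ValueError("need >= 20 samples in the decay-fit window")
        self.y = y
        self.dt = dt
        self.t = np.arange(y.size) * dt

    # initial tau from the first e-fold time of the (signed) decay
    def _tau0(self) -> float:
        y0 = self.y[0]
        if y0 == 0:
            return max(self.dt, self.t[-1] / 5)
        frac = self.y / y0
        below = np.flatnonzero(frac < np.exp(-1.0))
        if below.size:
            return max(self.dt, self.t[below[0]])
        return max(self.dt, self.t[-1] / 3)

    def _fit_single(self) -> tuple[np.ndarray, float]:
        y0, tau0 = self.y[0], self._tau0()
        best, best_rss = None, np.inf
        for fac in (1.0, 0.5, 2.0):
            try:
                p, _ = curve_fit(
                    lambda t, a, tau: a * np.exp(-t / tau),
                    self.t, self.y, p0=(y0, tau0 * fac),
                    bounds=([-np.inf, self.dt * 1e-3], [np.inf, np.inf]),
                    maxfev=10000)
            except RuntimeError:
                continue
            rss = float(np.sum((self.y - p[0] * np.exp(-self.t / p[1])) ** 2))
            if rss < best_rss:
                best, best_rss = p, rss
        if best is None:
            raise FitError("single-exponential fit did not converge")
        return best, best_rss

    def _fit_double(self, rng: np.random.Generator) -> tuple[np.ndarray, float]:
        y0, tau0 = self.y[0], self._tau0()
        # both amplitude components share the sign of the decay, which keeps
        # the fractional amplitudes in [0, 1] and excludes the degenerate
        # equal-tau/opposite-amplitude solution
        if y0 < 0:
            lo = [-np.inf, self.dt * 1e-3, -np.inf, self.dt * 1e-3]
            hi = [0.0, np.inf, 0.0, np.inf]
        else:
            lo = [0.0, self.dt * 1e-3, 0.0, self.dt * 1e-3]
            hi = [np.inf] * 4

        def f(t, af, tf, as_, ts):
            return af * np.exp(-t / tf) + as_ * np.exp(-t / ts)

        best, best_rss = None, np.inf
        starts = [(0.7 * y0, tau0, 0.3 * y0, 4 * tau0)]
        for _ in range(5):
            j = rng.uniform(0.5, 2.0, size=4)
            starts.append((0.7 * y0 * j[0], tau0 * j[1],
                           0.3 * y0 * j[2], 4 * tau0 * j[3]))
        for p0 in starts:
            try:
                p, _ = curve_fit(f, self.t, self.y, p0=p0, bounds=(lo, hi),
                                 maxfev=20000)
            except RuntimeError:
                continue
            rss = float(np.sum((self.y - f(self.t, *p)) ** 2))
            if rss < best_rss:
                best, best_rss = p, rss
        if best is None:
            raise FitError("double-exponential fit did not converge "
                           "after multistart")
        return best, best_rss

    def fit(self, model: str = "auto", seed: int = 0) -> DecayFit:
        """Fit the decay; ``model`` is 'auto' (BIC selection), 'single' or
        'double'."""
        if model not in ("auto", "single", "double"):
            raise ValueError("model must be auto|single|double")
        rng = np.random.default_rng(seed)
        n = self.y.size
        scale = float(np.max(np.abs(self.y))) or 1.0
        p1 = rss1 = p2 = rss2 = None
        if model in ("auto", "single"):
            p1, rss1 = self._fit_single()
        if model in ("auto", "double"):
            p2, rss2 = self._fit_double(rng)
        if model == "auto":
            use_double = _bic(rss2, n, 4, scale) < _bic(rss1, n, 2, scale)
        else:
            use_double = model == "double"
        if use_double:
            af, tf, as_, ts = p2
            if tf > ts:  # order fast <= slow
                af, tf, as_, ts = as_, ts, af, tf
            total = af + as_
            if total == 0:
                raise FitError("degenerate double fit: zero total amplitude")
            ff, fs = af / total, as_ / total
            tau_w = ff * tf + fs * ts
            return DecayFit(tau_fast=float(tf), tau_slow=float(ts),
                            frac_fast=float(ff), frac_slow=float(fs),
                            tau_w=float(tau_w), model="double",
                            rss=float(rss2), amplitude=float(total),
                            n_samples=n)
        a, tau = p1
        return DecayFit(tau_fast=float(tau), tau_slow=float(tau),
                        frac_fast=1.0, frac_slow=0.0, tau_w=float(tau),
                        model="single", rss=float(rss1), amplitude=float(a),
                        n_samples=n)


def fit_decay(y: np.ndarray, dt: float, model: str = "auto",
              seed: int = 0) -> DecayFit:
    """Convenience wrapper: fit the post-peak decay samples ``y``."""
    return ExponentialDecayModel(y, dt).fit(model=model, seed=seed)


def decay_fit_window(waveform: np.ndarray, dt: float, peak_index: int,
                     noise_sd: float = 0.0, tau_cap: float = 10.0) -> np.ndarray:
    """Extract the decay-fit window: peak to return within one noise SD of
    baseline, capped at ``tau_cap`` times a crude tau estimate."""
    y = np.asarray(waveform, dtype=float)[peak_index:]
    if noise_sd > 0:
        back = np.flatnonzero(np.abs(y) <= noise_sd)
        if back.size:
            y = y[: max(20, back[0] + 1)]
    # crude tau from first e-fold, cap the window length
    e_fold = np.flatnonzero(np.abs(y) < np.abs(y[0]) * np.exp(-1.0))
    tau_est = (e_fold[0] * dt) if e_fold.size else y.size * dt / 3
    n_cap = int(round(tau_cap * tau_est / dt))
    return y[: max(20, min(y.size, n_cap))]


def rise_time_10_90(waveform: np.ndarray, dt: float, baseline: float,
                    peak_index: int) -> float:
    """10-90% rise time (ms) by linear interpolation on the rising limb.

    Uses the last 10% crossing and the first 90% crossing before the peak;
    invariant to amplitude scaling and baseline offset.
    """
    y = np.asarray(waveform, dtype=float)
    amp = y[peak_index] - baseline
    if amp == 0:
        raise ValueError("peak must differ from baseline")
    frac = (y[: peak_index + 1] - baseline) / amp  # 1 at the peak

    def _cross(level: float, first: bool) -> float:
        above = frac >= level
        idx = np.flatnonzero(above[1:] & ~above[:-1])  # upward crossings
        if idx.size == 0:
            if frac[0] >= level:
                return 0.0
            raise ValueError(f"no {level:.0%} crossing before the peak")
        i = idx[0] if first else idx[-1]
        f0, f1 = frac[i], frac[i + 1]
        return (i + (level - f0) / (f1 - f0)) * dt

    t90 = _cross(0.9, first=True)
    t10_candidates = _cross(0.1, first=False)
    if t10_candidates > t90:  # take the last 10% crossing before t90
        above = frac >= 0.1
        idx = np.flatnonzero(above[1:] & ~above[:-1])
        idx = idx[(idx + 1) * dt <= t90 + dt]
        if idx.size == 0:
            raise ValueError("no 10% crossing before the 90% crossing")
        i = idx[-1]
        t10 = (i + (0.1 - frac[i]) / (frac[i + 1] - frac[i])) * dt
    else:
        t10 = t10_candidates
    return t90 - t10


def event_conductance(peak_amplitude: float, v: float, e_rev: float = 0.0) -> float:
    """Peak chord conductance in nS: |peak / (V - E_rev)| (pA / mV = nS)."""
    if v == e_rev:
        raise ValueError("conductance undefined at the reversal potential")
    return abs(peak_amplitude / (v - e_rev))
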