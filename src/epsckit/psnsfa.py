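"""Peak-scaled non-stationary fluctuation analysis (ps-NSFA).

Estimates the weighted-mean single-channel current ``i``, the number of
channels open at the peak ``N_p`` and the background variance from the
fluctuation of individual synaptic events about their peak-scaled ensemble
mean.  The ensemble-mean waveform is scaled to each event's peak; the decay
phase is divided into bins of equal amplitude (30 by default); within each
bin the variance of (event - scaled mean) is pooled across events; and the
variance-mean pairs are fitted with the parabola

    sigma^2_PS = i * I_mean - I_mean^2 / N_p + sigma^2_B.

The chord conductance gamma = |i| / |V - E_rev| (in pS) follows with
E_rev = 0 mV by convention.  Only the decay phase enters the fit because
latency jitter on the rising phase inflates variance unrelated to channel
gating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import lsq_linear

from .detect import EventEnsemble
from .io import QualityError


@dataclass
class ParabolicFitResult:
    """Results of a peak-scaled NSFA parabolic fit.

    ``i`` is the weighted-mean single-channel current (pA, signed),
    ``n_p`` the number of channels open at the peak, ``sigma2_b`` the
    fitted background variance (pA^2) and ``gamma`` the chord conductance
    in pS at the stated voltage.  ``n_p_unbounded`` flags a degenerate
    (non-positive-curvature) fit in which ``n_p`` is not identified.
    """

    bin_means: np.ndarray          # pA, per retained bin
    bin_variances: np.ndarray      # pA^2
    bin_counts: np.ndarray         # pooled samples per retained bin
    i: float
    n_p: float
    sigma2_b: float
    gamma: float                   # pS
    voltage: float                 # mV
    e_rev: float                   # mV
    n_events: int
    measured_sigma2_b: float       # pre-event baseline variance, pA^2
    n_p_unbounded: bool = False
    excluded_bins: int = 0

    def predict(self, current: np.ndarray) -> np.ndarray:
        """Fitted parabola evaluated at mean current values (pA)."""
        current = np.asarray(current, dtype=float)
        quad = 0.0 if self.n_p_unbounded else current**2 / self.n_p
        return self.i * current - quad + self.sigma2_b

    def summary(self) -> str:
        np_str = "unbounded" if self.n_p_unbounded else f"{self.n_p:10.2f}"
        return "\n".join([
            "Peak-scaled non-stationary fluctuation analysis",
            "=" * 50,
            f"events               {self.n_events:7d}",
            f"bins used            {len(self.bin_means):7d}"
            f"  (excluded {self.excluded_bins})",
            f"unitary current i    {self.i:10.4f} pA",
            f"channels at peak N_p {np_str}",
            f"sigma^2_B (fitted)   {self.sigma2_b:10.4f} pA^2",
            f"sigma^2_B (measured) {self.measured_sigma2_b:10.4f} pA^2",
            f"chord conductance    {self.gamma:10.2f} pS"
            f"  at {self.voltage:g} mV (E_rev {self.e_rev:g} mV)",
        ])

    def plot(self, ax=None):
        """Diagnostic variance-mean plot with the fitted parabola."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.bin_means, self.bin_variances, "o", label="binned variance")
        xs = np.linspace(0, self.bin_means.min(), 200)
        ax.plot(xs, self.predict(xs), "-", label="parabolic fit")
        ax.axhline(self.sigma2_b, ls="--", lw=0.8, color="gray")
        ax.set_xlabel("mean current (pA)")
        ax.set_ylabel("peak-scaled variance (pA$^2$)")
        ax.legend()
        return ax


class PeakScaledNSFA:
    """Peak-scaled NSFA model over an aligned event ensemble.

    Parameters
    ----------
    ensemble : EventEnsemble
        Peak-aligned, baseline-subtracted event waveforms.
    n_bins : int
        Number of equal-amplitude bins over the decay phase (default 30).
    voltage : float
        Holding potential, mV.
    e_rev : float
        Reversal potential, mV (0 by convention).
    min_events : int
        Quality floor; fewer events raises :class:`QualityError` because
        the parabola is not identifiable.
    min_bin_samples : int
        Bins whose pooled sample count falls below this are excluded.
    weighted : bool
        Weight bins by pooled sample count (plain least squares if False).
    """

    def __init__(
        self,
        ensemble: EventEnsemble,
        n_bins: int = 30,
        voltage: float = -60.0,
        e_rev: float = 0.0,
        min_events: int = 10,
        min_bin_samples: int = 5,
        weighted: bool = False,
    ):
        if n_bins < 3:
            raise ValueError("n_bins must be >= 3")
        if voltage == e_rev:
            raise ValueError("voltage must differ from E_rev")
        if ensemble.n_events < min_events:
            raise QualityError(
                f"{ensemble.n_events} events < quality floor of {min_events}; "
                "parabola unidentifiable")
        self.ensemble = ensemble
        self.n_bins = n_bins
        self.voltage = voltage
        self.e_rev = e_rev
        self.min_bin_samples = min_bin_samples
        self.weighted = weighted

    def _scales(self, mean: np.ndarray, peak_idx: int) -> tuple[np.ndarray, int]:
        """Per-event peak scale factors and the scale-window half width.

        The event peak is measured as the 3-sample average around the
        ensemble peak index.  Scaling clamps the residual there to ~0, so
        those samples are excluded from the variance fit (returned half
        width marks them).
        """
        lo, hi = max(0, peak_idx - 1), min(mean.size, peak_idx + 2)
        scales = self.ensemble.matrix[:, lo:hi].mean(axis=1) / mean[lo:hi].mean()
        return scales, hi - peak_idx

    def fit(self) -> ParabolicFitResult:
        ens = self.ensemble
        mean = ens.mean
        peak_idx = int(np.argmax(np.abs(mean)))
        peak_mean = mean[peak_idx]
        if peak_mean == 0:
            raise QualityError("flat ensemble mean; nothing to analyse")

        scales, clamp_n = self._scales(mean, peak_idx)

        decay = slice(peak_idx, mean.size)
        m = mean[decay]                                  # (n_samples,)
        resid = ens.matrix[:, decay] - scales[:, None] * m[None, :]
        var_s = resid.var(axis=0, ddof=1)                # per-sample pooled var
        usable = np.ones(m.size, dtype=bool)
        usable[:clamp_n] = False  # residuals clamped by the peak scaling

        # equal-amplitude bins of the mean decay, 0 .. |peak|
        frac = np.abs(m) / np.abs(peak_mean)
        frac = np.clip(frac, 0.0, 1.0)
        bin_idx = np.minimum((frac * self.n_bins).astype(int), self.n_bins - 1)

        bin_means = np.empty(self.n_bins)
        bin_vars = np.empty(self.n_bins)
        bin_counts = np.zeros(self.n_bins, dtype=int)
        for b in range(self.n_bins):
            sel = (bin_idx == b) & usable
            n_samp = int(sel.sum())
            bin_counts[b] = n_samp * ens.n_events
            if n_samp:
                bin_means[b] = m[sel].mean()
                bin_vars[b] = var_s[sel].mean()
        keep = bin_counts >= self.min_bin_samples
        excluded = int((~keep).sum())
        if keep.sum() < 3:
            raise QualityError("fewer than 3 occupied variance-mean bins")
        I = bin_means[keep]
        V2 = bin_vars[keep]
        w = np.sqrt(bin_counts[keep]) if self.weighted else np.ones(keep.sum())

        # sigma^2_PS = i*I - I^2 * c + s,  c = 1/N_p >= 0, s >= 0
        A = np.column_stack([I, -I**2, np.ones_like(I)]) * w[:, None]
        b_vec = V2 * w
        sol = lsq_linear(A, b_vec,
                         bounds=([-np.inf, 0.0, 0.0], [np.inf, np.inf, np.inf]))
        i_fit, c_fit, s_fit = sol.x
        unbounded = c_fit <= 1e-12
        if unbounded:
            warnings.warn("non-positive curvature: N_p unbounded (degenerate "
                          "parabola)", stacklevel=2)
        n_p = np.inf if unbounded else 1.0 / c_fit
        gamma = abs(i_fit / (self.voltage - self.e_rev)) * 1000.0  # nS -> pS

        # measured background variance from the pre-alignment baseline
        pre = ens.matrix[:, : max(1, ens.align_index // 2)]
        measured = float(pre.var(ddof=1)) if pre.size > 1 else 0.0

        return ParabolicFitResult(
            bin_means=I, bin_variances=V2, bin_counts=bin_counts[keep],
            i=float(i_fit), n_p=float(n_p), sigma2_b=float(s_fit),
            gamma=float(gamma), voltage=self.voltage, e_rev=self.e_rev,
            n_events=ens.n_events, measured_sigma2_b=measured,
            n_p_unbounded=bool(unbounded), excluded_bins=excluded)


def peak_scaled_nsfa(
    ensemble: EventEnsemble,
    n_bins: int = 30,
    voltage: float = -60.0,
    e_rev: float = 0.0,
    **kwargs,
) -> ParabolicFitResult:
    """Functional wrapper around :class:`PeakScaledNSFA`."""
    return PeakScaledNSFA(ensemble, n_bins=n_bins, voltage=voltage,
                          e_rev=e_rev, **kwargs).fit()
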