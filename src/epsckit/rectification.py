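"""Rectification indices of AMPA-receptor currents.

Two complementary measures: ``RI_slope``, the ratio of slope conductances
fitted to the positive (+20..+40 mV) and negative (-40..-20 mV) limbs of a
voltage-ramp I-V relation, and ``RI_CM``, the count-matched ratio of mean
mEPSC peak conductances at +60 and -60 mV (all events at +60 mV against an
equal number of the largest events at -60 mV).  Values well below 1
indicate inwardly rectifying, calcium-permeable receptors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .detect import Event
from .io import IVRamp
from .kinetics import event_conductance


@dataclass
class RectificationResult:
    """Slope conductances (nS) and rectification indices."""

    g_neg: Optional[float] = None
    g_pos: Optional[float] = None
    ri_slope: Optional[float] = None
    ri_cm: Optional[float] = None
    n_events_pos: int = 0
    n_events_neg: int = 0

    def summary(self) -> str:
        fmt = lambda v, u="": ("       n/a" if v is None else f"{v:10.4f}{u}")
        return "\n".join([
            "Rectification",
            "=" * 30,
            f"g_neg     {fmt(self.g_neg, ' nS')}",
            f"g_pos     {fmt(self.g_pos, ' nS')}",
            f"RI_slope  {fmt(self.ri_slope)}",
            f"RI_CM     {fmt(self.ri_cm)}",
            f"events    +{self.n_events_pos} / -{self.n_events_neg}",
        ])


def slope_conductance(ramp: IVRamp, window: tuple[float, float]) -> float:
    """OLS slope of current vs voltage within ``window`` (inclusive), nS."""
    lo, hi = min(window), max(window)
    if lo < ramp.voltage.min() or hi > ramp.voltage.max():
        raise ValueError("window lies outside the ramp voltage range")
    sel = (ramp.voltage >= lo) & (ramp.voltage <= hi)
    if sel.sum() < 10:
        raise ValueError("need >= 10 samples inside the window")
    slope, _ = np.polyfit(ramp.voltage[sel], ramp.current[sel], 1)
    return float(slope)  # pA/mV = nS


def ri_slope(
    ramp: IVRamp,
    neg_window: tuple[float, float] = (-40.0, -20.0),
    pos_window: tuple[float, float] = (20.0, 40.0),
) -> float:
    """Slope-conductance rectification index g_pos / g_neg."""
    g_neg = slope_conductance(ramp, neg_window)
    g_pos = slope_conductance(ramp, pos_window)
    if g_neg <= 0:
        raise ValueError("negative-limb slope conductance is not positive; "
                         "RI undefined")
    return g_pos / g_neg


_Amplitudes = Union[Sequence[float], Sequence[Event], np.ndarray]


def _amplitudes(events: _Amplitudes) -> np.ndarray:
    if len(events) and isinstance(events[0], Event):
        return np.array([e.peak_amplitude for e in events], dtype=float)
    return np.asarray(events, dtype=float)


def ri_count_matched(
    events_pos: _Amplitudes,
    events_neg: _Amplitudes,
    v_pos: float = 60.0,
    v_neg: float = -60.0,
    e_rev: float = 0.0,
    tie_policy: str = "fractional",
) -> float:
    """Count-matched rectification index RI_CM.

    Mean peak conductance of all events at the positive potential divided
    by the mean conductance of the equally many largest-magnitude events at
    the negative potential.  Ties at the selection cutoff are by default
    weighted fractionally so the effective count is exact
    (``tie_policy='truncate'`` keeps exactly the first k after a stable
    sort instead).
    """
    amp_pos = _amplitudes(events_pos)
    amp_neg = _amplitudes(events_neg)
    if amp_pos.size < 1 or amp_neg.size < 1:
        raise ValueError("need at least one event at each potential")
    if amp_neg.size < amp_pos.size:
        raise ValueError("cannot count-match: fewer negative than positive "
                         "events")
    g_pos = np.array([event_conductance(a, v_pos, e_rev) for a in amp_pos])
    g_neg_all = np.array([event_conductance(a, v_neg, e_rev) for a in amp_neg])
    k = amp_pos.size
    mags = np.sort(np.abs(amp_neg))[::-1]
    g_sorted = np.sort(g_neg_all)[::-1]  # conductance ranks == |amplitude| ranks
    if tie_policy == "truncate" or mags.size == k:
        g_mean_neg = g_sorted[:k].mean()
    elif tie_policy == "fractional":
        cutoff = mags[k - 1]
        above = mags > cutoff
        n_above = int(above.sum())
        n_tied = int((mags == cutoff).sum())
        frac = (k - n_above) / n_tied  # weight for each tied event
        w = np.where(mags > cutoff, 1.0, np.where(mags == cutoff, frac, 0.0))
        g_mean_neg = float(np.sum(w * g_sorted) / k)
    else:
        raise ValueError("tie_policy must be 'fractional' or 'truncate'")
    if g_mean_neg == 0:
        raise ValueError("zero mean negative-limb conductance")
    return float(g_pos.mean() / g_mean_neg)


def rectification_from_ramp(
    ramp: IVRamp,
    neg_window: tuple[float, float] = (-40.0, -20.0),
    pos_window: tuple[float, float] = (20.0, 40.0),
) -> RectificationResult:
    """Full slope-conductance rectification summary for one ramp."""
    g_neg = slope_conductance(ramp, neg_window)
    g_pos = slope_conductance(ramp, pos_window)
    if g_neg <= 0:
        raise ValueError("negative-limb slope conductance is not positive")
    return RectificationResult(g_neg=g_neg, g_pos=g_pos,
                               ri_slope=g_pos / g_neg)
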