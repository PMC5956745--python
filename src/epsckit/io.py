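"""Data containers and delimited-text readers/writers.

Unit conventions used package-wide: time in ms, current in pA (inward
negative), voltage in mV, conductance in nS (unitary values quoted in pS),
EM coordinates in nm, areas in μm².  Sweep tables are plain delimited text
(CSV): first column time in ms, one column per sweep in pA.  No proprietary
acquisition formats are parsed; :data:`SWEEP_READER_HOOKS` is the declared
adapter point for them.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """Raised when an input file violates the expected table layout."""


class QualityError(ValueError):
    """Raised when data fail a quality floor (e.g. too few events to fit)."""


#: Adapter hook for acquisition-hardware formats.  Maps a file suffix to a
#: callable ``path -> SweepRecording``.  Intentionally empty: only delimited
#: text is supported in this package.
SWEEP_READER_HOOKS: dict[str, Callable[[str], "SweepRecording"]] = {}

_REL_TOL_GRID = 1e-6  # relative tolerance for a uniform time grid


@dataclass
class SweepRecording:
    """A uniformly sampled multi-sweep current recording.

    Parameters
    ----------
    sampling_interval : float
        Sample spacing in ms.
    sweeps : ndarray, shape (n_sweeps, n_samples)
        Membrane current per sweep in pA, inward negative.
    holding_potential : float
        Holding potential in mV.
    stimulus_times : list of ndarray, optional
        Stimulus times in ms, one array per sweep.
    label : str
        Free-text identifier.
    """

    sampling_interval: float
    sweeps: np.ndarray
    holding_potential: float = -60.0
    stimulus_times: Optional[list[np.ndarray]] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))
        if not self.sampling_interval > 0:
            raise ValueError("sampling_interval must be positive")
        if self.sweeps.ndim != 2:
            raise ValueError("sweeps must be a 2-D array (sweeps x samples)")
        if self.stimulus_times is not None:
            if len(self.stimulus_times) != self.n_sweeps:
                raise ValueError("need one stimulus-time array per sweep")
            self.stimulus_times = [
                np.atleast_1d(np.asarray(s, dtype=float)) for s in self.stimulus_times
            ]
            dur = self.duration
            for s in self.stimulus_times:
                if s.size and (s.min() < 0 or s.max() > dur):
                    raise ValueError("stimulus times must lie within the sweep")

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def n_samples(self) -> int:
        return self.sweeps.shape[1]

    @property
    def duration(self) -> float:
        """Sweep duration in ms."""
        return self.n_samples * self.sampling_interval

    @property
    def time(self) -> np.ndarray:
        """Sample times in ms (shared by all sweeps)."""
        return np.arange(self.n_samples) * self.sampling_interval


@dataclass
class IVRamp:
    """A leak-subtracted current-voltage ramp record.

    ``voltage`` must be strictly monotonic (mV); ``current`` is the matching
    current in pA.
    """

    voltage: np.ndarray
    current: np.ndarray
    leak_subtracted: bool = True

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        if self.voltage.shape != self.current.shape or self.voltage.ndim != 1:
            raise ValueError("voltage and current must be 1-D and equal length")
        dv = np.diff(self.voltage)
        if not (np.all(dv > 0) or np.all(dv < 0)):
            raise ValueError("voltage must be strictly monotonic")


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters with their package defaults.

    The detection threshold is ``threshold_k`` times the baseline noise SD
    (the conventional ~5 pA threshold at ~1.7 pA baseline noise).  EM
    defaults implement the 0.1 μm² counting grid, the <100 nm active-zone
    proximity rule and per-50-nm normalisation.
    """

    threshold_k: float = 3.0            # detection threshold multiplier (x noise SD)
    baseline_window_ms: float = 10.0    # event-free window for noise estimation
    alignment_window_ms: float = 1.0    # refractory merge window for crossings
    smoothing_ms: float = 0.5           # boxcar width applied before thresholding
    align_pre_ms: float = 2.0           # pre-alignment extract for averaging
    align_post_ms: float = 12.0         # post-alignment extract for averaging
    decay_window_ms: float = 10.0       # decay-fit / contamination window
    nsfa_bins: int = 30                 # equal-amplitude bins for ps-NSFA
    nsfa_min_events: int = 10           # quality floor for the parabolic fit
    nsfa_min_bin_samples: int = 5       # pooled-sample floor per bin
    nsfa_weighted: bool = False         # count-weight bins (plain LS default)
    e_rev: float = 0.0                  # reversal potential, mV
    ri_neg_window: tuple[float, float] = (-40.0, -20.0)  # mV
    ri_pos_window: tuple[float, float] = (20.0, 40.0)    # mV
    qepsc_exclusion_ms: float = 10.0    # post-stimulus exclusion for qEPSC counting
    em_square_area_um2: float = 0.1     # counting-grid square area
    proximity_nm: float = 100.0         # AZ proximity radius
    az_unit_nm: float = 50.0            # AZ length normalisation unit
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("baseline_window_ms", "alignment_window_ms", "align_pre_ms",
                     "align_post_ms", "decay_window_ms", "qepsc_exclusion_ms",
                     "em_square_area_um2", "proximity_nm", "az_unit_nm"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")
        if self.nsfa_bins < 3:
            raise ValueError("nsfa_bins must be >= 3")
        if not self.threshold_k > 0:
            raise ValueError("threshold_k must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load a flat key-value (YAML-compatible) config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        if "ri_neg_window" in raw:
            raw["ri_neg_window"] = tuple(raw["ri_neg_window"])
        if "ri_pos_window" in raw:
            raw["ri_pos_window"] = tuple(raw["ri_pos_window"])
        return cls(**raw)

    def to_file(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["ri_neg_window"] = list(self.ri_neg_window)
        data["ri_pos_window"] = list(self.ri_pos_window)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Sweep tables
# ---------------------------------------------------------------------------

def read_sweeps(path: str | Path, metadata: Optional[dict] = None) -> SweepRecording:
    """Read a delimited sweep table: first column time (ms), rest sweeps (pA).

    ``metadata`` may carry ``holding_potential``, ``label`` and
    ``stimulus_times`` (a single sequence applied to every sweep, or one
    sequence per sweep).
    """
    metadata = dict(metadata or {})
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError("sweep table needs a time column and >=1 sweep column")
    if df.isna().any().any():
        raise FormatError("sweep table contains missing cells (ragged input)")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise FormatError("sweep table needs at least two samples")
    dt = np.diff(t)
    dt0 = dt.mean()
    if dt0 <= 0 or np.any(np.abs(dt - dt0) > _REL_TOL_GRID * abs(dt0)):
        raise FormatError("time column is not a uniform grid")
    sweeps = df.iloc[:, 1:].to_numpy(dtype=float).T
    stim = metadata.pop("stimulus_times", None)
    if stim is not None and np.ndim(stim) == 1:
        stim = [np.asarray(stim, dtype=float)] * sweeps.shape[0]
    return SweepRecording(
        sampling_interval=float(dt0),
        sweeps=sweeps,
        holding_potential=float(metadata.pop("holding_potential", -60.0)),
        stimulus_times=stim,
        label=str(metadata.pop("label", Path(path).stem)),
    )


def write_sweeps(recording: SweepRecording, path: str | Path) -> None:
    """Write a SweepRecording as a CSV sweep table (12 significant digits)."""
    cols = {"time_ms": recording.time}
    for j in range(recording.n_sweeps):
        cols[f"sweep_{j}"] = recording.sweeps[j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_ramp(path: str | Path, leak_subtracted: bool = True) -> IVRamp:
    """Read an I-V ramp CSV with columns voltage_mV, current_pA."""
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.isna().any().any():
        raise FormatError("ramp table needs complete voltage and current columns")
    return IVRamp(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float),
                  leak_subtracted=leak_subtracted)


def write_ramp(ramp: IVRamp, path: str | Path) -> None:
    pd.DataFrame({"voltage_mV": ramp.voltage, "current_pA": ramp.current}).to_csv(
        path, index=False, float_format="%.12g")
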