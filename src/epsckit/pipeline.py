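"""Stage runner chaining the analysis modules into tidy on-disk tables.

Every stage reads delimited text, writes tidy CSV tables keyed by
(recording, sweep, event) and appends a structured line-per-entry log
(stage, parameters, seed, counts) so external statistics can be applied
without re-parsing raw data.  Identical config + seed gives byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import detect as _detect
from . import em as _em
from . import kinetics as _kinetics
from . import psnsfa as _psnsfa
from . import quantal as _quantal
from . import rectification as _rect
from . import simulate as _sim
from .io import (AnalysisConfig, QualityError, read_ramp, read_sweeps,
                 write_ramp, write_sweeps)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "kinetics", "nsfa", "rectify", "quantal",
          "train", "em")


class UsageError(ValueError):
    """Unknown stage or malformed stage inputs."""


def _events_frame(events: Sequence[_detect.Event]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sweep": e.sweep_index,
        "onset_ms": e.onset_time,
        "peak_ms": e.peak_time,
        "peak_pA": e.peak_amplitude,
        "baseline_pA": e.local_baseline,
        "monotonic_rise": e.monotonic_rise,
        "clean_decay": e.clean_decay,
        "post_stimulus_ok": e.post_stimulus_ok,
    } for e in events])


def _events_from_frame(df: pd.DataFrame) -> list[_detect.Event]:
    return [_detect.Event(
        sweep_index=int(r.sweep), onset_time=float(r.onset_ms),
        peak_time=float(r.peak_ms), peak_amplitude=float(r.peak_pA),
        local_baseline=float(r.baseline_pA),
        monotonic_rise=bool(r.monotonic_rise),
        clean_decay=bool(r.clean_decay),
        post_stimulus_ok=bool(r.post_stimulus_ok),
    ) for r in df.itertuples()]


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.12g")


def _log(out_dir: Path, stage: str, config: AnalysisConfig, seed: int,
         **counts) -> None:
    entry = {"stage": stage, "seed": seed,
             **{f"n_{k}": v for k, v in counts.items()},
             **dataclasses.asdict(config)}
    line = " ".join(f"{k}={v}" for k, v in entry.items())
    logger.info("%s", line)
    with open(out_dir / "pipeline.log", "a") as fh:
        fh.write(line + "\n")


def _detect_and_screen(config: AnalysisConfig, sweeps_path: str,
                       stimulus_times=None, holding=None):
    meta = {}
    if holding is not None:
        meta["holding_potential"] = holding
    if stimulus_times is not None:
        meta["stimulus_times"] = stimulus_times
    rec = read_sweeps(sweeps_path, meta)
    _, noise_sd = _detect.estimate_baseline_noise(rec)
    events = _detect.detect_events(
        rec, k=config.threshold_k, noise_sd=noise_sd,
        merge_ms=config.alignment_window_ms,
        smoothing_ms=config.smoothing_ms)
    _detect.screen_events(events, rec, noise_sd=noise_sd,
                          decay_window_ms=config.decay_window_ms)
    return rec, events, noise_sd


def run_pipeline(
    config: AnalysisConfig,
    inputs: Sequence[str],
    stage: str,
    out_dir: str | Path = ".",
    seed: Optional[int] = None,
    simulate_model: str = "mepsc",
) -> list[Path]:
    """Run one pipeline stage; returns the paths written.

    ``inputs`` are stage-specific file paths (sweep CSVs, a ramp CSV, or
    annotation JSONs); ``simulate_model`` selects the generator for the
    simulate stage (mepsc|ramp|sr2|train|terminal).
    """
    if stage not in STAGES:
        raise UsageError(f"unknown stage {stage!r}; choose from {STAGES}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    written: list[Path] = []

    if stage == "simulate":
        written += _run_simulate(config, out_dir, seed, simulate_model)
    elif stage == "detect":
        if len(inputs) != 1:
            raise UsageError("detect needs exactly one sweep CSV")
        rec, events, noise_sd = _detect_and_screen(config, inputs[0])
        df = _events_frame(events)
        p = out_dir / "events.csv"
        _write(df, p)
        written.append(p)
        _log(out_dir, stage, config, seed, sweeps=rec.n_sweeps,
             events=len(events), noise_sd_mpa=round(1000 * noise_sd))
    elif stage == "kinetics":
        if len(inputs) != 1:
            raise UsageError("kinetics needs exactly one sweep CSV")
        rec, events, noise_sd = _detect_and_screen(config, inputs[0])
        ens = _detect.align_and_average(
            events, rec, pre_ms=config.align_pre_ms,
            post_ms=config.align_post_ms)
        mean = ens.mean
        pk = int(np.argmax(np.abs(mean)))
        rise = _kinetics.rise_time_10_90(mean, ens.dt, 0.0, pk)
        decay = _kinetics.decay_fit_window(mean, ens.dt, pk, noise_sd)
        fit = _kinetics.fit_decay(decay, ens.dt, seed=seed)
        g = _kinetics.event_conductance(mean[pk], rec.holding_potential,
                                        config.e_rev)
        df = pd.DataFrame([{
            "n_events": ens.n_events, "rise_10_90_ms": rise,
            "tau_fast_ms": fit.tau_fast, "tau_slow_ms": fit.tau_slow,
            "frac_fast": fit.frac_fast, "tau_w_ms": fit.tau_w,
            "model": fit.model, "peak_pA": mean[pk],
            "peak_conductance_nS": g,
        }])
        p = out_dir / "kinetics.csv"
        _write(df, p)
        written.append(p)
        _log(out_dir, stage, config, seed, events=ens.n_events)
    elif stage == "nsfa":
        if len(inputs) != 1:
            raise UsageError("nsfa needs exactly one sweep CSV")
        rec, events, noise_sd = _detect_and_screen(config, inputs[0])
        try:
            ens = _detect.align_and_average(
                events, rec, pre_ms=config.align_pre_ms,
                post_ms=config.align_post_ms)
            res = _psnsfa.peak_scaled_nsfa(
                ens, n_bins=config.nsfa_bins,
                voltage=rec.holding_potential, e_rev=config.e_rev,
                min_events=config.nsfa_min_events,
                min_bin_samples=config.nsfa_min_bin_samples,
                weighted=config.nsfa_weighted)
        except (QualityError, ValueError) as exc:
            logger.warning("nsfa fit refused: %s", exc)
            _log(out_dir, stage, config, seed, events=len(events),
                 refused=1)
            return written
        bins = pd.DataFrame({
            "mean_pA": res.bin_means, "variance_pA2": res.bin_variances,
            "pooled_samples": res.bin_counts,
        })
        p1 = out_dir / "nsfa_bins.csv"
        _write(bins, p1)
        summ = pd.DataFrame([{
            "i_pA": res.i, "n_p": res.n_p, "sigma2_b_pA2": res.sigma2_b,
            "gamma_pS": res.gamma, "n_events": res.n_events,
            "n_p_unbounded": res.n_p_unbounded,
        }])
        p2 = out_dir / "nsfa_summary.csv"
        _write(summ, p2)
        written += [p1, p2]
        _log(out_dir, stage, config, seed, events=res.n_events,
             bins=len(res.bin_means))
    elif stage == "rectify":
        if len(inputs) == 1:
            ramp = read_ramp(inputs[0])
            res = _rect.rectification_from_ramp(
                ramp, config.ri_neg_window, config.ri_pos_window)
        elif len(inputs) == 2:  # two event tables: +60 mV then -60 mV
            pos = pd.read_csv(inputs[0])["peak_pA"].to_numpy(float)
            neg = pd.read_csv(inputs[1])["peak_pA"].to_numpy(float)
            res = _rect.RectificationResult(
                ri_cm=_rect.ri_count_matched(pos, neg, e_rev=config.e_rev),
                n_events_pos=pos.size, n_events_neg=neg.size)
        else:
            raise UsageError("rectify needs one ramp CSV or two event tables")
        p = out_dir / "rectification.csv"
        _write(pd.DataFrame([dataclasses.asdict(res)]), p)
        written.append(p)
        _log(out_dir, stage, config, seed, inputs=len(inputs))
    elif stage == "quantal":
        if len(inputs) != 2:
            raise UsageError("quantal needs a sweep CSV and a stimulus-time "
                             "CSV (columns sweep, stim_ms)")
        stim_df = pd.read_csv(inputs[1])
        stim = [stim_df.loc[stim_df["sweep"] == s, "stim_ms"].to_numpy(float)
                for s in sorted(stim_df["sweep"].unique())]
        rec, events, noise_sd = _detect_and_screen(
            config, inputs[0], stimulus_times=None)
        rec.stimulus_times = [np.atleast_1d(s) for s in stim]
        summary = _quantal.analyze_sr2_session(
            rec, events, exclusion_ms=config.qepsc_exclusion_ms)
        p1 = out_dir / "qepsc_counts.csv"
        _write(pd.DataFrame({
            "sweep": np.arange(summary.n_sweeps),
            "qepsc_count": summary.per_sweep_counts}), p1)
        p2 = out_dir / "qepsc_amplitudes.csv"
        _write(pd.DataFrame({"amplitude_pA": summary.qepsc_amplitudes}), p2)
        p3 = out_dir / "quantal_summary.csv"
        _write(pd.DataFrame([{
            "mean_count": summary.per_sweep_counts.mean(),
            "failure_rate": summary.failure_rate,
            "initial_epsc_pA": summary.initial_epsc_amplitude,
            "initial_epsc_all_sweeps_pA": summary.initial_epsc_amplitude_all,
            "mean_qepsc_pA": summary.mean_qepsc_amplitude,
        }]), p3)
        written += [p1, p2, p3]
        _log(out_dir, stage, config, seed, sweeps=summary.n_sweeps,
             qepscs=int(summary.per_sweep_counts.sum()))
    elif stage == "train":
        if not inputs:
            raise UsageError("train needs >= 1 'condition=path' input")
        paths = dict(tok.split("=", 1) for tok in inputs)
        stim_csv = paths.pop("stimuli", None)
        if stim_csv is None:
            raise UsageError("train needs a stimuli=<csv> input "
                             "(column stim_ms)")
        stims = pd.read_csv(stim_csv)["stim_ms"].to_numpy(float)
        recs = {}
        for name, path in paths.items():
            recs[name] = read_sweeps(path, {"stimulus_times": stims})
        reference = next(iter(paths))
        results = _quantal.analyze_train(recs, n_pulses=stims.size,
                                         reference=reference)
        rows = []
        for name, res in results.items():
            for j, (a, na) in enumerate(zip(res.per_pulse_amplitudes,
                                            res.normalized_amplitudes), 1):
                rows.append({"condition": name, "pulse": j,
                             "amplitude_pA": a, "normalized": na,
                             "ppr_2_1": res.ppr_2_1})
        p = out_dir / "train_summary.csv"
        _write(pd.DataFrame(rows), p)
        written.append(p)
        _log(out_dir, stage, config, seed, conditions=len(results))
    elif stage == "em":
        if not inputs:
            raise UsageError("em needs >= 1 annotation JSON")
        rows = []
        for path in inputs:
            ann = _em.read_annotation(path)
            rows.append(_em.vesicle_stats(
                ann, square_area_um2=config.em_square_area_um2,
                proximity_nm=config.proximity_nm,
                unit_nm=config.az_unit_nm).to_row())
        p = out_dir / "vesicle_stats.csv"
        _write(pd.DataFrame(rows), p)
        written.append(p)
        _log(out_dir, stage, config, seed, terminals=len(rows))
    return written


def _run_simulate(config: AnalysisConfig, out_dir: Path, seed: int,
                  model_name: str) -> list[Path]:
    written: list[Path] = []
    qm = _sim.QuantalModel()
    if model_name == "mepsc":
        session = _sim.SessionModel(seed=seed)
        rec, truth = _sim.simulate_mepsc_recording(qm, session)
        p1, p2 = out_dir / "sweeps.csv", out_dir / "truth.csv"
        write_sweeps(rec, p1)
        _write(truth, p2)
        written += [p1, p2]
        _log(out_dir, "simulate", config, seed, sweeps=rec.n_sweeps,
             true_events=len(truth))
    elif model_name == "ramp":
        ramp = _sim.simulate_iv_ramp(1.0, 1.0, noise_sd=2.0, seed=seed)
        p = out_dir / "ramp.csv"
        write_ramp(ramp, p)
        written.append(p)
        _log(out_dir, "simulate", config, seed, samples=ramp.voltage.size)
    elif model_name == "sr2":
        session = _sim.SessionModel(
            seed=seed, n_sweeps=30, sweep_duration=400.0,
            sr2_release=_sim.Sr2Release(failure_prob=0.1))
        rec, truth = _sim.simulate_sr2_session(qm, session)
        p1, p2 = out_dir / "sweeps.csv", out_dir / "truth.csv"
        write_sweeps(rec, p1)
        _write(truth, p2)
        p3 = out_dir / "stimuli.csv"
        _write(pd.DataFrame({
            "sweep": np.arange(rec.n_sweeps),
            "stim_ms": [s[0] for s in rec.stimulus_times]}), p3)
        written += [p1, p2, p3]
        _log(out_dir, "simulate", config, seed, sweeps=rec.n_sweeps)
    elif model_name == "train":
        truth, rec = _sim.simulate_train(qm, seed=seed)
        p1, p2 = out_dir / "sweeps.csv", out_dir / "truth.csv"
        write_sweeps(rec, p1)
        _write(truth, p2)
        p3 = out_dir / "stimuli.csv"
        _write(pd.DataFrame({"stim_ms": rec.stimulus_times[0]}), p3)
        written += [p1, p2, p3]
        _log(out_dir, "simulate", config, seed, pulses=len(truth))
    elif model_name == "terminal":
        ann = _sim.simulate_terminal(seed=seed)
        p = out_dir / "terminal.json"
        _em.write_annotation(ann, p)
        written.append(p)
        _log(out_dir, "simulate", config, seed, vesicles=ann.n_vesicles)
    else:
        raise UsageError(f"unknown simulate model {model_name!r}")
    return written
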