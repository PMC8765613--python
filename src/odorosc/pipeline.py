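"""End-to-end orchestration: synth -> preprocess -> respiration ->
spectral -> dynamics -> behavior -> pac.

Every random procedure draws from an explicit seed recorded in the run
metadata; re-running with the same configuration reproduces every output
byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import band_dynamics as dyn
from . import behavior, io, pac, preprocess, respiration, spectral, synth

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("odorosc")


@dataclass
class PipelineConfig:
    """Paths, stage toggles, and stage parameters for one pipeline run."""

    out_dir: str = "odorosc_out"
    recording_path: str | None = None
    events_path: str | None = None

    run_synth: bool = True
    run_preprocess: bool = True
    run_respiration: bool = True
    run_spectral: bool = True
    run_dynamics: bool = True
    run_behavior: bool = True
    run_pac: bool = True

    seed: int = 0
    n_trials: int = 40
    intertrial_interval: tuple[float, float] = (9.0, 0.8)
    cue_to_sniff_delay: tuple[float, float] = (2.0, 3.0)

    epoch_window: tuple[float, float] = (-2.0, 4.0)
    baseline_window: tuple[float, float] = (-0.55, -0.05)
    bank_stride: int = 1
    n_perm_zmap: int = 10_000
    n_perm_cluster: int = 10_000
    n_perm_pac: int = 1000
    q: float = 0.05
    bootstrap_reps: int = 2000
    phase_bootstrap_reps: int = 1000
    outcome_reps: int = 200
    outcome_n_each: int = 71
    corr_inner: int = 1000
    corr_outer: int = 50
    svm_reps: int = 500
    svm_n_each: int = 30
    pac_window: tuple[float, float] = (0.0, 1.0)
    n_bins: int = 18
    log_level: str = "INFO"

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**raw)
        for name in ("intertrial_interval", "cue_to_sniff_delay", "epoch_window",
                     "baseline_window", "pac_window"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg


@dataclass
class RunReport:
    outputs: dict[str, str] = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    completed_stages: list[str] = field(default_factory=list)
    failed_stage: str | None = None
    error: str | None = None


def _band_series(trials, band):
    series = dyn.band_average(trials, band)
    bmeans, bsd = dyn.band_baseline(trials, band)
    return series, bmeans, bsd


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order.

    Any stage failure aborts the run; the report lists completed stages,
    per-stage wall-clock, warning counts, and every output file written.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config=dataclasses.asdict(config))
    io.write_json(out_dir / "config.json", dataclasses.asdict(config))
    report.outputs["config"] = str(out_dir / "config.json")

    caught: list[str] = []
    state: dict = {}

    def do(name, fn):
        t_start = time.perf_counter()
        log.info("stage %s", name)
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            fn()
        for w in wlist:
            caught.append(f"{name}: {w.message}")
        report.stage_seconds[name] = round(time.perf_counter() - t_start, 3)
        report.completed_stages.append(name)

    def synth_stage():
        cfg = synth.SynthConfig(
            n_trials=config.n_trials, seed=config.seed,
            intertrial_interval=config.intertrial_interval,
            cue_to_sniff_delay=config.cue_to_sniff_delay,
            epoch_window=config.epoch_window,
            baseline_window=config.baseline_window,
        )
        rec, events, truth = synth.generate_recording(cfg)
        io.write_recording(out_dir / "recording.npz", rec)
        io.write_events(out_dir / "events.tsv", events)
        io.write_json(out_dir / "truth.json", {
            "band_names": truth.band_names,
            "trial_amplitudes": truth.trial_amplitudes,
            "burst_windows": truth.burst_windows,
            "coupling_depth": truth.coupling_depth,
            "correct": truth.correct.astype(int),
            "sniff_times": truth.sniff_times,
            "cue_times": truth.cue_times,
        })
        report.outputs.update(recording=str(out_dir / "recording.npz"),
                              events=str(out_dir / "events.tsv"),
                              truth=str(out_dir / "truth.json"))
        state["rec"], state["events"] = rec, events

    def load_stage():
        if config.recording_path is None or config.events_path is None:
            raise FileNotFoundError("recording_path and events_path are required "
                                    "when the synth stage is disabled")
        state["rec"] = io.read_recording(config.recording_path)
        state["events"] = io.read_events(config.events_path)

    def preprocess_stage():
        state["clean"] = preprocess.preprocess_chain(state["rec"])
        airflow = getattr(state["rec"], "airflow", None)
        if airflow is not None:
            state["clean"].airflow = airflow
        io.write_recording(out_dir / "clean.npz", state["clean"])
        report.outputs["clean"] = str(out_dir / "clean.npz")

    def respiration_stage():
        rec = state.get("clean", state["rec"])
        airflow = getattr(rec, "airflow", None)
        if airflow is None:
            raise ValueError("recording has no airflow trace")
        fs = state["rec"].sampling_rate  # airflow stays on the raw clock
        breaths = respiration.detect_breaths(np.asarray(airflow), fs)
        df = pd.DataFrame({
            "inhale_onset_s": breaths.inhale_onsets,
            "peak_time_s": breaths.peak_times,
            "exhale_onset_s": breaths.exhale_onsets,
            "trough_time_s": breaths.trough_times,
            "peak_volume": breaths.peak_volumes,
            "trough_volume": breaths.trough_volumes,
        })
        df.to_csv(out_dir / "breaths.tsv", sep="\t", index=False, float_format="%.6f")
        report.outputs["breaths"] = str(out_dir / "breaths.tsv")
        state["breaths"] = breaths

    def spectral_stage():
        clean = state.get("clean", state["rec"])
        events = state["events"]
        if config.run_behavior and "correct" not in events.columns:
            raise ValueError("event table lacks the 'correct' column required "
                             "by the behavior stage")
        fs = clean.sampling_rate
        bank = spectral.build_filter_bank()
        idx = np.arange(0, bank.n_kept, config.bank_stride)
        stack = spectral.amplitude_stack(clean.samples[0], fs, bank, band_indices=idx,
                                         start_time=clean.start_time)
        state["bank"], state["stack"] = bank, stack

        tensors = {}
        for cond in ("odor", "no_odor"):
            sub = events[events["condition"] == cond]
            if len(sub) < 2:
                continue
            trials = spectral.epoch(stack, sub["sniff_time_s"].to_numpy(),
                                    config.epoch_window, meta=sub.reset_index(drop=True))
            trials = spectral.baseline_correct(trials, stack,
                                               trials.meta["cue_time_s"].to_numpy(),
                                               config.baseline_window)
            tensors[cond] = trials
            zmap = spectral.circular_shift_zmap(
                stack, trials.meta["sniff_time_s"].to_numpy(),
                trials.meta["cue_time_s"].to_numpy(), config.epoch_window,
                config.baseline_window, n_perm=config.n_perm_zmap, q=config.q,
                seed=config.seed)
            io.write_zmap_tsv(out_dir / f"zmap_{cond}.tsv", zmap)
            report.outputs[f"zmap_{cond}"] = str(out_dir / f"zmap_{cond}.tsv")
        if "odor" in tensors and "no_odor" in tensors:
            diff = spectral.condition_difference_zmap(
                tensors["odor"], tensors["no_odor"], n_perm=config.n_perm_zmap,
                q=config.q, seed=config.seed)
            io.write_zmap_tsv(out_dir / "zmap_difference.tsv", diff)
            report.outputs["zmap_difference"] = str(out_dir / "zmap_difference.tsv")
        state["tensors"] = tensors
        io.write_json(out_dir / "spectral_meta.json", {
            "n_perm": config.n_perm_zmap, "seed": config.seed, "q": config.q,
            "bank_stride": config.bank_stride,
        })
        report.outputs["spectral_meta"] = str(out_dir / "spectral_meta.json")

    def dynamics_stage():
        trials = state["tensors"]["odor"]
        airflow = getattr(state.get("clean", state["rec"]), "airflow", None)
        fs_raw = state["rec"].sampling_rate
        cluster_rows, phase_rows = [], []
        for band in dyn.DEFAULT_BANDS:
            try:
                series, bmeans, bsd = _band_series(trials, band)
            except ValueError:
                continue
            z = dyn.znormalize(series, bsd)
            result = dyn.cluster_mass_test(z, trials.times,
                                           n_perm=config.n_perm_cluster,
                                           seed=config.seed)
            for c in result.clusters:
                cluster_rows.append((band.name, c.start_s, c.end_s, c.mass, c.p,
                                     int(c.significant)))
            if airflow is not None:
                n_t = len(trials.times)
                starts = np.round((trials.meta["sniff_time_s"].to_numpy()
                                   + trials.times[0]) * fs_raw).astype(int)
                ok = (starts >= 0) & (starts + n_t <= len(airflow))
                resp = np.asarray(airflow)[starts[ok, None] + np.arange(n_t)[None, :]]
                ps = dyn.peak_phase_bootstrap(z[ok], resp, trials.times, fs_raw,
                                              reps=config.phase_bootstrap_reps,
                                              seed=config.seed)
                phase_rows.append((band.name, ps.mean_angle, ps.plv, ps.rayleigh_z,
                                   ps.rayleigh_p))
        pd.DataFrame(cluster_rows, columns=["band", "start_s", "end_s", "mass", "p", "sig"]
                     ).to_csv(out_dir / "clusters.tsv", sep="\t", index=False,
                              float_format="%.6g")
        report.outputs["clusters"] = str(out_dir / "clusters.tsv")
        if phase_rows:
            pd.DataFrame(phase_rows, columns=["band", "mean_angle_rad", "plv",
                                              "rayleigh_z", "rayleigh_p"]
                         ).to_csv(out_dir / "phase_stats.tsv", sep="\t", index=False,
                                  float_format="%.6g")
            report.outputs["phase_stats"] = str(out_dir / "phase_stats.tsv")

    def behavior_stage():
        trials = state["tensors"]["odor"]
        correct = trials.meta["correct"].to_numpy().astype(bool)
        band_series, svm_evals, rows = {}, {}, []
        for band in dyn.DEFAULT_BANDS:
            try:
                series, bmeans, bsd = _band_series(trials, band)
            except ValueError:
                continue
            band_series[band.name] = dyn.znormalize(series, bsd)
            ev = behavior.svm_separability(series, bmeans, trials.times, correct,
                                           n_each=config.svm_n_each, reps=config.svm_reps,
                                           seed=config.seed)
            svm_evals[band.name] = {"auc": ev.auc,
                                    "optimized_accuracy": ev.optimized_accuracy,
                                    "cv_folds": ev.cv_folds}
        if correct.all() or not correct.any():
            caught.append("behavior: single outcome class; outcome analyses skipped")
        else:
            od = behavior.balanced_outcome_difference(band_series, correct,
                                                      n_each=config.outcome_n_each,
                                                      reps=config.outcome_reps,
                                                      seed=config.seed)
            for b, name in enumerate(od.band_names):
                rows.append((name, od.differences[b].mean(), float(od.t[b]), float(od.p[b])))
            pd.DataFrame(rows, columns=["band", "mean_difference", "t", "p"]
                         ).to_csv(out_dir / "outcome_differences.tsv", sep="\t",
                                  index=False, float_format="%.6g")
            report.outputs["outcome_differences"] = str(out_dir / "outcome_differences.tsv")
        io.write_json(out_dir / "svm.json", svm_evals)
        report.outputs["svm"] = str(out_dir / "svm.json")

    def pac_stage():
        clean = state.get("clean", state["rec"])
        events = state["events"]
        sub = events[events["condition"] == "odor"]
        phase, amps, centers, n_kept, n_t = pac.pac_epochs(
            clean.samples[0], clean.sampling_rate, sub["sniff_time_s"].to_numpy(),
            window=config.pac_window, bank=state.get("bank"),
            start_time=clean.start_time)
        for kind, fn in (("circular_shift", lambda: pac.mi_null_circular_shift(
                              phase, amps, n_perm=config.n_perm_pac, q=config.q,
                              n_bins=config.n_bins, seed=config.seed, centers=centers)),
                         ("trial_shuffle", lambda: pac.mi_null_trial_shuffle(
                              phase, amps, n_kept, n_perm=config.n_perm_pac, q=config.q,
                              n_bins=config.n_bins, seed=config.seed, centers=centers))):
            res = fn()
            df = pd.DataFrame({"band_hz": res.amp_band_centers, "mi_raw": res.mi_raw,
                               "mi_z": res.mi_z, "p_adj": res.p_adjusted,
                               "sig": res.fdr_mask.astype(int)})
            df.to_csv(out_dir / f"pac_{kind}.tsv", sep="\t", index=False,
                      float_format="%.6g")
            report.outputs[f"pac_{kind}"] = str(out_dir / f"pac_{kind}.tsv")
        io.write_json(out_dir / "pac_meta.json", {
            "n_perm": config.n_perm_pac, "n_bins": config.n_bins,
            "seed": config.seed, "window": list(config.pac_window)})
        report.outputs["pac_meta"] = str(out_dir / "pac_meta.json")

    stages = []
    if config.run_synth:
        stages.append(("synth", synth_stage))
    else:
        stages.append(("load", load_stage))
    if config.run_preprocess:
        stages.append(("preprocess", preprocess_stage))
    if config.run_respiration:
        stages.append(("respiration", respiration_stage))
    if config.run_spectral:
        stages.append(("spectral", spectral_stage))
    if config.run_dynamics:
        stages.append(("dynamics", dynamics_stage))
    if config.run_behavior:
        stages.append(("behavior", behavior_stage))
    if config.run_pac:
        stages.append(("pac", pac_stage))

    for name, fn in stages:
        try:
            do(name, fn)
        except Exception as exc:  # abort with a report of completed stages
            report.failed_stage = name
            report.error = f"{type(exc).__name__}: {exc}"
            log.error("stage %s failed: %s", name, report.error)
            break

    report.warnings = caught
    io.write_json(out_dir / "run_report.json", dataclasses.asdict(report))
    report.outputs["run_report"] = str(out_dir / "run_report.json")
    if report.failed_stage is not None:
        raise RuntimeError(f"pipeline stage {report.failed_stage!r} failed: "
                           f"{report.error}")
    return report
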