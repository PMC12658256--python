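"""Run configuration, pipeline orchestration and manifests.

A :class:`RunConfig` resolves a YAML file against documented defaults
(unknown keys rejected, field types checked) and :func:`run_pipeline`
executes the configured stages — simulate, kinematics, respirometry,
cardiac, crowding — writing tidy CSV outputs and a JSON manifest with a
config hash and per-file checksums so identical (config, seed) runs can
be verified byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError
from .specs import (AccSpec, CrowdingResponse, CrowdingSchedule, EcgSpec,
                    RespiroSpec, SwimmerSpec)
from . import biologger, challenge, kinematics, respirometry, synthetic

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "kinematics", "respiro", "cardiac", "crowding")


@dataclass
class AnalysisParams:
    """Analysis-stage parameters with the study's method defaults."""

    fps: float = 75.0
    window_s: float = 0.85
    landmark_fraction: float = 0.8
    opercular_fraction: float = 0.25
    video_duration_s: float = 2.0
    cadence_min: float = 10.0
    poly_degree: int = 2
    luminance_threshold: float = 128.0
    n_midline_points: int = 100
    body_mass_kg: float = 0.391
    speeds: tuple[float, ...] = challenge.DEFAULT_SPEEDS
    n_ecg_segments: int = 6
    acc_duration_min: float = 10.0


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    swimmer: SwimmerSpec = field(default_factory=SwimmerSpec)
    ecg: EcgSpec = field(default_factory=EcgSpec)
    acc: AccSpec = field(default_factory=AccSpec)
    respiro: RespiroSpec = field(default_factory=RespiroSpec)
    crowding_schedule: CrowdingSchedule = field(default_factory=CrowdingSchedule)
    crowding_response: CrowdingResponse = field(default_factory=CrowdingResponse)
    analysis: AnalysisParams = field(default_factory=AnalysisParams)

    def to_dict(self) -> dict:
        return _asdict_clean(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _asdict_clean(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _asdict_clean(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_asdict_clean(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


_TUPLE_FIELDS = {"stages", "speeds", "stress_times", "hold_durations",
                 "post_window", "gravity_orientation", "dynamic_amp",
                 "hr_stress_peaks", "acc_stress_peaks", "amp_stress_peaks"}


def _build_dataclass(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or cls.__name__}: expected a mapping")
    known = {f.name: f for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            raise ConfigError(f"unknown key {path + key!r}")
        f = known[key]
        if dataclasses.is_dataclass(f.type) or (
                f.default_factory is not dataclasses.MISSING
                and dataclasses.is_dataclass(f.default_factory)):
            kwargs[key] = _build_dataclass(f.default_factory, value,
                                           f"{path}{key}.")
        elif key in _TUPLE_FIELDS:
            if not isinstance(value, (list, tuple)):
                raise ConfigError(f"field {path + key!r} must be a list")
            kwargs[key] = tuple(value)
        else:
            if isinstance(value, (dict, list)):
                raise ConfigError(
                    f"field {path + key!r} has the wrong type: "
                    f"expected a scalar, got {type(value).__name__}")
            kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration under {path or 'root'}: {exc}")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration; empty or missing content = defaults.

    Unknown keys raise :class:`ConfigError` naming the key; scalar
    fields given mappings or lists raise naming the field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is not None:
            data = loaded
    if overrides:
        data.update(overrides)
    return _build_dataclass(RunConfig, data, "")


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


@dataclass
class RunManifest:
    """Provenance record written alongside every run's outputs."""

    config_hash: str
    version: str
    seed: int
    stages_completed: list[str]
    checksums: dict[str, str]
    failed_stage: str | None = None
    log_path: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the configured stages and write CSV outputs + manifest.

    Stage outputs are deterministic functions of (config, seed), so a
    repeated run produces identical checksums.  A stage failure is
    recorded in the manifest (partial completion) and re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ap = config.analysis
    completed: list[str] = []
    outputs: dict[str, Path] = {}
    state: dict = {}

    def stage_simulate():
        frames, swim_truth = synthetic.generate_swim_video(
            config.swimmer, duration=ap.video_duration_s, fps=ap.fps,
            seed=config.seed)
        state["frames"], state["swim_truth"] = frames, swim_truth
        frame_dir = out / "frames"
        frame_dir.mkdir(exist_ok=True)
        for i in range(frames.n_frames):
            iio.imwrite(frame_dir / f"frame_{i:05d}.png", frames.frames[i])
        outputs["frames_first"] = frame_dir / "frame_00000.png"

        ecg, ecg_truth = synthetic.generate_ecg(
            config.ecg, n_segments=ap.n_ecg_segments, seed=config.seed + 1)
        state["ecg"], state["ecg_truth"] = ecg, ecg_truth
        rows = []
        for j, seg in enumerate(ecg.segments):
            t = ecg.start_times[j] + np.arange(seg.size) / ecg.sample_rate
            rows.append(pd.DataFrame({"timestamp_s": t, "channel": "ecg_au",
                                      "value": seg}))
        _write_csv(pd.concat(rows, ignore_index=True), out / "ecg.csv")
        outputs["ecg"] = out / "ecg.csv"

        acc, acc_truth = synthetic.generate_acc(
            config.acc, duration_min=ap.acc_duration_min, seed=config.seed + 2)
        state["acc"], state["acc_truth"] = acc, acc_truth
        acc_df = pd.DataFrame(acc.samples, columns=["ax_mg", "ay_mg", "az_mg"])
        acc_df.insert(0, "timestamp_s", acc.times)
        _write_csv(acc_df, out / "acc_raw.csv")
        outputs["acc_raw"] = out / "acc_raw.csv"

        traces = []
        for i, speed in enumerate(ap.speeds):
            spec = dataclasses.replace(config.respiro)
            trace, truth = synthetic.generate_o2_trace(spec,
                                                       seed=config.seed + 10 + i)
            traces.append((speed, trace, truth))
        state["o2_traces"] = traces
        o2_rows = [pd.DataFrame({"timestamp_s": tr.time_h * 3600.0,
                                 "channel": f"o2_pct_{speed:.1f}mps",
                                 "value": tr.o2_percent})
                   for speed, tr, _ in traces]
        _write_csv(pd.concat(o2_rows, ignore_index=True), out / "o2.csv")
        outputs["o2"] = out / "o2.csv"

        session, crowd_truth = synthetic.generate_crowding_session(
            config.crowding_schedule, config.crowding_response,
            seed=config.seed + 3)
        state["session"], state["crowd_truth"] = session, crowd_truth
        _write_csv(session.records, out / "crowding_raw.csv")
        outputs["crowding_raw"] = out / "crowding_raw.csv"

        # structured truth sidecar: seed, spec echo, per-channel truth
        sidecar = {
            "seed": config.seed,
            "swimmer_spec": _asdict_clean(config.swimmer),
            "swim_truth": {k: swim_truth[k] for k in
                           ("tbf_hz", "tba_px", "hwf_hz", "hwa_px")},
            "ecg_spec": _asdict_clean(config.ecg),
            "ecg_truth": {
                "heart_rate_bpm": ecg_truth["heart_rate_bpm"],
                "qrs_amplitude": ecg_truth["qrs_amplitude"],
                "beat_times_s": [bt.tolist()
                                 for bt in ecg_truth["beat_times"]],
            },
            "acc_spec": _asdict_clean(config.acc),
            "acc_truth_mg": acc_truth["external_acc_mg"].tolist(),
            "respiro_spec": _asdict_clean(config.respiro),
            "o2_truth": {f"{speed:.1f}mps": tr_truth.truth
                         for speed, _, tr_truth in traces},
            "crowding_phase_labels": crowd_truth["phase_slow"].tolist(),
        }
        (out / "ground_truth.json").write_text(
            json.dumps(sidecar, indent=2, sort_keys=True))
        outputs["ground_truth"] = out / "ground_truth.json"

    def _ensure_simulated():
        if "frames" not in state:
            stage_simulate()

    def stage_kinematics():
        _ensure_simulated()
        frames = state["frames"]
        truth = state["swim_truth"]
        area_range, ratio_range = kinematics.default_selection_ranges(
            truth["expected_area_px2"])
        track = kinematics.track_video(frames, ap.luminance_threshold,
                                       area_range, ratio_range,
                                       ap.n_midline_points)
        exc = kinematics.landmark_excursion(track, ap.landmark_fraction)
        hw = kinematics.head_width_series(track, ap.opercular_fraction)
        tail = kinematics.spectro_kinematics(exc, ap.fps, ap.window_s)
        head = kinematics.spectro_kinematics(hw, ap.fps, ap.window_s)
        summary = kinematics.summarize_kinematics(tail, head)
        n = tail.time.size
        _write_csv(pd.DataFrame({
            "time_s": tail.time,
            "excursion_px": exc.lateral_excursion[:n],
            "head_width_px": hw[:n],
            "tbf_hz": tail.frequency, "tba_px": tail.amplitude,
            "hwf_hz": head.frequency, "hwa_px": head.amplitude,
        }), out / "kinematics_frames.csv")
        _write_csv(pd.DataFrame([{
            "tbf_hz": summary.tbf, "tba_px": summary.tba,
            "hwf_hz": summary.hwf, "hwa_px": summary.hwa,
        }]), out / "kinematics_summary.csv")
        outputs["kinematics_frames"] = out / "kinematics_frames.csv"
        outputs["kinematics_summary"] = out / "kinematics_summary.csv"

    def stage_respiro():
        _ensure_simulated()
        rows = []
        speeds, cots = [], []
        for speed, trace, truth in state["o2_traces"]:
            res = respirometry.compute_mo2(trace,
                                           truth["background_rate"],
                                           ap.body_mass_kg)
            res = respirometry.compute_cot(res, speed)
            rows.append({"speed_mps": speed, "mo2_abs_mg_h": res.mo2_abs,
                         "mo2_mg_kg_h": res.mo2_mass_specific,
                         "cot_mg_kg_km": res.cot})
            speeds.append(speed)
            cots.append(res.cot)
        coeffs, r2 = respirometry.fit_cot_curve(speeds, cots, ap.poly_degree)
        try:
            est = respirometry.optimal_speed(coeffs, r2)
            est.uopt_bls = respirometry.to_body_lengths(
                est.uopt_mps, config.swimmer.standard_length)
            endurance = pd.DataFrame([{
                "uopt_mps": est.uopt_mps, "uopt_bls": est.uopt_bls,
                "cot_min_mg_kg_km": est.cot_min, "r_squared": est.r_squared,
                "extrapolated": est.extrapolated,
            }])
        except Exception as exc:  # flat COT profile has no interior minimum
            log.warning("no U_opt estimate: %s", exc)
            endurance = pd.DataFrame()
        _write_csv(pd.DataFrame(rows), out / "respirometry.csv")
        _write_csv(endurance, out / "endurance.csv")
        outputs["respirometry"] = out / "respirometry.csv"
        outputs["endurance"] = out / "endurance.csv"

    def stage_cardiac():
        _ensure_simulated()
        ecg = state["ecg"]
        rows = []
        for j, seg in enumerate(ecg.segments):
            rec = biologger.segment_cardiac_record(seg, ecg.start_times[j],
                                                   ecg.sample_rate)
            rows.append({"time_s": rec.time_s, "hr_bpm": rec.hr_bpm,
                         "amp_au": rec.amp_au, "quality_flag": rec.flag.value})
        _write_csv(pd.DataFrame(rows), out / "cardiac.csv")
        acc = state["acc"]
        per_min = biologger.external_acceleration(acc.samples, acc.sample_rate)
        _write_csv(pd.DataFrame({"minute": np.arange(per_min.size),
                                 "acc_mg": per_min}), out / "activity.csv")
        outputs["cardiac"] = out / "cardiac.csv"
        outputs["activity"] = out / "activity.csv"

    def stage_crowding():
        _ensure_simulated()
        session = state["session"]
        summaries = challenge.phase_summaries(session.records, session.schedule)
        for channel, summary in summaries.items():
            path = out / f"crowding_summary_{channel}.csv"
            _write_csv(summary, path)
            outputs[f"crowding_summary_{channel}"] = path
        # welfare timeline from the 10-min channels, relative to basal
        rec = session.records
        rec = rec.assign(phase=challenge.label_crowding_phases(
            rec["time_min"], session.schedule))
        wide = (rec.pivot_table(index=["time_min", "phase"], columns="channel",
                                values="value", aggfunc="mean")
                .reset_index())
        basal = wide[wide["phase"] == "basal"]
        hr_mu, hr_sd = basal["hr_bpm"].mean(), basal["hr_bpm"].std(ddof=1)
        acc_mu = basal["acc_mg"].mean()
        amp_mu = basal["amp_au"].mean()
        slow = wide.dropna(subset=["hr_bpm", "amp_au"])
        timeline = pd.DataFrame({
            "time_min": slow["time_min"],
            "phase": slow["phase"],
            "hr_rel": (slow["hr_bpm"] - hr_mu) / hr_sd,
            "acc_rel": slow["acc_mg"] / acc_mu,
            "amp_rel": slow["amp_au"] / amp_mu,
        })
        timeline = challenge.classify_welfare_timeline(timeline)
        _write_csv(timeline, out / "welfare_timeline.csv")
        outputs["welfare_timeline"] = out / "welfare_timeline.csv"
        report = out / "crowding_report.txt"
        lines = [f"crowding session: {len(session.schedule.stress_times)} "
                 f"stress events at {session.schedule.stress_times} min"]
        for channel, summary in summaries.items():
            lines.append(f"\n[{channel}]")
            for _, r in summary.iterrows():
                lines.append(f"  {r['phase']:>12s}: {r['mean']:8.2f} "
                             f"+/- {r['se']:.2f} (n={r['n']}) {r['letters']}")
        report.write_text("\n".join(lines) + "\n")
        outputs["crowding_report"] = report

    stage_fns = {"simulate": stage_simulate, "kinematics": stage_kinematics,
                 "respiro": stage_respiro, "cardiac": stage_cardiac,
                 "crowding": stage_crowding}
    failed = None
    name = None
    try:
        for name in config.stages:
            if name not in stage_fns:
                raise ConfigError(f"unknown stage {name!r}")
            log.info("running stage %s (seed=%d)", name, config.seed)
            stage_fns[name]()
            completed.append(name)
    except Exception:
        failed = name
        raise
    finally:
        manifest = RunManifest(
            config_hash=config.config_hash(),
            version=__version__,
            seed=config.seed,
            stages_completed=completed,
            checksums={k: _sha256(p) for k, p in sorted(outputs.items())},
            failed_stage=failed,
        )
        manifest.write(out / "manifest.json")
    return manifest
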