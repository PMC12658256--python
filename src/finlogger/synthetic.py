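"""Seeded generators for every input modality, with exact ground truth.

The generators emulate the recordings of a swim-tunnel / crowding stress
study on European sea bass: silhouette video of an undulating fish seen
against a light background, short ECG segments logged on a fixed
cadence, 10-Hz tri-axial acceleration, percent-saturation oxygen decline
in a closed tunnel, and a multichannel crowding session with four stress
inductions.  Every generator returns ``(data, GroundTruth)`` and is
bitwise reproducible from ``(spec, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .errors import GenerationError
from .specs import (
    AccSpec,
    CrowdingResponse,
    CrowdingSchedule,
    EcgSpec,
    GroundTruth,
    RespiroSpec,
    SwimmerSpec,
)

BACKGROUND_LEVEL = 230  # light translucid background
FISH_LEVEL = 30  # dark silhouette seen from below

_N_BODY_SAMPLES = 200  # arc-length samples along the body used for rasterization


@dataclass
class FrameSequence:
    """A stack of 8-bit grayscale silhouette frames."""

    frames: np.ndarray  # (n_frames, height, width) uint8
    fps: float

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


@dataclass
class EcgTraceSet:
    """ECG segments recorded on a fixed cadence."""

    segments: np.ndarray  # (n_segments, n_samples)
    sample_rate: float
    start_times: np.ndarray  # s from session start, one per segment


@dataclass
class AccSeries:
    """Raw tri-axial accelerometer samples in milli-g."""

    samples: np.ndarray  # (n, 3)
    sample_rate: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.shape[0]) / self.sample_rate


@dataclass
class O2Trace:
    """Percent-saturation oxygen readings in a closed tunnel."""

    time_h: np.ndarray
    o2_percent: np.ndarray
    do_max: float  # mg O2 / L
    volume: float  # L


@dataclass
class CrowdingSession:
    """Tidy multichannel crowding-session record.

    ``records`` has columns ``time_min`` (minutes from midnight),
    ``individual``, ``channel`` (hr_bpm | acc_mg | amp_au), ``value``.
    """

    records: pd.DataFrame
    schedule: CrowdingSchedule
    response: CrowdingResponse = field(default_factory=CrowdingResponse)


# ---------------------------------------------------------------------------
# swim-tunnel video
# ---------------------------------------------------------------------------

def _body_geometry(spec: SwimmerSpec):
    """Static body geometry sampled along arc length (head at s=0)."""
    L = spec.length_px
    s = np.linspace(0.0, L, _N_BODY_SAMPLES)
    # amplitude envelope, linear head -> tail
    env = spec.head_yaw_amp + (spec.tail_beat_amp - spec.head_yaw_amp) * s / L
    # width profile: half-elliptic head rising to the max at 0.3 SL, then
    # a linear taper to a narrow caudal peduncle
    w_max = 0.12 * L
    s_h = 0.30 * L
    head = w_max * np.sqrt(np.clip(1.0 - ((s_h - s) / s_h) ** 2, 0.0, 1.0))
    tail = w_max * (1.0 - 0.92 * (s - s_h) / (L - s_h))
    width = np.where(s <= s_h, head, tail)
    width = np.maximum(width, 2.0)
    # opercular bump used to localize the width modulation
    s_op = 0.25 * L
    bump = np.exp(-(((s - s_op) / (0.08 * L)) ** 2))
    return s, env, width, bump


def generate_swim_video(
    spec: SwimmerSpec,
    flow_speed: float = 0.0,
    duration: float = 4.0,
    fps: float = 75.0,
    seed: int = 0,
    frame_shape: tuple[int, int] | None = None,
    noise_sd: float = 0.0,
    phase: float = 0.0,
) -> tuple[FrameSequence, GroundTruth]:
    """Render silhouette frames of a travelling-wave swimmer.

    The midline is a travelling sine with an amplitude envelope growing
    linearly head to tail; the outline is a symmetric width profile
    (half-elliptic head, tapering tail) swept along the midline, with a
    rhythmic width modulation at the opercular station.  The fish is
    dark on a light background, tunnel axis horizontal.

    Returns the frames and a truth record holding the per-frame midline,
    the tail-landmark excursion at 0.8 SL, the opercular head-width
    series, and the four kinematic truth parameters (TBF, TBA, HWF, HWA).
    """
    n_frames = int(round(duration * fps))
    if n_frames < int(np.ceil(0.85 * fps)):
        raise GenerationError(
            "duration*fps must cover at least one 0.85-s spectrogram window"
        )
    rng = np.random.default_rng(seed)
    s, env, width0, bump = _body_geometry(spec)
    L = spec.length_px
    lam = spec.wave_speed_ratio * L

    if frame_shape is None:
        h = int(np.ceil(0.12 * L + 2 * (max(spec.tail_beat_amp, spec.head_yaw_amp)
                                        + spec.opercular_amp) + 40))
        w = int(np.ceil(L + 40))
        frame_shape = (h, w)
    h, w = frame_shape
    x0 = (w - L) / 2.0
    y0 = h / 2.0

    t = np.arange(n_frames) / fps
    frames = np.full((n_frames, h, w), BACKGROUND_LEVEL, dtype=np.uint8)

    s_land = 0.8 * L
    s_op = 0.25 * L
    midlines = np.empty((n_frames, _N_BODY_SAMPLES, 2))
    widths = np.empty((n_frames, _N_BODY_SAMPLES))
    tail_exc = np.empty(n_frames)
    head_width = np.empty(n_frames)

    f = spec.tail_beat_freq
    f_op = spec.opercular_freq
    for i, ti in enumerate(t):
        y = y0 + env * np.sin(2 * np.pi * (f * ti - s / lam) + phase)
        wt = width0 + spec.opercular_amp * np.sin(2 * np.pi * f_op * ti) * bump
        wt = np.maximum(wt, 1.0)
        x = x0 + s
        # outline: midline +/- half width along the local normal
        dx = np.gradient(x)
        dy = np.gradient(y)
        norm = np.hypot(dx, dy)
        nx, ny = -dy / norm, dx / norm
        ux, uy = x + nx * wt / 2, y + ny * wt / 2
        lx, ly = x - nx * wt / 2, y - ny * wt / 2
        px = np.concatenate([ux, lx[::-1]])
        py = np.concatenate([uy, ly[::-1]])
        if (px.min() < 0 or px.max() > w - 1 or py.min() < 0 or py.max() > h - 1):
            raise GenerationError(f"silhouette clipped by frame border at frame {i}")
        rr, cc = draw_polygon(py, px, shape=(h, w))
        frames[i, rr, cc] = FISH_LEVEL
        if noise_sd > 0:
            noisy = frames[i].astype(float) + rng.normal(0, noise_sd, (h, w))
            frames[i] = np.clip(noisy, 0, 255).astype(np.uint8)
        midlines[i, :, 0] = x
        midlines[i, :, 1] = y
        widths[i] = wt
        env_land = np.interp(s_land, s, env)
        tail_exc[i] = env_land * np.sin(2 * np.pi * (f * ti - s_land / lam) + phase)
        head_width[i] = (np.interp(s_op, s, width0)
                         + spec.opercular_amp * np.sin(2 * np.pi * f_op * ti)
                         * np.interp(s_op, s, bump))

    truth = GroundTruth(
        seed=seed,
        spec=spec,
        truth={
            "times_s": t,
            "midline": midlines,
            "width": widths,
            "tail_excursion_px": tail_exc,
            "head_width_px": head_width,
            "tbf_hz": f,
            "tba_px": float(np.interp(s_land, s, env)),
            "hwf_hz": f_op,
            "hwa_px": spec.opercular_amp * float(np.interp(s_op, s, bump)),
            "body_axis_y": y0,
            "flow_speed": flow_speed,
            "expected_area_px2": float(np.trapezoid(widths[0], s)),
        },
    )
    return FrameSequence(frames=frames, fps=fps), truth


# ---------------------------------------------------------------------------
# ECG
# ---------------------------------------------------------------------------

def _qrs_template(sample_rate: float, amplitude: float):
    """Triangular R spike plus smaller S trough; R - S span == amplitude."""
    r_half = max(2, round(0.020 * sample_rate))  # 20-ms R half-width
    s_half = max(1, round(0.015 * sample_rate))
    s_lag = round(0.030 * sample_rate)  # S trough 30 ms after R
    r_h = 0.75 * amplitude
    s_d = 0.25 * amplitude
    n = s_lag + 2 * s_half + r_half + 1
    tpl = np.zeros(n)
    centre = r_half
    for k in range(-r_half, r_half + 1):
        tpl[centre + k] += r_h * (1 - abs(k) / r_half)
    s_centre = centre + s_lag
    for k in range(-s_half, s_half + 1):
        idx = s_centre + k
        if 0 <= idx < n:
            tpl[idx] -= s_d * (1 - abs(k) / s_half)
    return tpl, centre


def generate_ecg(
    spec: EcgSpec,
    n_segments: int = 1,
    seed: int = 0,
    phase: float | None = None,
) -> tuple[EcgTraceSet, GroundTruth]:
    """Synthesize ECG segments with QRS complexes at known beat times.

    ``phase`` fixes the first beat time within every segment (seconds);
    by default it is drawn uniformly per segment.  Raises if a segment
    is shorter than one beat interval at the requested heart rate.
    """
    period = 60.0 / spec.heart_rate
    if period > spec.segment_length:
        raise GenerationError(
            f"segment of {spec.segment_length} s is shorter than one beat "
            f"interval ({period:.2f} s) at {spec.heart_rate} bpm"
        )
    rng = np.random.default_rng(seed)
    n = spec.n_samples
    fs = spec.sample_rate
    tpl, tpl_centre = _qrs_template(fs, spec.qrs_amplitude)

    segments = np.zeros((n_segments, n))
    beat_times = []
    for j in range(n_segments):
        ph = rng.uniform(0, period) if phase is None else phase
        beats = np.arange(ph, spec.segment_length, period)
        # beats whose R centre falls inside the segment are kept; the
        # template is clipped at the segment boundaries
        keep = []
        for tb in beats:
            c = round(tb * fs)
            if not 0 <= c < n:
                continue
            lo = c - tpl_centre
            hi = lo + len(tpl)
            src_lo = max(0, -lo)
            src_hi = len(tpl) - max(0, hi - n)
            segments[j, max(0, lo):min(n, hi)] += tpl[src_lo:src_hi]
            keep.append(tb)
        if spec.noise_sd > 0:
            segments[j] += rng.normal(0, spec.noise_sd, n)
        beat_times.append(np.asarray(keep))

    start_times = np.arange(n_segments) * spec.cadence_min * 60.0
    truth = GroundTruth(
        seed=seed,
        spec=spec,
        truth={
            "beat_times": beat_times,
            "heart_rate_bpm": spec.heart_rate,
            "qrs_amplitude": spec.qrs_amplitude,
        },
    )
    return EcgTraceSet(segments=segments, sample_rate=fs, start_times=start_times), truth


# ---------------------------------------------------------------------------
# accelerometer
# ---------------------------------------------------------------------------

def generate_acc(
    spec: AccSpec,
    duration_min: float,
    seed: int = 0,
) -> tuple[AccSeries, GroundTruth]:
    """Synthesize raw 10-Hz tri-axial samples: gravity + sinusoid + noise.

    The truth record stores the per-minute mean magnitude of the dynamic
    (above-gravity) component, i.e. the external acceleration a perfect
    gravity-removal step would report.
    """
    if duration_min * 60.0 < spec.averaging_window:
        raise ValueError("duration must cover at least one averaging window")
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate
    n = int(round(duration_min * 60.0 * fs))
    t = np.arange(n) / fs
    g = 1000.0 * np.asarray(spec.gravity_orientation)  # 1 g = 1000 mg
    dyn = np.outer(np.sin(2 * np.pi * spec.dynamic_freq * t),
                   np.asarray(spec.dynamic_amp))
    samples = g[None, :] + dyn
    if spec.noise_sd > 0:
        samples = samples + rng.normal(0, spec.noise_sd, samples.shape)

    spw = spec.samples_per_window
    n_windows = n // spw
    dyn_mag = np.linalg.norm(dyn, axis=1)
    true_means = dyn_mag[: n_windows * spw].reshape(n_windows, spw).mean(axis=1)

    truth = GroundTruth(
        seed=seed,
        spec=spec,
        truth={"external_acc_mg": true_means,
               "samples_per_window": spw},
    )
    return AccSeries(samples=samples, sample_rate=fs), truth


# ---------------------------------------------------------------------------
# respirometry
# ---------------------------------------------------------------------------

def generate_o2_trace(spec: RespiroSpec, seed: int = 0) -> tuple[O2Trace, GroundTruth]:
    """Synthesize a linear %-saturation decline in a closed tunnel.

    The slope is the one implied by inverting the oxygen-consumption
    relation MO2 = dO2% * (DOmax * L / 100) / t for the combined fish +
    background rate.  Raises if the trace would cross 0 % within the
    measurement window.
    """
    rng = np.random.default_rng(seed)
    slope_pct_per_h = (spec.true_mo2 + spec.background_rate) / (
        spec.do_max * spec.tunnel_volume / 100.0
    )
    t_h = np.arange(0.0, spec.measurement_duration * 60.0 + 1e-9,
                    spec.sample_interval) / 3600.0
    o2 = spec.start_percent - slope_pct_per_h * t_h
    if o2.min() < 0:
        raise GenerationError(
            "parameters imply oxygen below 0 % within the measurement window"
        )
    if spec.noise_sd > 0:
        o2 = o2 + rng.normal(0, spec.noise_sd, o2.shape)
    truth = GroundTruth(
        seed=seed,
        spec=spec,
        truth={
            "true_mo2": spec.true_mo2,
            "background_rate": spec.background_rate,
            "slope_pct_per_h": slope_pct_per_h,
        },
    )
    return O2Trace(time_h=t_h, o2_percent=o2, do_max=spec.do_max,
                   volume=spec.tunnel_volume), truth


# ---------------------------------------------------------------------------
# crowding session
# ---------------------------------------------------------------------------

def _step_decay(t: np.ndarray, events: np.ndarray, peaks: np.ndarray,
                basal: float, tau: float, cumulative: bool) -> np.ndarray:
    """Noiseless channel trajectory: spikes at events decaying with tau.

    ``cumulative`` selects the heart-rate style model where increments
    are solved so the value at each event equals the target peak despite
    residual elevation from earlier events.
    """
    increments = np.empty_like(peaks)
    for k, (tk, pk) in enumerate(zip(events, peaks)):
        residual = sum(
            increments[j] * np.exp(-(tk - events[j]) / tau)
            for j in range(k)
        ) if cumulative else 0.0
        increments[k] = pk - basal - residual
    out = np.full_like(t, basal, dtype=float)
    for tk, inc in zip(events, increments):
        mask = t >= tk
        out[mask] += inc * np.exp(-(t[mask] - tk) / tau)
    return out


def crowding_phase_for_time(t: float, schedule: CrowdingSchedule) -> str:
    """Phase label for one measurement time (minutes from midnight).

    Labels: ``basal`` before the first event, ``stress_k`` for the
    measurement taken at event k (within one cadence step), ``recovery_k``
    for the 50 min following it, ``final_rec`` 2-4 h after the last
    event, ``uncategorized`` otherwise.
    """
    events = schedule.stress_times
    cad = schedule.measurement_cadence
    if t < events[0]:
        return "basal"
    for k, ek in enumerate(events, start=1):
        if ek <= t < ek + cad:
            return f"stress_{k}"
        if ek + cad <= t <= ek + schedule.recovery_window:
            if k < len(events) and t >= events[k]:
                continue  # next event takes precedence (does not occur at defaults)
            return f"recovery_{k}"
    last = events[-1]
    lo, hi = schedule.post_window
    if last + lo <= t <= last + hi:
        return "final_rec"
    return "uncategorized"


def generate_crowding_session(
    schedule: CrowdingSchedule | None = None,
    response: CrowdingResponse | None = None,
    seed: int = 0,
    n_individuals: int = 12,
    session_start_min: float = 6 * 60.0,
    session_end_min: float | None = None,
) -> tuple[CrowdingSession, GroundTruth]:
    """Simulate HR/AMP (10-min cadence) and ACC (1-min) during crowding.

    Heart rate accumulates across events (partial exponential decay, no
    return to basal); ACC and AMP spike at each event and decay quickly.
    Each individual carries a random intercept.  Truth stores the
    noiseless trajectories and the phase label of every measurement.
    """
    schedule = schedule or CrowdingSchedule()
    response = response or CrowdingResponse()
    rng = np.random.default_rng(seed)
    events = np.asarray(schedule.stress_times, dtype=float)
    if session_end_min is None:
        session_end_min = events[-1] + schedule.post_window[1]

    cad = schedule.measurement_cadence
    t_slow = np.arange(session_start_min, session_end_min + 1e-9, cad)
    t_fast = np.arange(session_start_min, session_end_min + 1e-9, 1.0)

    hr_true = _step_decay(t_slow, events, np.asarray(response.hr_stress_peaks),
                          response.hr_basal, response.hr_tau_min, cumulative=True)
    amp_true = _step_decay(t_slow, events, np.asarray(response.amp_stress_peaks),
                           response.amp_basal, response.amp_tau_min, cumulative=False)
    acc_true = _step_decay(t_fast, events, np.asarray(response.acc_stress_peaks),
                           response.acc_basal, response.acc_tau_min, cumulative=False)

    frames = []
    for ind in range(n_individuals):
        offset = rng.normal(0.0, response.individual_sd)
        for name, tt, base, sd, scale in (
            ("hr_bpm", t_slow, hr_true, response.hr_noise_sd, 1.0),
            ("amp_au", t_slow, amp_true, response.amp_noise_sd, 0.3),
            ("acc_mg", t_fast, acc_true, response.acc_noise_sd, 0.2),
        ):
            vals = base + scale * offset + rng.normal(0.0, sd, tt.shape)
            frames.append(pd.DataFrame({
                "time_min": tt,
                "individual": f"fish_{ind:02d}",
                "channel": name,
                "value": vals,
            }))
    records = pd.concat(frames, ignore_index=True)

    truth = GroundTruth(
        seed=seed,
        spec=(schedule, response),
        truth={
            "time_slow_min": t_slow,
            "time_fast_min": t_fast,
            "hr_true": hr_true,
            "amp_true": amp_true,
            "acc_true": acc_true,
            "phase_slow": np.array([crowding_phase_for_time(t, schedule)
                                    for t in t_slow]),
            "phase_fast": np.array([crowding_phase_for_time(t, schedule)
                                    for t in t_fast]),
            "n_events": schedule.n_events,
        },
    )
    return CrowdingSession(records=records, schedule=schedule,
                           response=response), truth
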