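"""Parameter specifications for the synthetic-data generators.

Each spec is a frozen dataclass whose defaults encode the study conditions
of the experiments the generators emulate: a ~28-cm, ~390-g European sea
bass swimming in a 127-L swim tunnel filmed at 75 fps, an implanted
biologger sampling ECG at 200 Hz for 7.5 s every 10 min and tri-axial
acceleration at 10 Hz averaged per minute, and a four-event crowding
stress session with inductions on the hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Sequence


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class SwimmerSpec:
    """Geometry and kinematics of the simulated swimmer.

    Lengths are in cm (converted to px via ``pixel_scale``), frequencies
    in Hz and amplitudes in px.  ``tail_beat_amp`` is the lateral
    half-peak-to-peak excursion of the travelling wave at the tail tip;
    the amplitude envelope grows linearly from ``head_yaw_amp`` at the
    snout to ``tail_beat_amp`` at the tail.  ``wave_speed_ratio`` is the
    body-wave wavelength expressed in standard lengths.
    """

    standard_length: float = 28.3  # cm
    body_mass: float = 391.0  # g
    tail_beat_freq: float = 3.0  # Hz
    tail_beat_amp: float = 20.0  # px at the tail tip
    head_yaw_amp: float = 2.0  # px at the snout
    opercular_freq: float = 4.5  # Hz, rhythmic head-width (opercular) pumping
    opercular_amp: float = 3.0  # px, half-peak-to-peak width modulation
    wave_speed_ratio: float = 1.0  # wavelength / SL
    pixel_scale: float = 10.0  # px per cm

    def __post_init__(self) -> None:
        _require(self.standard_length > 0, "standard_length must be > 0")
        _require(self.body_mass > 0, "body_mass must be > 0")
        _require(self.tail_beat_freq >= 0, "tail_beat_freq must be >= 0")
        _require(self.tail_beat_amp >= 0, "tail_beat_amp must be >= 0")
        _require(self.head_yaw_amp >= 0, "head_yaw_amp must be >= 0")
        _require(self.opercular_amp >= 0, "opercular_amp must be >= 0")
        _require(self.pixel_scale > 0, "pixel_scale must be > 0")
        _require(self.wave_speed_ratio > 0, "wave_speed_ratio must be > 0")

    @property
    def length_px(self) -> float:
        return self.standard_length * self.pixel_scale


@dataclass(frozen=True)
class EcgSpec:
    """Parameters of the simulated single-lead ECG segments.

    ``qrs_amplitude`` is the R-peak-to-S-trough span in the logger's
    arbitrary units; noise is additive Gaussian.
    """

    heart_rate: float = 60.0  # bpm
    qrs_amplitude: float = 250.0  # a.u., R - S span
    noise_sd: float = 10.0  # a.u.
    sample_rate: float = 200.0  # Hz
    segment_length: float = 7.5  # s
    cadence_min: float = 10.0  # one segment every `cadence_min` minutes

    def __post_init__(self) -> None:
        _require(self.heart_rate > 0, "heart_rate must be > 0")
        _require(self.qrs_amplitude > 0, "qrs_amplitude must be > 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        n = self.sample_rate * self.segment_length
        _require(
            abs(n - round(n)) < 1e-9,
            "sample_rate * segment_length must be an integer sample count",
        )

    @property
    def n_samples(self) -> int:
        return round(self.sample_rate * self.segment_length)


@dataclass(frozen=True)
class AccSpec:
    """Parameters of the simulated tri-axial accelerometer stream (milli-g)."""

    gravity_orientation: tuple[float, float, float] = (0.0, 0.0, 1.0)
    dynamic_amp: tuple[float, float, float] = (20.0, 0.0, 0.0)  # mg per axis
    dynamic_freq: float = 1.5  # Hz; 1.5 at 10 Hz sampling covers a uniform
    # 20-point phase grid per 2 s, so the discrete |sin| mean matches the
    # continuous 2A/pi and the 2-s gravity moving average nulls it exactly
    noise_sd: float = 0.0  # mg
    sample_rate: float = 10.0  # Hz
    averaging_window: float = 60.0  # s

    def __post_init__(self) -> None:
        norm = math.sqrt(sum(c * c for c in self.gravity_orientation))
        _require(abs(norm - 1.0) < 1e-9, "gravity_orientation must be a unit vector")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.sample_rate > 0 and self.averaging_window > 0,
                 "sample_rate and averaging_window must be > 0")

    @property
    def samples_per_window(self) -> int:
        return round(self.sample_rate * self.averaging_window)


@dataclass(frozen=True)
class RespiroSpec:
    """Parameters of a closed-tunnel oxygen-decline measurement.

    ``true_mo2`` and ``background_rate`` are absolute rates in mg O2/h;
    the dissolved-oxygen ceiling defaults to 7.157 mg O2/L (22 degC
    seawater) in a 127-L tunnel measured over 40 min.
    """

    do_max: float = 7.157  # mg O2 / L at saturation
    tunnel_volume: float = 127.0  # L
    true_mo2: float = 100.0  # mg O2 / h, fish only
    background_rate: float = 0.0  # mg O2 / h, bacterial
    noise_sd: float = 0.05  # % saturation
    measurement_duration: float = 40.0  # min
    sample_interval: float = 2.0  # s between probe readings
    start_percent: float = 100.0

    def __post_init__(self) -> None:
        _require(self.do_max > 0, "do_max must be > 0")
        _require(self.tunnel_volume > 0, "tunnel_volume must be > 0")
        _require(self.true_mo2 >= 0, "true_mo2 must be >= 0")
        _require(self.background_rate >= 0, "background_rate must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.measurement_duration > 0, "measurement_duration must be > 0")


def _as_minutes(t: Any) -> float:
    """Accept 'HH:MM' strings or numeric minutes-from-midnight."""
    if isinstance(t, str):
        hh, mm = t.split(":")
        return int(hh) * 60.0 + int(mm)
    return float(t)


@dataclass(frozen=True)
class CrowdingSchedule:
    """Timing of the four-step crowding stress protocol.

    Events default to on-the-hour inductions at 10:00-13:00.  The four
    hold durations (refill immediately, after 1 min, after 5 min, and
    after 5 min with chasing) are carried as protocol metadata; the
    response generator treats every event as an instantaneous spike.
    Phase windows: each stressor is followed by a 50-min recovery
    window; the final-recovery window spans 2-4 h after the last event.
    """

    stress_times: tuple[float, ...] = ("10:00", "11:00", "12:00", "13:00")
    hold_durations: tuple[float, ...] = (0.0, 1.0, 5.0, 5.0)  # min
    measurement_cadence: float = 10.0  # min
    recovery_window: float = 50.0  # min after each event
    post_window: tuple[float, float] = (120.0, 240.0)  # min after last event
    basal_window: float = 240.0  # min before first event

    def __post_init__(self) -> None:
        times = tuple(_as_minutes(t) for t in self.stress_times)
        object.__setattr__(self, "stress_times", times)
        _require(all(b > a for a, b in zip(times, times[1:])),
                 "stress_times must be strictly increasing")
        _require(self.measurement_cadence > 0, "measurement_cadence must be > 0")
        _require(self.post_window[1] > self.post_window[0] >= 0,
                 "post_window must be an increasing pair")

    @property
    def n_events(self) -> int:
        return len(self.stress_times)


@dataclass(frozen=True)
class CrowdingResponse:
    """Noiseless response model for the crowding session, per channel.

    Heart rate follows a step-and-partial-decay model: each event adds an
    increment chosen so the value *at* the event equals the corresponding
    ``hr_stress_peaks`` entry, then decays exponentially (time constant
    ``hr_tau_min``) without returning to basal between events.  ACC and
    AMP spike at each event and decay quickly back to baseline.  Default
    peak levels are calibration values reproducing the printed per-event
    means of the study this emulates (the third heart-rate peak is not
    printed and is interpolated).
    """

    hr_basal: float = 61.94  # bpm
    hr_stress_peaks: tuple[float, ...] = (83.91, 89.9, 96.9, 104.0)
    hr_tau_min: float = 90.0
    hr_noise_sd: float = 2.0
    acc_basal: float = 11.83  # mg
    acc_stress_peaks: tuple[float, ...] = (52.25, 54.33, 56.58, 37.66)
    acc_tau_min: float = 2.0
    acc_noise_sd: float = 1.5
    amp_basal: float = 12.24  # a.u.
    amp_stress_peaks: tuple[float, ...] = (165.85, 267.83, 284.63, 264.04)
    amp_tau_min: float = 2.0
    amp_noise_sd: float = 4.0
    individual_sd: float = 4.0  # between-individual random intercept SD (HR scale)

    def __post_init__(self) -> None:
        _require(self.hr_basal > 0, "hr_basal must be > 0")
        _require(self.hr_tau_min > 0 and self.acc_tau_min > 0 and self.amp_tau_min > 0,
                 "decay time constants must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Truth record attached to every generated dataset.

    ``truth`` holds per-channel truth arrays and scalars (beat times,
    noiseless trajectories, true rates, per-frame midlines, phase
    labels); the spec echo and seed make every sample reproducible.
    """

    seed: int
    spec: Any
    truth: dict = field(default_factory=dict)

    def __getitem__(self, key: str):
        return self.truth[key]
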