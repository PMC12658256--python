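"""Biologger signal processing: heart rate, QRS amplitude, activity.

Raw inputs are the modalities an implanted archival tag records: short
single-lead ECG segments (200 Hz, 7.5 s, every 10 min) and 10-Hz
tri-axial acceleration.  Outputs are the derived channels used in the
downstream challenge analyses: heart rate in bpm from an automatic QRS
detector, QRS amplitude (R-peak minus S-trough span) in the tag's
arbitrary units, minute-averaged external acceleration in milli-g, and
20-point pre-experiment baselines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, filtfilt, find_peaks

log = logging.getLogger(__name__)

REFRACTORY_S = 0.2  # minimum spacing between detected beats
SEARCH_S = 0.060  # S-trough search half-window around the R peak


class QualityFlag(str, Enum):
    OK = "ok"
    LOW_CONFIDENCE = "low_confidence"
    REJECTED = "rejected"


@dataclass
class QrsDetection:
    """Automatic QRS annotation of one ECG segment."""

    beat_times: np.ndarray  # s, strictly increasing
    amplitudes: np.ndarray  # a.u., per-beat R - S span
    flag: QualityFlag

    @property
    def n_beats(self) -> int:
        return self.beat_times.size


@dataclass
class CardiacRecord:
    """One HR/AMP measurement point."""

    time_s: float
    hr_bpm: float | None
    amp_au: float | None
    flag: QualityFlag


@dataclass
class Baseline:
    """Pre-experiment reference level of one channel."""

    mean: float
    se: float
    n: int
    channel: str

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a baseline needs at least 2 points")
        if self.se < 0:
            raise ValueError("se must be >= 0")


def _two_means_threshold(heights: np.ndarray) -> tuple[float, float]:
    """Split peak heights into noise/beat clusters; midpoint threshold.

    Returns (threshold, separation ratio of the cluster centres).
    """
    c1, c2 = float(heights.min()), float(heights.max())
    for _ in range(50):
        mid = 0.5 * (c1 + c2)
        lo, hi = heights[heights <= mid], heights[heights > mid]
        if lo.size == 0 or hi.size == 0:
            break
        n1, n2 = float(lo.mean()), float(hi.mean())
        if n1 == c1 and n2 == c2:
            break
        c1, c2 = n1, n2
    return 0.5 * (c1 + c2), c2 / max(c1, 1e-12)


def detect_qrs(
    samples: np.ndarray,
    sample_rate: float = 200.0,
    snr_floor: float = 2.0,
) -> QrsDetection:
    """Automatic QRS detection on one ECG segment.

    Pipeline: 5-40 Hz band-pass, squared energy smoothed over 50 ms,
    candidate peaks at 200-ms refractory spacing, adaptive threshold by
    two-means clustering of candidate heights, then an inter-beat-
    interval repair pass (weak extra beats inside 0.55x the median
    interval are dropped; gaps near twice the median are filled with the
    best sub-threshold candidate).  Each beat is refined to the local R
    maximum of the raw signal and paired with the S trough within
    +/-60 ms; the per-beat amplitude is the R - S span.  A flat segment
    returns no beats with a ``rejected`` flag; weak separation between
    the beat and noise clusters yields ``low_confidence``.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2 * sample_rate:
        raise ValueError("need at least 2 s of signal")
    if np.ptp(x) < 1e-12:
        return QrsDetection(np.empty(0), np.empty(0), QualityFlag.REJECTED)

    nyq = sample_rate / 2.0
    b, a = butter(2, [5.0 / nyq, 40.0 / nyq], btype="band")
    filt = filtfilt(b, a, x)
    energy = uniform_filter1d(filt ** 2, max(3, round(0.050 * sample_rate)))
    refractory = round(REFRACTORY_S * sample_rate)
    candidates, _ = find_peaks(energy, distance=refractory)
    if candidates.size == 0:
        return QrsDetection(np.empty(0), np.empty(0), QualityFlag.REJECTED)
    heights = np.sqrt(energy[candidates])
    threshold, separation = _two_means_threshold(heights)
    height_of = dict(zip(candidates.tolist(), heights.tolist()))
    beats = [int(p) for p, h in zip(candidates, heights) if h > threshold]
    if not beats:
        return QrsDetection(np.empty(0), np.empty(0), QualityFlag.REJECTED)

    # inter-beat-interval repair: drop weak extras, fill missed beats
    for _ in range(4):
        if len(beats) < 3:
            break
        ibis = np.diff(beats)
        med = float(np.median(ibis))
        action = False
        for i, d in enumerate(ibis):
            if d < 0.55 * med:
                weaker = i if height_of[beats[i]] < height_of[beats[i + 1]] \
                    else i + 1
                del beats[weaker]
                action = True
                break
        if action:
            continue
        for i, d in enumerate(ibis):
            if 1.6 * med < d < 2.6 * med:
                gap = [p for p in candidates
                       if beats[i] + refractory <= p <= beats[i + 1] - refractory]
                if gap:
                    beats = sorted(beats + [int(max(gap, key=height_of.get))])
                    action = True
                break
        if not action:
            break

    # refine to the raw R peak; a consensus R/S offset across beats keeps
    # the per-beat extreme-value bias of noisy argmax/argmin searches small
    half = round(SEARCH_S * sample_rate)
    tight = max(2, round(0.040 * sample_rate))  # provisional R search: +/-40 ms
    provisional = []
    for p in beats:
        lo, hi = max(0, p - tight), min(x.size, p + tight + 1)
        provisional.append(lo + int(np.argmax(x[lo:hi])))
    r_shift = int(np.median([r - p for r, p in zip(provisional, beats)]))
    s_offsets = []
    for r in provisional:
        lo, hi = max(0, r - half), min(x.size, r + half + 1)
        s_offsets.append(lo + int(np.argmin(x[lo:hi])) - r)
    s_shift = int(np.median(s_offsets))

    beat_idx, amps = [], []
    for p in beats:
        r0 = min(max(p + r_shift, 1), x.size - 2)
        r_idx = r0 - 1 + int(np.argmax(x[r0 - 1:r0 + 2]))
        s0 = min(max(r_idx + s_shift, 1), x.size - 2)
        s_val = float(np.min(x[s0 - 1:s0 + 2]))
        beat_idx.append(r_idx)
        amps.append(float(x[r_idx]) - s_val)
    order = np.argsort(beat_idx)
    beat_idx = np.asarray(beat_idx)[order]
    amps = np.asarray(amps)[order]

    flag = QualityFlag.OK if separation >= snr_floor else \
        QualityFlag.LOW_CONFIDENCE
    return QrsDetection(beat_times=beat_idx / sample_rate, amplitudes=amps,
                        flag=flag)


def heart_rate(beat_times: np.ndarray, segment_duration: float | None = None
               ) -> float | None:
    """Heart rate in bpm from the mean inter-beat interval.

    HR = 60 * (n - 1) / (t_n - t_1).  Returns None (record to be
    flagged) with fewer than 2 beats.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2:
        return None
    span = beat_times[-1] - beat_times[0]
    if span <= 0:
        return None
    return 60.0 * (beat_times.size - 1) / span


def segment_cardiac_record(samples: np.ndarray, time_s: float,
                           sample_rate: float = 200.0) -> CardiacRecord:
    """HR and AMP for one ECG segment, carrying the detector's flag."""
    det = detect_qrs(samples, sample_rate)
    hr = heart_rate(det.beat_times)
    amp = float(np.median(det.amplitudes)) if det.n_beats else None
    flag = det.flag
    if hr is None and flag == QualityFlag.OK:
        flag = QualityFlag.REJECTED
    return CardiacRecord(time_s=time_s, hr_bpm=hr, amp_au=amp, flag=flag)


def external_acceleration(
    samples: np.ndarray,
    sample_rate: float = 10.0,
    window_s: float = 60.0,
    gravity_window_s: float = 2.0,
) -> np.ndarray:
    """Minute-averaged external (above-gravity) acceleration in milli-g.

    The gravity component is removed per axis with a moving average over
    ``gravity_window_s``; the Euclidean norm of the residual is averaged
    over each full ``window_s`` window.  A trailing partial window is
    dropped with a log entry.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 3:
        raise ValueError("samples must be an (n, 3) tri-axial array")
    n_g = max(1, round(gravity_window_s * sample_rate))
    gravity = uniform_filter1d(samples, n_g, axis=0, mode="nearest")
    residual = samples - gravity
    mag = np.linalg.norm(residual, axis=1)
    spw = round(window_s * sample_rate)
    n_windows = mag.size // spw
    dropped = mag.size - n_windows * spw
    if dropped:
        log.info("dropping trailing partial window of %d samples", dropped)
    if n_windows == 0:
        raise ValueError("no full averaging window in the input")
    return mag[: n_windows * spw].reshape(n_windows, spw).mean(axis=1)


def compute_baseline(values: np.ndarray, n: int = 20,
                     channel: str = "hr_bpm") -> Baseline:
    """Mean and SE of the ``n`` most recent pre-experiment points."""
    values = np.asarray(values, dtype=float)
    if values.size < n:
        raise ValueError(
            f"baseline needs {n} points but only {values.size} are available"
        )
    tail = values[-n:]
    return Baseline(mean=float(tail.mean()),
                    se=float(tail.std(ddof=1) / np.sqrt(n)),
                    n=n, channel=channel)
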