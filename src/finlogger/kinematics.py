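"""Silhouette tracking and spectral kinematics of a swimming fish.

The processing chain mirrors a swim-tunnel video analysis: a luminance
threshold selects dark objects against the light background, the fish is
picked among candidate contours by surface area and length/width ratio,
a midline (central axis) is extracted per frame, and the lateral
excursion of a tail landmark at 0.8x standard length — together with the
head width at the opercular station — is analysed with a short-time
spectrogram (0.85-s Hann window shifted frame by frame).  Tail/head beat
frequency and amplitude are read from the spectrogram maximum at each
frame, with parabolic interpolation around the peak bin for sub-bin
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import polygon as draw_polygon
from skimage.measure import find_contours, label, regionprops

from .errors import AmbiguousDetection, FinloggerError, NoFishDetected
from .synthetic import FrameSequence

DEFAULT_WINDOW_S = 0.85
DEFAULT_LANDMARK_FRACTION = 0.8
DEFAULT_OPERCULAR_FRACTION = 0.25


@dataclass
class Contour:
    """A closed fish-candidate outline in pixel coordinates (x, y)."""

    xy: np.ndarray  # (n, 2), closed polygon (first point == last point)
    area: float  # px^2, shoelace area of the polygon
    length_width_ratio: float

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("contour area must be > 0")


@dataclass
class Midline:
    """Ordered central axis of one frame, head first."""

    points: np.ndarray  # (n_points, 2) as (x, y)
    widths: np.ndarray  # (n_points,) body width at each midline point
    arc_length: np.ndarray  # (n_points,) cumulative, strictly increasing


@dataclass
class MidlineTrack:
    """Per-frame midlines with a common point count."""

    points: np.ndarray  # (n_frames, n_points, 2)
    widths: np.ndarray  # (n_frames, n_points)
    frame_rate: float

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


@dataclass
class ExcursionSeries:
    """Signed lateral excursion of a body landmark, one value per frame."""

    time: np.ndarray  # s
    lateral_excursion: np.ndarray  # px, + toward +y (image down)
    landmark_fraction: float


@dataclass
class SpectroTrack:
    """Per-frame dominant frequency and amplitude from the spectrogram."""

    time: np.ndarray  # s, window centres
    frequency: np.ndarray  # Hz
    amplitude: np.ndarray  # px, sinusoid-equivalent amplitude
    window_s: float


@dataclass
class KinematicsSummary:
    """Trial-level tail and head beat statistics.

    TBF/HWF in Hz; TBA/HWA in px, or cm when a pixel scale is supplied.
    """

    tbf: float
    tba: float
    hwf: float
    hwa: float
    units: str = "px"


def _shoelace_area(xy: np.ndarray) -> float:
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def detect_fish_contour(
    frame: np.ndarray,
    luminance_threshold: float = 128,
    area_range: tuple[float, float] = (500.0, 1e7),
    ratio_range: tuple[float, float] = (2.0, 20.0),
) -> Contour:
    """Select the fish outline among dark objects in a grayscale frame.

    Objects darker than ``luminance_threshold`` are labelled; the unique
    object whose filled area lies in ``area_range`` and whose
    major/minor-axis ratio lies in ``ratio_range`` is returned as a
    closed contour.  Raises :class:`NoFishDetected` when nothing passes
    and :class:`AmbiguousDetection` when several objects do.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise ValueError("frame must be a 2-D grayscale image")
    mask = frame < luminance_threshold
    labelled = label(mask)
    passing = []
    for prop in regionprops(labelled):
        minor = max(prop.axis_minor_length, 1e-9)
        ratio = prop.axis_major_length / minor
        if area_range[0] <= prop.area <= area_range[1] and \
                ratio_range[0] <= ratio <= ratio_range[1]:
            passing.append((prop, ratio))
    if not passing:
        raise NoFishDetected(
            f"no object passed area {area_range} and ratio {ratio_range} filters"
        )
    if len(passing) > 1:
        raise AmbiguousDetection([(p.area, r) for p, r in passing])
    prop, ratio = passing[0]
    obj_mask = np.zeros(frame.shape, dtype=float)
    obj_mask[labelled == prop.label] = 1.0
    contours = find_contours(obj_mask, 0.5)
    outline = max(contours, key=len)  # (row, col) -> (x, y)
    xy = outline[:, ::-1].copy()
    return Contour(xy=xy, area=_shoelace_area(xy[:-1] if np.allclose(xy[0], xy[-1])
                                              else xy),
                   length_width_ratio=ratio)


def _mask_from_contour(contour: Contour) -> tuple[np.ndarray, int, int]:
    """Rasterize the contour polygon into a tight binary mask."""
    xy = contour.xy
    x_off = int(np.floor(xy[:, 0].min())) - 1
    y_off = int(np.floor(xy[:, 1].min())) - 1
    h = int(np.ceil(xy[:, 1].max())) - y_off + 2
    w = int(np.ceil(xy[:, 0].max())) - x_off + 2
    rr, cc = draw_polygon(xy[:, 1] - y_off, xy[:, 0] - x_off, shape=(h, w))
    mask = np.zeros((h, w), dtype=bool)
    mask[rr, cc] = True
    return mask, x_off, y_off


def extract_midline(contour: Contour, n_points: int = 100) -> Midline:
    """Central axis of a near-horizontal silhouette, head first.

    The filled silhouette is scanned column by column along the tunnel
    axis; the midline point of each column is the centre of the vertical
    pixel run and the local width is its extent.  Points are resampled
    to ``n_points`` equally spaced in arc length.  The head end is the
    end with the larger mean body width over the first 20 % of arc
    length.
    """
    if contour.xy.shape[0] < 3:
        raise FinloggerError("degenerate contour: fewer than 3 points")
    mask, x_off, y_off = _mask_from_contour(contour)
    cols = np.where(mask.any(axis=0))[0]
    if cols.size < 3:
        raise FinloggerError("degenerate contour: silhouette narrower than 3 px")
    # restrict to the contiguous span containing the bulk of the object
    xs, ys, ws = [], [], []
    for c in range(cols.min(), cols.max() + 1):
        rows = np.where(mask[:, c])[0]
        if rows.size == 0:
            continue
        xs.append(c + x_off)
        ys.append(0.5 * (rows.min() + rows.max()) + y_off)
        ws.append(float(rows.max() - rows.min() + 1))
    pts = np.column_stack([xs, ys]).astype(float)
    widths = np.asarray(ws)

    seg = np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total <= 0:
        raise FinloggerError("degenerate contour: zero-length midline")

    # head = wider end over the anterior 20 % of arc length
    head_mask = arc <= 0.2 * total
    tail_mask = arc >= 0.8 * total
    if widths[tail_mask].mean() > widths[head_mask].mean():
        pts = pts[::-1]
        widths = widths[::-1]
        arc = total - arc[::-1]

    target = np.linspace(0.0, total, n_points)
    out = np.column_stack([
        np.interp(target, arc, pts[:, 0]),
        np.interp(target, arc, pts[:, 1]),
    ])
    w_out = np.interp(target, arc, widths)
    return Midline(points=out, widths=w_out, arc_length=target)


def track_video(
    frames: FrameSequence,
    luminance_threshold: float = 128,
    area_range: tuple[float, float] = (500.0, 1e7),
    ratio_range: tuple[float, float] = (2.0, 20.0),
    n_points: int = 100,
) -> MidlineTrack:
    """Detect the fish and extract its midline in every frame."""
    pts = np.empty((frames.n_frames, n_points, 2))
    wds = np.empty((frames.n_frames, n_points))
    for i in range(frames.n_frames):
        contour = detect_fish_contour(frames.frames[i], luminance_threshold,
                                      area_range, ratio_range)
        ml = extract_midline(contour, n_points)
        pts[i] = ml.points
        wds[i] = ml.widths
    return MidlineTrack(points=pts, widths=wds, frame_rate=frames.fps)


def _head_axis(points: np.ndarray) -> tuple[float, float]:
    """Least-squares line y = a + b x through the anterior 20 % of points."""
    n_head = max(2, points.shape[0] // 5)
    x = points[:n_head, 0]
    y = points[:n_head, 1]
    b, a = np.polyfit(x, y, 1)
    return a, b


def landmark_excursion(track: MidlineTrack,
                       fraction: float = DEFAULT_LANDMARK_FRACTION,
                       axis: str = "mean") -> ExcursionSeries:
    """Signed lateral excursion of the point at ``fraction`` of arc length.

    The excursion is the perpendicular distance from the reference axis
    through the head (least-squares line through the anterior 20 % of
    midline points), positive toward +y.  With ``axis="mean"`` (the
    default) the head axis is averaged over the trial before projecting:
    a station-holding fish yaws its head with the body wave, and the
    instantaneous axis slope, extrapolated to the tail, would inflate
    the apparent excursion severalfold.  ``axis="per_frame"`` keeps the
    instantaneous axis for free-swimming sequences.
    """
    if not 0 < fraction <= 1:
        raise ValueError("landmark fraction must lie in (0, 1]")
    if axis not in ("mean", "per_frame"):
        raise ValueError("axis must be 'mean' or 'per_frame'")
    n_frames, n_points, _ = track.points.shape
    idx = fraction * (n_points - 1)
    lo = int(np.floor(idx))
    hi = min(lo + 1, n_points - 1)
    frac = idx - lo
    axes = np.array([_head_axis(track.points[i]) for i in range(n_frames)])
    if axis == "mean":
        axes = np.broadcast_to(axes.mean(axis=0), axes.shape)
    exc = np.empty(n_frames)
    for i in range(n_frames):
        pts = track.points[i]
        a, b = axes[i]
        p = (1 - frac) * pts[lo] + frac * pts[hi]
        exc[i] = (p[1] - a - b * p[0]) / np.hypot(1.0, b)
    return ExcursionSeries(time=track.times, lateral_excursion=exc,
                           landmark_fraction=fraction)


def head_width_series(track: MidlineTrack,
                      head_region_fraction: float = DEFAULT_OPERCULAR_FRACTION
                      ) -> np.ndarray:
    """Body width at the opercular station (default 0.25x arc length)."""
    if not 0 < head_region_fraction < 1:
        raise ValueError("head_region_fraction must lie in (0, 1)")
    n_points = track.widths.shape[1]
    idx = head_region_fraction * (n_points - 1)
    lo = int(np.floor(idx))
    hi = min(lo + 1, n_points - 1)
    frac = idx - lo
    return (1 - frac) * track.widths[:, lo] + frac * track.widths[:, hi]


def _parabolic_peak(mag: np.ndarray, k: int) -> tuple[float, float]:
    """Sub-bin peak location and height by parabolic interpolation on log |X|."""
    if k <= 0 or k >= mag.size - 1:
        return float(k), mag[k]
    a, b, c = np.log(mag[k - 1] + 1e-300), np.log(mag[k] + 1e-300), \
        np.log(mag[k + 1] + 1e-300)
    denom = a - 2 * b + c
    if denom == 0:
        return float(k), mag[k]
    delta = 0.5 * (a - c) / denom
    height = np.exp(b - 0.25 * (a - c) * delta)
    return k + delta, height


def spectro_kinematics(
    series: np.ndarray | ExcursionSeries,
    fps: float,
    window_s: float = DEFAULT_WINDOW_S,
    amplitude_floor: float = 1e-6,
) -> SpectroTrack:
    """Dominant non-DC frequency and amplitude per frame.

    A Hann window of ``window_s`` (rounded to a whole frame count) is
    shifted one frame at a time; at each position the non-DC spectrogram
    maximum gives the frequency (parabolically interpolated) and the
    amplitude, scaled so a pure sinusoid of amplitude A returns A.
    Windows whose peak falls below ``amplitude_floor`` report zero
    amplitude and zero frequency.
    """
    if isinstance(series, ExcursionSeries):
        values = series.lateral_excursion
    else:
        values = np.asarray(series, dtype=float)
    n_win = int(round(window_s * fps))
    if values.size < n_win:
        raise ValueError(
            f"series of {values.size} samples is shorter than the "
            f"{n_win}-frame analysis window"
        )
    win = np.hanning(n_win)
    scale = 2.0 / win.sum()  # |X_peak| * scale == sinusoid amplitude
    n_out = values.size - n_win + 1
    freqs = np.empty(n_out)
    amps = np.empty(n_out)
    centre = (n_win - 1) / 2.0
    for i in range(n_out):
        seg = values[i:i + n_win]
        seg = seg - seg.mean()  # remove DC so the peak is the oscillation
        mag = np.abs(np.fft.rfft(seg * win))
        mag[0] = 0.0
        k = int(np.argmax(mag))
        if mag[k] * scale < amplitude_floor:
            freqs[i] = 0.0
            amps[i] = 0.0
            continue
        pos, height = _parabolic_peak(mag, k)
        freqs[i] = pos * fps / n_win
        amps[i] = height * scale
    times = (np.arange(n_out) + centre) / fps
    return SpectroTrack(time=times, frequency=freqs, amplitude=amps,
                        window_s=n_win / fps)


def summarize_kinematics(
    tail_track: SpectroTrack,
    head_track: SpectroTrack,
    pixel_scale: float | None = None,
) -> KinematicsSummary:
    """Trial-level means of the per-frame spectrogram tracks.

    TBF/TBA come from the tail-excursion track, HWF/HWA from the
    head-width track.  With ``pixel_scale`` (px per cm) the amplitudes
    are converted to cm.
    """
    if tail_track.frequency.size == 0 or head_track.frequency.size == 0:
        raise ValueError("cannot summarize empty spectrogram tracks")
    tba = float(tail_track.amplitude.mean())
    hwa = float(head_track.amplitude.mean())
    units = "px"
    if pixel_scale is not None:
        tba /= pixel_scale
        hwa /= pixel_scale
        units = "cm"
    return KinematicsSummary(
        tbf=float(tail_track.frequency.mean()),
        tba=tba,
        hwf=float(head_track.frequency.mean()),
        hwa=hwa,
        units=units,
    )


def default_selection_ranges(expected_area_px2: float,
                             expected_ratio: float = 8.0,
                             slack: float = 0.3):
    """Area/ratio filter ranges centred on a generator's expected geometry."""
    return (
        ((1 - slack) * expected_area_px2, (1 + slack) * expected_area_px2),
        ((1 - slack) * expected_ratio, (1 + slack) * expected_ratio),
    )
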