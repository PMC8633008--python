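"""Contractility kinematics of a beating syncytium from marker trajectories.

A recording is a set of markers tracked frame by frame on beating
cardiomyocytes; coordinates are in pixels and time in seconds. Four
metrics summarize each recording:

* chronotropy — beat frequency [Hz], from counting displacement peaks;
* kinematic inotropy — maximum contraction velocity [pixel/s];
* dynamic inotropy — contraction-force proxy as unit-mass peak
  acceleration [pixel/s^2] (with H = 1/2 m|v|^2 + const and m := 1 the
  force along the path reduces to the acceleration magnitude);
* ergotropy — mean kinetic energy of the motion [pixel^2/s^2].

Displacement peaks are counted on the *signed* displacement of each marker
projected onto its dominant motion axis (first principal component of the
trajectory): for a marker oscillating about its rest position the unsigned
Euclidean displacement peaks twice per beat, while the signed projection
peaks once per beat for both sinusoidal and pulse-like waveforms.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, savgol_filter

from .errors import InsufficientDataError, NonUniformSamplingError

__all__ = [
    "TrajectorySet",
    "KinematicsSummary",
    "compute_displacement",
    "compute_chronotropy",
    "compute_velocity_acceleration",
    "summarize_kinematics",
    "read_trajectories",
    "write_trajectories",
    "track_video",
]

#: minimum peak prominence, as a fraction of the series interquartile range
PEAK_PROMINENCE_IQR_FRACTION = 0.2
#: spectral power fraction above 0.6 x Nyquist that triggers pre-smoothing
JITTER_ENERGY_THRESHOLD = 0.10


@dataclass
class TrajectorySet:
    """Marker trajectories on a shared, uniform time base.

    positions has shape (n_markers, n_frames, 2) holding (x, y) in pixels;
    ``times`` defaults to frame_index / fps.
    """

    positions: np.ndarray
    fps: float
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_markers, n_frames, 2)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.times is not None:
            self.times = np.asarray(self.times, dtype=float)
            if self.times.shape != (self.n_frames,):
                raise ValueError("times must have one entry per frame")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("times must be strictly increasing")

    @property
    def n_markers(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    @property
    def t(self) -> np.ndarray:
        if self.times is not None:
            return self.times
        return np.arange(self.n_frames) / self.fps

    @property
    def duration(self) -> float:
        """Recording length in seconds (n_frames / fps for the uniform base)."""
        return self.n_frames / self.fps

    def reversed(self) -> "TrajectorySet":
        return TrajectorySet(positions=self.positions[:, ::-1, :], fps=self.fps)

    def scaled(self, c: float) -> "TrajectorySet":
        return TrajectorySet(positions=self.positions * c, fps=self.fps)


@dataclass
class KinematicsSummary:
    chronotropy: float  # Hz
    kinematic_inotropy: float  # pixel/s
    dynamic_inotropy: float  # pixel/s^2
    ergotropy: float  # pixel^2/s^2
    per_marker_records: pd.DataFrame = field(repr=False, default=None)
    no_peaks_warning: bool = False

    def to_row(self) -> dict:
        return {
            "chronotropy_hz": self.chronotropy,
            "kinematic_inotropy_px_s": self.kinematic_inotropy,
            "dynamic_inotropy_px_s2": self.dynamic_inotropy,
            "ergotropy_px2_s2": self.ergotropy,
        }


def _uniform_dt(traj: TrajectorySet) -> float:
    if traj.times is None:
        return 1.0 / traj.fps
    dts = np.diff(traj.times)
    dt = dts.mean()
    if np.max(np.abs(dts - dt)) > 1e-6 * dt:
        raise NonUniformSamplingError(
            "time base is non-uniform beyond tolerance; resample first"
        )
    return float(dt)


def compute_displacement(traj: TrajectorySet, rest: str = "first") -> np.ndarray:
    """Per-marker displacement magnitude from the rest position, in pixels.

    ``rest`` selects the displacement origin: "first" (first-frame position,
    the default) or "mean" (time-averaged position, appropriate for motion
    that orbits rather than returns to its start). Returns an
    (n_markers, n_frames) array.
    """
    if traj.n_frames < 3:
        raise InsufficientDataError("need at least 3 frames for displacement")
    if rest == "first":
        origin = traj.positions[:, :1, :]
    elif rest == "mean":
        origin = traj.positions.mean(axis=1, keepdims=True)
    else:
        raise ValueError("rest must be 'first' or 'mean'")
    return np.linalg.norm(traj.positions - origin, axis=2)


def _principal_axis(positions_m: np.ndarray) -> np.ndarray:
    """Unit vector of the dominant motion direction of one marker."""
    centered = positions_m - positions_m.mean(axis=0)
    if not np.any(centered):
        return np.array([1.0, 0.0])
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def _projected_displacement(traj: TrajectorySet) -> np.ndarray:
    """Signed displacement of each marker along its dominant motion axis."""
    out = np.empty((traj.n_markers, traj.n_frames))
    for m in range(traj.n_markers):
        u = _principal_axis(traj.positions[m])
        out[m] = (traj.positions[m] - traj.positions[m, 0]) @ u
    return out


def _count_peaks(series: np.ndarray, fps: float) -> int:
    q75, q25 = np.percentile(series, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 0
    # the spacing floor 0.25 / (fps/2) is sub-frame at any fps, so prominence
    # does the actual beat/jitter separation
    distance = max(1, int(round(0.25 * fps / (fps / 2.0))))
    peaks, _ = find_peaks(
        series,
        prominence=PEAK_PROMINENCE_IQR_FRACTION * iqr,
        distance=distance,
    )
    return len(peaks)


def compute_chronotropy(traj: TrajectorySet) -> float:
    """Beat frequency [Hz]: median across markers of peak count / duration."""
    freq, _ = _chronotropy_detail(traj)
    return freq


def _chronotropy_detail(traj: TrajectorySet) -> tuple[float, np.ndarray]:
    if traj.n_frames < 3:
        raise InsufficientDataError("need at least 3 frames")
    proj = _projected_displacement(traj)
    counts = np.array([_count_peaks(proj[m], traj.fps) for m in range(traj.n_markers)])
    freqs = counts / traj.duration
    freq = float(np.median(freqs))
    if np.all(counts == 0):
        warnings.warn("no displacement peaks detected; chronotropy set to 0 Hz")
    return freq, counts


def _jittery(series: np.ndarray) -> bool:
    """True when > 10% of the (mean-removed) spectral power sits above 0.6 x Nyquist."""
    x = series - series.mean()
    total = float(np.sum(x**2))
    if total == 0:
        return False
    spec = np.abs(np.fft.rfft(x)) ** 2
    n = len(spec)
    hi = spec[int(np.ceil(0.6 * (n - 1))) :].sum()
    return hi / spec[1:].sum() > JITTER_ENERGY_THRESHOLD if spec[1:].sum() > 0 else False


def compute_velocity_acceleration(
    traj: TrajectorySet,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker speed [px/s] and acceleration magnitude [px/s^2] series.

    Central differences in time; a local quadratic smoother (5-frame
    Savitzky-Golay) is applied to the coordinates first, but only for
    markers whose displacement shows appreciable high-frequency (tracking
    jitter) energy.
    """
    if traj.n_frames < 5:
        raise InsufficientDataError("need at least 5 frames to differentiate")
    dt = _uniform_dt(traj)
    pos = traj.positions.copy()
    proj = _projected_displacement(traj)
    for m in range(traj.n_markers):
        if _jittery(proj[m]):
            pos[m] = savgol_filter(pos[m], window_length=5, polyorder=2, axis=0)
    v = np.gradient(pos, dt, axis=1)
    speed = np.linalg.norm(v, axis=2)
    a = np.gradient(v, dt, axis=1)
    accel = np.linalg.norm(a, axis=2)
    return speed, accel


def _series_max(series: np.ndarray) -> float:
    """Maximum of a sampled series, refined by quadratic interpolation.

    The discrete grid rarely hits the true extremum of a smooth signal;
    fitting a parabola through the sample maximum and its neighbors
    removes most of the sampling-phase bias.
    """
    k = int(np.argmax(series))
    if 0 < k < len(series) - 1:
        l, c, r = series[k - 1], series[k], series[k + 1]
        denom = l - 2 * c + r
        if denom < 0:
            delta = 0.5 * (l - r) / denom
            if abs(delta) <= 1:
                return float(c - 0.25 * (l - r) * delta)
    return float(series[k])


def summarize_kinematics(traj: TrajectorySet) -> KinematicsSummary:
    """All four contractility metrics of one recording.

    kinematic_inotropy / dynamic_inotropy: median across markers of each
    marker's maximum speed / acceleration magnitude; ergotropy: mean over
    all markers and frames of (1/2) speed^2.
    """
    chrono, counts = _chronotropy_detail(traj)
    speed, accel = compute_velocity_acceleration(traj)
    per_marker = pd.DataFrame(
        {
            "marker": np.arange(traj.n_markers),
            "n_peaks": counts,
            "beat_freq_hz": counts / traj.duration,
            "max_speed_px_s": [_series_max(speed[m]) for m in range(traj.n_markers)],
            "max_accel_px_s2": [_series_max(accel[m]) for m in range(traj.n_markers)],
            "mean_ke_px2_s2": 0.5 * (speed**2).mean(axis=1),
        }
    )
    return KinematicsSummary(
        chronotropy=chrono,
        kinematic_inotropy=float(np.median(per_marker["max_speed_px_s"])),
        dynamic_inotropy=float(np.median(per_marker["max_accel_px_s2"])),
        ergotropy=float(0.5 * np.mean(speed**2)),
        per_marker_records=per_marker,
        no_peaks_warning=bool(np.all(counts == 0)),
    )


# ---------------------------------------------------------------------------
# I/O: trajectory tables (marker_id, frame, x, y) + sidecar JSON with fps
# ---------------------------------------------------------------------------


def read_trajectories(
    csv_path: str | Path,
    fps: float | None = None,
    sidecar: str | Path | None = None,
) -> TrajectorySet:
    """Load a trajectory table; fps comes from the argument or the sidecar JSON."""
    csv_path = Path(csv_path)
    if fps is None:
        sidecar = Path(sidecar) if sidecar else csv_path.with_suffix(".json")
        meta = json.loads(Path(sidecar).read_text())
        fps = float(meta["fps"])
    df = pd.read_csv(csv_path)
    required = {"marker_id", "frame", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory CSV must have columns {sorted(required)}")
    df = df.sort_values(["marker_id", "frame"])
    markers = []
    for _, g in df.groupby("marker_id", sort=True):
        markers.append(g[["x", "y"]].to_numpy(dtype=float))
    lengths = {m.shape[0] for m in markers}
    if len(lengths) != 1:
        raise ValueError("all markers must share the same time base")
    return TrajectorySet(positions=np.stack(markers), fps=fps)


def write_trajectories(
    traj: TrajectorySet,
    csv_path: str | Path,
    pixel_size: float | None = None,
) -> None:
    """Write the (marker_id, frame, x, y) table and an fps sidecar JSON."""
    csv_path = Path(csv_path)
    m, n, _ = traj.positions.shape
    df = pd.DataFrame(
        {
            "marker_id": np.repeat(np.arange(m), n),
            "frame": np.tile(np.arange(n), m),
            "x": traj.positions[:, :, 0].ravel(),
            "y": traj.positions[:, :, 1].ravel(),
        }
    )
    df.to_csv(csv_path, index=False)
    meta = {"fps": traj.fps}
    if pixel_size is not None:
        meta["pixel_size"] = pixel_size
    csv_path.with_suffix(".json").write_text(json.dumps(meta, indent=2) + "\n")


def track_video(
    path: str | Path,
    seeds: list[tuple[float, float]] | None = None,
    grid: tuple[int, int] = (3, 4),
    template_size: int = 21,
    fps: float | None = None,
) -> TrajectorySet:
    """Minimal normalized-cross-correlation template tracker (convenience only).

    Trajectory tables are the canonical input; this helper converts a simple
    video by matching fixed first-frame templates in every later frame.
    ``seeds`` are (x, y) template centers; when omitted a grid of points over
    the central region of the frame is used.
    """
    import imageio.v3 as iio
    from skimage.feature import match_template

    frames = iio.imread(str(path))
    if frames.ndim == 4:  # RGB
        frames = frames.mean(axis=3)
    if fps is None:
        try:
            meta = iio.immeta(str(path))
            fps = float(meta.get("fps", 30.0))
        except Exception:
            fps = 30.0
    h, w = frames.shape[1:]
    half = template_size // 2
    if seeds is None:
        gy = np.linspace(0.25 * h, 0.75 * h, grid[0])
        gx = np.linspace(0.25 * w, 0.75 * w, grid[1])
        seeds = [(x, y) for y in gy for x in gx]
    first = frames[0].astype(float)
    trajectories = []
    for sx, sy in seeds:
        cx, cy = int(round(sx)), int(round(sy))
        tmpl = first[cy - half : cy + half + 1, cx - half : cx + half + 1]
        track = []
        for frame in frames:
            corr = match_template(frame.astype(float), tmpl, pad_input=True)
            py, px = np.unravel_index(np.argmax(corr), corr.shape)
            track.append((float(px), float(py)))
        trajectories.append(track)
    return TrajectorySet(positions=np.asarray(trajectories), fps=fps)
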