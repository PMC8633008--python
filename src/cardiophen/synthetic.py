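"""Synthetic fixtures with known ground truth for every measurement stage.

Four generators emulate the raw data of an embryoid-body cardiomyocyte
phenotyping experiment:

* :func:`make_striation_image` — periodic Z-band textures (alpha-actinin
  immunofluorescence look-alikes) with a single ``disorganization`` knob
  running from perfect stripes (0) to a full intensity-preserving pixel
  scramble (1);
* :func:`make_beat_trajectories` — marker trajectories of a beating
  syncytium with a set beat frequency and waveform;
* :func:`make_zstack` — confocal core-sample stacks with uniform signal
  over a known polygonal region plus additive background;
* :func:`make_cell_mask` — digitized ellipses with closed-form shape
  metrics.

Every generator is a pure function of its spec (including the seed) and
returns the data together with a ground-truth record that downstream tests
compare against.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage

from ._geometry import polygon_mask
from .errors import InvalidSpecError
from .kinematics import TrajectorySet

__all__ = [
    "StriationSpec",
    "BeatSpec",
    "StackSpec",
    "make_striation_image",
    "make_beat_trajectories",
    "make_zstack",
    "make_cell_mask",
    "save_ground_truth",
]

# intensity range of all generated images
_BG = 0.2
_FG = 1.0


@dataclass(frozen=True)
class StriationSpec:
    """Parameters of a synthetic striated (sarcomere-like) texture.

    ``period`` is the Z-band-to-Z-band distance in pixels, ``band_width``
    the Z-band thickness (FWHM of the Gaussian band profile), and
    ``orientation`` the direction (degrees, from +x towards +y) of the
    striation normal, i.e. the axis along which intensity is periodic.
    ``band_length``/``band_gap`` optionally break each band into segments
    of finite extent along the Z-line direction, which is what the
    "sarcomere width" measurement estimates.
    """

    image_size: tuple[int, int] = (128, 128)
    period: float = 10.0
    band_width: float = 3.0
    orientation: float = 0.0
    disorganization: float = 0.0
    noise_sd: float = 0.0
    pixel_size: float = 0.1  # µm / pixel
    seed: int = 0
    band_length: float | None = None
    band_gap: float | None = None

    def validate(self) -> None:
        if self.period < 2:
            raise InvalidSpecError("striation period must be >= 2 pixels")
        if not 0.0 <= self.disorganization <= 1.0:
            raise InvalidSpecError("disorganization must lie in [0, 1]")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.band_width <= 0 or self.pixel_size <= 0:
            raise InvalidSpecError("band_width and pixel_size must be positive")
        if min(self.image_size) < 16:
            raise InvalidSpecError("image must be at least 16x16 pixels")


@dataclass(frozen=True)
class BeatSpec:
    """Parameters of a synthetic beating-syncytium recording.

    Markers oscillate about random rest positions along random unit
    directions: x(t) = x0 + A * u * s(2*pi*f*t) (+ tracking jitter), where
    s is either a sinusoid or a train of raised-cosine contraction pulses.
    """

    n_markers: int = 12
    beat_frequency: float = 1.0  # Hz
    displacement_amplitude: float = 2.0  # pixels
    fps: float = 30.0
    duration: float = 10.0  # s
    waveform: str = "sinusoid"  # or "pulse-train"
    jitter_sd: float = 0.0  # pixels
    seed: int = 0
    # fraction of a beat period occupied by the contraction pulse
    pulse_duty: float = 0.3

    def validate(self) -> None:
        if self.n_markers < 1:
            raise InvalidSpecError("need at least one marker")
        if self.beat_frequency >= self.fps / 2:
            raise InvalidSpecError(
                "beat_frequency must be below fps/2 (sampling must resolve beats)"
            )
        if self.duration * self.beat_frequency < 3:
            raise InvalidSpecError("recording must span at least 3 beats")
        if self.waveform not in ("sinusoid", "pulse-train"):
            raise InvalidSpecError(f"unknown waveform {self.waveform!r}")
        if self.jitter_sd < 0 or self.displacement_amplitude < 0:
            raise InvalidSpecError("amplitude and jitter_sd must be >= 0")
        if not 0 < self.pulse_duty < 1:
            raise InvalidSpecError("pulse_duty must lie in (0, 1)")


@dataclass(frozen=True)
class StackSpec:
    """Parameters of a synthetic confocal core-sample Z-stack.

    Each slice equals ``background_level`` everywhere, ``signal_level``
    inside ``signal_region`` (a polygon in pixel coordinates), plus
    optional Gaussian noise.
    """

    n_slices: int = 5
    slice_size: tuple[int, int] = (64, 64)
    signal_region: tuple = ((10.0, 10.0), (20.0, 10.0), (20.0, 20.0), (10.0, 20.0))
    signal_level: float = 200.0
    background_level: float = 50.0
    noise_sd: float = 0.0
    z_step: float = 0.5  # µm, carried as metadata
    seed: int = 0

    def validate(self) -> None:
        if self.n_slices < 1:
            raise InvalidSpecError("need at least one slice")
        if not self.signal_level >= self.background_level >= 0:
            raise InvalidSpecError("need signal_level >= background_level >= 0")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if len(self.signal_region) < 3:
            raise InvalidSpecError("signal_region polygon needs >= 3 vertices")


def _orientation_field(shape, theta0, disorganization, rng):
    """Smooth per-pixel striation-normal angle (radians)."""
    theta = np.full(shape, theta0, dtype=float)
    if disorganization > 0:
        noise = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(noise, sigma=8.0, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            smooth /= sd
        theta += disorganization * (np.pi / 3) * smooth
    return theta


def make_striation_image(spec: StriationSpec) -> tuple[np.ndarray, dict]:
    """Render a striated texture; return (image, ground-truth record).

    Disorganization < 1 perturbs the texture with two jitters scaled by the
    parameter — a smooth local rotation of the striation normal and a
    per-stripe phase offset. Disorganization == 1 replaces the organized
    image by a full random permutation of its pixels, which preserves the
    intensity histogram exactly.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    rows, cols = np.mgrid[0:h, 0:w].astype(float)

    d = spec.disorganization
    d_render = 0.0 if d >= 1.0 else d
    theta = _orientation_field((h, w), np.deg2rad(spec.orientation), d_render, rng)
    u = cols * np.cos(theta) + rows * np.sin(theta)

    if d_render > 0:
        stripe = np.floor(u / spec.period).astype(int)
        stripe -= stripe.min()
        offsets = rng.normal(0.0, d_render * spec.period / 2.0, size=stripe.max() + 1)
        u = u + offsets[stripe]

    frac = np.mod(u, spec.period)
    dist = np.minimum(frac, spec.period - frac)  # distance to nearest band center
    sigma_b = spec.band_width / 2.355  # FWHM -> Gaussian sigma
    profile = np.exp(-0.5 * (dist / sigma_b) ** 2)

    if spec.band_length is not None:
        gap = spec.band_gap if spec.band_gap is not None else spec.band_length / 2.0
        v = -cols * np.sin(np.deg2rad(spec.orientation)) + rows * np.cos(
            np.deg2rad(spec.orientation)
        )
        pitch = spec.band_length + gap
        profile = profile * (np.mod(v, pitch) < spec.band_length)

    image = _BG + (_FG - _BG) * profile

    if d >= 1.0:
        image = rng.permutation(image.ravel()).reshape(h, w)

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=image.shape)
        image = np.clip(image, 0.0, 1.2)

    truth = {
        "true_period_um": spec.period * spec.pixel_size,
        "true_period_px": spec.period,
        "true_band_width_um": spec.band_width * spec.pixel_size,
        "true_band_length_um": (
            None if spec.band_length is None else spec.band_length * spec.pixel_size
        ),
        "true_orientation_deg": spec.orientation,
        "pixel_size": spec.pixel_size,
        "disorganization": d,
    }
    return image, truth


def _waveform(spec: BeatSpec, t: np.ndarray) -> np.ndarray:
    f = spec.beat_frequency
    if spec.waveform == "sinusoid":
        return np.sin(2 * np.pi * f * t)
    # raised-cosine (sin^2) contraction pulse occupying `pulse_duty` of a beat
    w = spec.pulse_duty / f
    t_loc = np.mod(t, 1.0 / f)
    s = np.zeros_like(t)
    inside = t_loc < w
    s[inside] = np.sin(np.pi * t_loc[inside] / w) ** 2
    return s


def make_beat_trajectories(spec: BeatSpec) -> tuple[TrajectorySet, dict]:
    """Simulate marker trajectories; return (TrajectorySet, ground truth).

    Ground-truth kinematics come from the closed forms of the waveform:
    sinusoid — peak speed 2*pi*f*A, peak acceleration (2*pi*f)^2*A, mean
    kinetic energy (2*pi*f*A)^2 / 4; raised-cosine pulse of width w — peak
    speed pi*A/w, peak acceleration 2*pi^2*A/w^2, mean kinetic energy
    A^2*pi^2*f/(4*w).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_frames = int(round(spec.duration * spec.fps))
    t = np.arange(n_frames) / spec.fps

    x0 = rng.uniform(50.0, 450.0, size=(spec.n_markers, 2))
    angles = rng.uniform(0.0, 2 * np.pi, size=spec.n_markers)
    u = np.stack([np.cos(angles), np.sin(angles)], axis=1)

    s = _waveform(spec, t)
    positions = (
        x0[:, None, :]
        + spec.displacement_amplitude * u[:, None, :] * s[None, :, None]
    )
    if spec.jitter_sd > 0:
        positions = positions + rng.normal(
            0.0, spec.jitter_sd, size=positions.shape
        )

    A, f = spec.displacement_amplitude, spec.beat_frequency
    if spec.waveform == "sinusoid":
        peak_speed = 2 * np.pi * f * A
        peak_accel = (2 * np.pi * f) ** 2 * A
        mean_ke = (2 * np.pi * f * A) ** 2 / 4.0
    else:
        w = spec.pulse_duty / f
        peak_speed = np.pi * A / w
        peak_accel = 2 * np.pi**2 * A / w**2
        # <1/2 s'^2>: s' = (pi/w) sin(2 pi t/w) on a fraction f*w of the time
        mean_ke = 0.5 * (A * np.pi / w) ** 2 * (f * w) * 0.5

    truth = {
        "true_frequency_hz": f,
        "true_peak_speed": peak_speed,
        "true_peak_acceleration": peak_accel,
        "true_mean_kinetic_energy": mean_ke,
        "true_n_beats": int(round(spec.duration * f)),
        "waveform": spec.waveform,
    }
    return TrajectorySet(positions=positions, fps=spec.fps), truth


def make_zstack(spec: StackSpec) -> tuple[np.ndarray, dict]:
    """Simulate a core-sample Z-stack; return (stack [n, h, w], ground truth).

    The noiseless ground-truth corrected total fluorescence is
    n_slices * (signal - background) * area(signal_region), with the area
    counted as the number of pixel centers inside the polygon.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    mask = polygon_mask(spec.slice_size, spec.signal_region)
    area = int(mask.sum())
    if area == 0:
        raise InvalidSpecError("signal_region contains no pixel centers")

    base = np.full(spec.slice_size, spec.background_level, dtype=float)
    base[mask] = spec.signal_level
    stack = np.repeat(base[None, :, :], spec.n_slices, axis=0)
    if spec.noise_sd > 0:
        stack = stack + rng.normal(0.0, spec.noise_sd, size=stack.shape)
        stack = np.clip(stack, 0.0, None)

    truth = {
        "true_ctf": spec.n_slices * (spec.signal_level - spec.background_level) * area,
        "signal_area_px": area,
        "n_slices": spec.n_slices,
        "z_step_um": spec.z_step,
    }
    return stack, truth


def _ramanujan_perimeter(a: float, b: float) -> float:
    h = ((a - b) / (a + b)) ** 2
    return np.pi * (a + b) * (1 + 3 * h / (10 + np.sqrt(4 - 3 * h)))


def make_cell_mask(
    semi_major: float,
    semi_minor: float,
    orientation: float = 0.0,
    pixel_size: float = 0.1,
) -> tuple[np.ndarray, dict]:
    """Digitized filled ellipse with closed-form shape ground truth.

    ``semi_major``/``semi_minor`` are the ellipse semi-axes a >= b in
    pixels; ``orientation`` rotates the major axis (degrees). The mask grid
    is odd-sized and centered so that a circle is exactly invariant under
    90-degree rotation.
    """
    if semi_minor > semi_major:
        semi_major, semi_minor = semi_minor, semi_major
    if semi_minor < 4:
        raise InvalidSpecError("ellipse semi-axes must be >= 4 pixels")
    a, b = float(semi_major), float(semi_minor)
    half = int(np.ceil(a)) + 4
    size = 2 * half + 1
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    th = np.deg2rad(orientation)
    xr = xx * np.cos(th) + yy * np.sin(th)
    yr = -xx * np.sin(th) + yy * np.cos(th)
    mask = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0

    ecc = np.sqrt(1.0 - (b / a) ** 2)
    perim = _ramanujan_perimeter(a, b)
    area = np.pi * a * b
    truth = {
        "true_area_um2": area * pixel_size**2,
        "true_eccentricity": ecc,
        "true_elongation": a / b,
        "true_circularity": 4 * np.pi * area / perim**2,
        "true_perimeter_um": perim * pixel_size,
        "pixel_size": pixel_size,
    }
    assert size == mask.shape[0] == mask.shape[1]
    return mask, truth


def save_ground_truth(truth: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, default=float) + "\n")


def save_image(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


def save_stack(stack: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def spec_to_dict(spec) -> dict:
    return dataclasses.asdict(spec)
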