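"""Corrected Total Fluorescence (CTF) stereology of EB core Z-stacks.

The cardiomyocyte compartment volume of an embryoid-body core sample is
proxied by summing the stained-channel intensities of all optical sections
(a SUM projection), integrating them over the core ROI (integrated
density, IntDen = sum of pixel intensities = mean x area), and subtracting
the slice-count-scaled background:

    CTF = IntDen(SUM projection, signal ROI) - n * mean(background IntDen)

where n is the number of slices. The background term is measured per
slice in cardiomyocyte-free ROIs, normalized per unit area, and rescaled
to the signal ROI's area before the n-fold subtraction, so the formula
stays consistent when signal and background ROIs differ in size. A
projection-based background variant is available via
``background_on="projection"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from ._geometry import polygon_mask
from .errors import InvalidStackError, MissingBackgroundError, RoiOutOfBoundsError

__all__ = [
    "CoreStack",
    "CtfResult",
    "sum_projection",
    "integrated_density",
    "compute_ctf",
    "read_stack",
    "read_rois",
]


@dataclass
class CoreStack:
    """An ordered confocal Z-stack with signal and background ROI polygons."""

    slices: np.ndarray  # (n, h, w)
    signal_roi: tuple  # polygon vertices (x, y) in pixel coords
    background_rois: list = field(default_factory=list)
    z_step: float = 0.5  # µm, metadata only
    stack_id: str = ""
    label: str = "CTR"

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=float)
        if self.slices.ndim == 2:
            self.slices = self.slices[None, :, :]
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise InvalidStackError("stack must be a (n, h, w) array with n >= 1")

    @property
    def n(self) -> int:
        return self.slices.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices.shape[1:]


@dataclass
class CtfResult:
    ctf: float  # intensity * pixel
    intden_sum: float
    mean_background_intden: float
    n: int
    negative_flag: bool = False
    stack_id: str = ""
    label: str = "CTR"

    def to_row(self) -> dict:
        return {
            "stack_id": self.stack_id,
            "label": self.label,
            "ctf": self.ctf,
            "intden_sum": self.intden_sum,
            "mean_background_intden": self.mean_background_intden,
            "n_slices": self.n,
            "negative_flag": self.negative_flag,
        }


def sum_projection(stack: CoreStack | np.ndarray) -> np.ndarray:
    """Pixel-wise sum over slices (the ImageJ SUM projection)."""
    slices = stack.slices if isinstance(stack, CoreStack) else np.asarray(stack, float)
    if slices.ndim == 2:
        return slices.copy()
    if slices.ndim != 3:
        raise InvalidStackError("expected a (n, h, w) stack")
    return slices.sum(axis=0)


def _roi_mask(image_shape: tuple[int, int], roi) -> np.ndarray:
    verts = np.asarray(roi, dtype=float)
    h, w = image_shape
    if verts[:, 0].min() < 0 or verts[:, 1].min() < 0 or verts[:, 0].max() > w or verts[
        :, 1
    ].max() > h:
        raise RoiOutOfBoundsError("ROI polygon extends outside the image")
    mask = polygon_mask(image_shape, verts)
    if not mask.any():
        raise RoiOutOfBoundsError("ROI contains no pixel centers")
    return mask


def integrated_density(image: np.ndarray, roi) -> float:
    """Sum of intensities over pixels whose centers fall inside the polygon."""
    image = np.asarray(image, dtype=float)
    mask = _roi_mask(image.shape, roi)
    return float(image[mask].sum())


def compute_ctf(stack: CoreStack, background_on: str = "slices") -> CtfResult:
    """Corrected total fluorescence of one core stack.

    intden_sum integrates the SUM projection over the signal ROI;
    mean_background_intden is the background intensity per unit area
    (per-slice mean over slices and background ROIs by default, or measured
    on the projection and divided by n with ``background_on="projection"``),
    rescaled to the signal ROI's pixel area. A negative CTF (signal below
    background) is flagged, not raised.
    """
    if len(stack.background_rois) == 0:
        raise MissingBackgroundError("CTF needs at least one background ROI")
    if background_on not in ("slices", "projection"):
        raise ValueError("background_on must be 'slices' or 'projection'")

    projection = sum_projection(stack)
    signal_mask = _roi_mask(stack.shape, stack.signal_roi)
    signal_area = int(signal_mask.sum())
    intden_sum = float(projection[signal_mask].sum())

    per_area = []
    for roi in stack.background_rois:
        mask = _roi_mask(stack.shape, roi)
        area = int(mask.sum())
        if background_on == "slices":
            # mean over slices of the per-slice IntDen, per unit area
            per_area.append(float(stack.slices[:, mask].sum()) / (stack.n * area))
        else:
            per_area.append(float(projection[mask].sum()) / (stack.n * area))
    mean_background_intden = float(np.mean(per_area)) * signal_area

    ctf = intden_sum - stack.n * mean_background_intden
    return CtfResult(
        ctf=float(ctf),
        intden_sum=intden_sum,
        mean_background_intden=mean_background_intden,
        n=stack.n,
        negative_flag=bool(ctf < 0),
        stack_id=stack.stack_id,
        label=stack.label,
    )


def read_stack(tiff_path: str | Path, rois_json: str | Path, **kwargs) -> CoreStack:
    """Load a multi-page TIFF and its ROI JSON.

    The JSON holds ``signal`` (one polygon) and ``background`` (a list of
    polygons); polygons are lists of [x, y] vertices, 0-based pixel
    coordinates, origin top-left.
    """
    slices = tifffile.imread(str(tiff_path))
    rois = json.loads(Path(rois_json).read_text())
    return CoreStack(
        slices=slices,
        signal_roi=rois["signal"],
        background_rois=rois.get("background", []),
        stack_id=Path(tiff_path).stem,
        **kwargs,
    )
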