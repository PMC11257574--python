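"""Quantification of division-site fluorescence.

Implements the measurement conventions used for calibrated multichannel
z-stacks of dividing cells: sum/max z-projections; total ROI intensity with
local cytoplasmic background subtracted from a surrounding ROI pair
(ROI2 ~ twice the area of ROI1, including it); width-averaged axial
colocalization profiles across the division plane; 3-pixel-wide line scans
in the middle focal plane with several peak-based alignment strategies; and
a rim-spread index that summarises whether signal sits on the annular rim
of the division plane or has spread over its centre.

Pixel coordinates are 0-based with origin top-left, x rightwards and y
downwards; ROI bounds are half-open; physical positions are micrometres via
the stack's pixel size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "RectROI",
    "LineProfile",
    "read_stack",
    "write_stack",
    "project",
    "roi_background_subtracted_intensity",
    "axial_colocalization_profile",
    "line_scan",
    "align_profiles",
    "rim_spread_index",
]


@dataclass
class ImageStack:
    """channels x z x y x x intensity array with pixel/z calibration (um)."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    channels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"stack must be 4-D (c,z,y,x), got {self.data.ndim}-D")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size_um and z_step_um must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel labels must match channel axis length")

    def channel_index(self, channel: int | str) -> int:
        if isinstance(channel, str):
            return self.channels.index(channel)
        return int(channel)


@dataclass(frozen=True)
class RectROI:
    """Half-open pixel rectangle [x0, x0+width) x [y0, y0+height)."""

    x0: int
    y0: int
    width: int
    height: int

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("ROI must have positive width and height")
        if self.x0 < 0 or self.y0 < 0:
            raise ValueError("ROI origin must be non-negative")

    @property
    def area(self) -> int:
        return self.width * self.height

    def contains(self, other: "RectROI") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x0 + self.width >= other.x0 + other.width
            and self.y0 + self.height >= other.y0 + other.height
        )

    def slice(self) -> tuple[slice, slice]:
        return (slice(self.y0, self.y0 + self.height), slice(self.x0, self.x0 + self.width))

    def check_within(self, image: np.ndarray) -> None:
        h, w = image.shape[-2:]
        if self.y0 + self.height > h or self.x0 + self.width > w:
            raise ValueError(f"ROI {self} exceeds image bounds {w}x{h}")


@dataclass
class LineProfile:
    """Width-averaged intensity profile; positions in um from the origin."""

    positions: np.ndarray
    values: np.ndarray
    width_pixels: int = 1
    alignment: dict = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must have equal length")
        if len(self.positions) > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")


# --------------------------------------------------------------------------
# stack I/O (shaped TIFF with embedded calibration metadata)

def write_stack(stack: ImageStack, path: str | Path) -> None:
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        metadata={
            "axes": "CZYX",
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
            "channels": json.dumps(stack.channels),
        },
    )


def read_stack(path: str | Path) -> ImageStack:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    if data.ndim == 3:  # single channel stored without channel axis
        data = data[None]
    if "pixel_size_um" not in meta or "z_step_um" not in meta:
        raise ValueError(f"{path}: missing pixel/z calibration metadata")
    channels = json.loads(meta.get("channels", "[]")) or [
        f"ch{i}" for i in range(data.shape[0])
    ]
    return ImageStack(
        data=np.asarray(data, float),
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        channels=list(channels),
    )


# --------------------------------------------------------------------------
# projections and ROI intensities

def project(
    stack: ImageStack,
    channel: int | str,
    mode: str = "sum",
    z_range: tuple[int, int] | None = None,
) -> np.ndarray:
    """Pixelwise sum or max projection of one channel over a z range."""
    ci = stack.channel_index(channel)
    z0, z1 = (0, stack.data.shape[1]) if z_range is None else z_range
    if z1 <= z0:
        raise ValueError(f"empty z range ({z0}, {z1})")
    block = stack.data[ci, z0:z1]
    if mode == "sum":
        return block.sum(axis=0)
    if mode == "max":
        return block.max(axis=0)
    raise ValueError(f"unknown projection mode {mode!r}")


def roi_background_subtracted_intensity(
    image: np.ndarray, roi1: RectROI, roi2: RectROI
) -> float:
    """Total ROI1 intensity minus local cytoplasmic background.

    ROI2 must contain ROI1 (and be larger); the per-pixel background is
    estimated from the ROI2\\ROI1 annulus and scaled to ROI1's area:

        corrected = I1 - A1 * (I2 - I1) / (A2 - A1)
    """
    roi1.check_within(image)
    roi2.check_within(image)
    if not roi2.contains(roi1):
        raise ValueError("ROI1 must lie within ROI2")
    if roi2.area <= roi1.area:
        raise ValueError("ROI2 must be strictly larger than ROI1")
    i1 = float(image[roi1.slice()].sum())
    i2 = float(image[roi2.slice()].sum())
    return i1 - roi1.area * (i2 - i1) / (roi2.area - roi1.area)


def axial_colocalization_profile(
    image: np.ndarray,
    roi: RectROI,
    pixel_size_um: float,
    long_axis: str = "x",
    label: str = "",
) -> LineProfile:
    """Mean-over-width profile along the ROI's long axis, positions in um.

    For the standard usage the ROI (about 1.5 x 3.5 um) lies across the
    division plane with its long axis along the cell long axis; each
    position is the mean over all pixels perpendicular to that axis.
    """
    roi.check_within(image)
    block = image[roi.slice()]
    if long_axis == "x":
        values = block.mean(axis=0)
        start = roi.x0
    elif long_axis == "y":
        values = block.mean(axis=1)
        start = roi.y0
    else:
        raise ValueError(f"long_axis must be 'x' or 'y', got {long_axis!r}")
    positions = (start + np.arange(values.size) + 0.5) * pixel_size_um
    return LineProfile(
        positions=positions,
        values=values,
        width_pixels=roi.height if long_axis == "x" else roi.width,
        alignment={"strategy": "none"},
        label=label,
    )


def line_scan(
    image: np.ndarray,
    start: tuple[float, float],
    end: tuple[float, float],
    width_pixels: int = 3,
    pixel_size_um: float = 1.0,
    label: str = "",
) -> LineProfile:
    """Width-averaged intensity along a line ((x, y) endpoints, pixels).

    The profile is the mean over a ``width_pixels`` band perpendicular to
    the line at unit-pixel steps.  Axis-aligned integer lines reduce to
    exact pixel means; oblique lines sample by bilinear interpolation.
    """
    if width_pixels < 1:
        raise ValueError("width_pixels must be >= 1")
    x0, y0 = start
    x1, y1 = end
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("zero-length line")
    n = int(round(length)) + 1
    t = np.linspace(0.0, length, n)
    ux, uy = (x1 - x0) / length, (y1 - y0) / length
    px, py = -uy, ux  # unit perpendicular
    offsets = np.arange(width_pixels, dtype=float) - (width_pixels - 1) / 2.0

    axis_aligned = (
        float(x0).is_integer() and float(y0).is_integer()
        and float(x1).is_integer() and float(y1).is_integer()
        and (x0 == x1 or y0 == y1)
    )
    if axis_aligned:
        xs = np.rint(x0 + t * ux).astype(int)
        ys = np.rint(y0 + t * uy).astype(int)
        rows = []
        for off in offsets:
            oy = ys + int(round(off * py))
            ox = xs + int(round(off * px))
            if oy.min() < 0 or oy.max() >= image.shape[0] or ox.min() < 0 or ox.max() >= image.shape[1]:
                raise ValueError("line band exceeds image bounds")
            rows.append(image[oy, ox])
        values = np.mean(rows, axis=0)
    else:
        samples = np.empty((width_pixels, n))
        for k, off in enumerate(offsets):
            sx = x0 + t * ux + off * px
            sy = y0 + t * uy + off * py
            if sx.min() < -0.5 or sx.max() > image.shape[1] - 0.5 or sy.min() < -0.5 or sy.max() > image.shape[0] - 0.5:
                raise ValueError("line band exceeds image bounds")
            samples[k] = ndimage.map_coordinates(
                image, np.vstack([sy, sx]), order=1, mode="nearest"
            )
        values = samples.mean(axis=0)
    positions = t * pixel_size_um
    return LineProfile(
        positions=positions,
        values=values,
        width_pixels=width_pixels,
        alignment={"strategy": "none"},
        label=label,
    )


# --------------------------------------------------------------------------
# profile alignment

def _smooth3(values: np.ndarray) -> np.ndarray:
    """3-point moving mean with shrinking windows at the ends."""
    v = np.asarray(values, float)
    out = v.copy()
    if v.size >= 2:
        out[0] = v[:2].mean()
        out[-1] = v[-2:].mean()
    if v.size >= 3:
        out[1:-1] = (v[:-2] + v[1:-1] + v[2:]) / 3.0
    return out


def _peak_position(profile: LineProfile) -> float:
    """Global-maximum position after 3-point smoothing."""
    smoothed = _smooth3(profile.values)
    return float(profile.positions[int(np.argmax(smoothed))])


def _two_peak_midpoint(profile: LineProfile, min_separation: int = 3) -> float:
    """Midpoint of the two highest local maxima >= min_separation apart."""
    smoothed = _smooth3(profile.values)
    interior = (smoothed[1:-1] >= smoothed[:-2]) & (smoothed[1:-1] >= smoothed[2:])
    candidates = np.nonzero(interior)[0] + 1
    candidates = candidates[np.argsort(smoothed[candidates])[::-1]]
    chosen: list[int] = []
    for idx in candidates:
        if all(abs(idx - c) >= min_separation for c in chosen):
            chosen.append(int(idx))
        if len(chosen) == 2:
            break
    if len(chosen) < 2:
        raise ValueError(
            f"profile {profile.label or '<unnamed>'}: fewer than two separated "
            "local maxima; cannot align by two-peak midpoint"
        )
    return float(np.mean(profile.positions[sorted(chosen)]))


def align_profiles(
    profiles: Sequence[LineProfile],
    strategy: str,
    reference: LineProfile | None = None,
    centers: Sequence[float] | None = None,
) -> list[LineProfile]:
    """Shift profile positions so the strategy's origin sits at 0.

    Strategies:
      - ``reference_peak``: all profiles shift by the peak position of the
        common ``reference`` profile (e.g. a contractile-ring marker).
      - ``brightest_pixel``: each profile centred on its own peak.
      - ``two_peak_midpoint``: each profile centred on the midpoint of its
        two highest local maxima (double-peaked septum signals).
      - ``external_center``: per-profile origins supplied in ``centers``
        (e.g. septum midpoints read off DIC images).

    Values are untouched; only positions move.
    """
    if strategy == "reference_peak":
        if reference is None:
            raise ValueError("reference_peak alignment requires a reference profile")
        origins = [_peak_position(reference)] * len(profiles)
    elif strategy == "brightest_pixel":
        origins = [_peak_position(p) for p in profiles]
    elif strategy == "two_peak_midpoint":
        origins = [_two_peak_midpoint(p) for p in profiles]
    elif strategy == "external_center":
        if centers is None or len(centers) != len(profiles):
            raise ValueError("external_center alignment needs one center per profile")
        origins = [float(c) for c in centers]
    else:
        raise ValueError(f"unknown alignment strategy {strategy!r}")

    aligned = []
    for p, origin in zip(profiles, origins):
        aligned.append(
            replace(
                p,
                positions=p.positions - origin,
                values=p.values.copy(),
                alignment={"strategy": strategy, "origin_um": origin},
            )
        )
    return aligned


def rim_spread_index(profile: LineProfile) -> float:
    """Centre-vs-rim balance of a profile spanning the full cell diameter.

    Splits the profile into thirds and returns
    ``center / (center + rim)`` of the mean intensities: ~0 for signal
    confined to the rim (a division-plane ring seen end-on), ~1 for signal
    concentrated at the centre (signal spread over the division plane).
    """
    v = profile.values
    if v.size < 3:
        raise ValueError("profile too short for a rim-spread index")
    k = v.size // 3
    rim = float(np.mean(np.concatenate([v[:k], v[-k:]])))
    center = float(np.mean(v[k : v.size - k]))
    total = center + rim
    if total <= 0:
        raise ValueError("rim-spread index undefined on an all-zero profile")
    return center / total
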