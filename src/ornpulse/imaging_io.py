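"""Image-stack and trace-table I/O plus deterministic preprocessing.

The preprocessing chain implemented here is: per-frame mean filtering
(disk neighborhood, radius in pixels), rolling-ball background estimation
(grayscale opening with a ball structuring element) and subtraction, and
ROI mean-intensity extraction. Filters are applied in that order when
both are requested.

Conventions
-----------
* Pixel coordinates are (row, col), 0-based.
* Stacks are ``T x H x W`` float arrays; frame_interval is in seconds.
* Trace tables are tab- or comma-separated text with a leading ``time_s``
  column and one column per trace; the sample rate is inferred from the
  (required, uniform) time spacing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "ImageStack",
    "ROI",
    "FluorescenceTrace",
    "mean_filter",
    "rolling_ball_background",
    "subtract_background",
    "extract_roi_trace",
    "load_trace_table",
    "write_trace_table",
    "read_stack",
    "write_stack",
    "read_roi_mask",
]

_TIME_TOL = 1e-6  # s; max deviation from uniform spacing in trace tables


@dataclass
class ImageStack:
    """A fluorescence movie: ``frames[t, row, col]`` in camera units."""

    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a T x H x W array with T >= 1")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frames contain non-finite intensities")
        if not (self.frame_interval > 0):
            raise ValueError("frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.frame_interval


@dataclass
class ROI:
    """A region of interest given as a boolean mask over the frame."""

    label: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")
        if not self.mask.any():
            raise ValueError(f"ROI {self.label!r} is empty")

    @classmethod
    def from_pixels(cls, label: str, pixels, shape: tuple[int, int]) -> "ROI":
        mask = np.zeros(shape, dtype=bool)
        for r, c in pixels:
            if not (0 <= r < shape[0] and 0 <= c < shape[1]):
                raise ValueError(f"ROI {label!r}: pixel ({r}, {c}) outside frame bounds {shape}")
            mask[r, c] = True
        return cls(label, mask)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


@dataclass
class FluorescenceTrace:
    """Raw ROI mean intensity versus time at a known sample rate."""

    values: np.ndarray
    sample_rate: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("trace values must be 1-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"trace {self.label!r} contains non-finite values")
        if not (self.sample_rate > 0):
            raise ValueError("sample_rate must be > 0")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk of Euclidean radius ``radius`` (center included)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def square_footprint(radius: int) -> np.ndarray:
    if radius < 0:
        raise ValueError("radius must be >= 0")
    n = 2 * int(radius) + 1
    return np.ones((n, n), dtype=bool)


def mean_filter(stack: ImageStack, radius: int, shape: str = "disk") -> ImageStack:
    """Per-frame arithmetic mean over a disk (or square) neighborhood.

    Edge pixels are averaged over their in-bounds neighbors only
    (neighborhood truncation). ``radius`` 0 is the identity.
    """
    if radius != int(radius) or radius < 0:
        raise ValueError("radius must be a non-negative integer")
    radius = int(radius)
    if radius == 0:
        return ImageStack(stack.frames.copy(), stack.frame_interval)
    if shape == "disk":
        fp = disk_footprint(radius)
    elif shape == "square":
        fp = square_footprint(radius)
    else:
        raise ValueError(f"unknown neighborhood shape {shape!r}")
    weights = fp.astype(float)[None, :, :]  # do not mix frames
    num = ndimage.correlate(stack.frames, weights, mode="constant", cval=0.0)
    den = ndimage.correlate(np.ones_like(stack.frames), weights, mode="constant", cval=0.0)
    return ImageStack(num / den, stack.frame_interval)


def ball_structure(radius: int, height: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Footprint and heights of a spherical-cap structuring element.

    The ball has pixel radius ``radius``; its height in intensity units
    defaults to ``radius`` and can be rescaled via ``height``.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    radius = int(radius)
    fp = disk_footprint(radius)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    with np.errstate(invalid="ignore"):
        h = np.sqrt(np.maximum(radius**2 - yy**2 - xx**2, 0.0))
    if height is not None:
        if height <= 0:
            raise ValueError("height must be > 0")
        h = h * (float(height) / radius)
    h[~fp] = 0.0
    return fp, h


def paraboloid_structure(radius: int, height: float | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Paraboloid-cap alternative to the ball element."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    radius = int(radius)
    fp = disk_footprint(radius)
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    hmax = float(height) if height is not None else float(radius)
    h = hmax * (1.0 - (yy**2 + xx**2) / radius**2)
    h = np.maximum(h, 0.0)
    h[~fp] = 0.0
    return fp, h


def rolling_ball_background(
    stack: ImageStack,
    radius: int,
    height: float | None = None,
    element: str = "ball",
) -> ImageStack:
    """Estimate the smooth background of each frame by the rolling-ball method.

    Implemented as grayscale opening (erosion then dilation) with a
    non-flat ball structuring element, the standard interpretation of
    the method: the background at each pixel is the surface traced by a
    ball of the given radius rolled under the intensity landscape.
    Out-of-bounds neighbors are ignored (neighborhood truncation), so a
    constant frame is its own background everywhere including edges.

    The returned stack is the background; subtract it from the input to
    obtain the corrected stack (see :func:`subtract_background`).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    _, H, W = stack.shape
    if radius >= H and radius >= W:
        raise ValueError(f"rolling-ball radius {radius} exceeds both image dimensions ({H}x{W})")
    if element == "ball":
        fp, h = ball_structure(radius, height)
    elif element == "paraboloid":
        fp, h = paraboloid_structure(radius, height)
    else:
        raise ValueError(f"unknown structuring element {element!r}")
    fp3 = fp[None, :, :]
    h3 = h[None, :, :]
    eroded = ndimage.grey_erosion(
        stack.frames, footprint=fp3, structure=h3, mode="constant", cval=math.inf
    )
    background = ndimage.grey_dilation(
        eroded, footprint=fp3, structure=h3, mode="constant", cval=-math.inf
    )
    return ImageStack(background, stack.frame_interval)


def subtract_background(stack: ImageStack, background: ImageStack) -> ImageStack:
    if stack.shape != background.shape:
        raise ValueError("stack and background shapes differ")
    return ImageStack(stack.frames - background.frames, stack.frame_interval)


def extract_roi_trace(
    stack: ImageStack,
    roi: ROI,
    mean_radius: int = 0,
    ball_radius: int = 0,
) -> FluorescenceTrace:
    """Mean intensity over the ROI pixels per frame.

    When requested, the frames are mean-filtered first and the
    rolling-ball background subtracted second, matching the stated
    preprocessing order.
    """
    _, H, W = stack.shape
    if roi.mask.shape != (H, W):
        raise ValueError(
            f"ROI mask shape {roi.mask.shape} does not match frame shape {(H, W)}"
        )
    work = stack
    if mean_radius:
        work = mean_filter(work, mean_radius)
    if ball_radius:
        bg = rolling_ball_background(work, ball_radius)
        work = subtract_background(work, bg)
    values = work.frames[:, roi.mask].mean(axis=1)
    return FluorescenceTrace(values, stack.sample_rate, label=roi.label)


# ---------------------------------------------------------------------------
# tabular text I/O


def _infer_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def load_trace_table(path) -> list[FluorescenceTrace]:
    """Read a trace table (time_s column + one column per trace).

    The sample rate is inferred from the time column, which must be
    uniformly spaced to within 1e-6 s. Missing values are rejected with
    a row/column report.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_infer_sep(path))
    if df.shape[1] < 2:
        raise ValueError("trace table needs a time column and at least one trace column")
    if df.isna().any().any():
        bad = [
            f"row {int(i)}, column {c!r}"
            for c in df.columns
            for i in df.index[df[c].isna()]
        ]
        raise ValueError("missing values in trace table: " + "; ".join(bad))
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace table needs at least two time points to infer sample rate")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > _TIME_TOL):
        raise ValueError(
            f"non-uniform time spacing (max deviation {np.abs(dt - dt[0]).max():.3g} s "
            f"exceeds tolerance {_TIME_TOL} s)"
        )
    if dt[0] <= 0:
        raise ValueError("time column must be strictly increasing")
    rate = 1.0 / dt[0]
    return [
        FluorescenceTrace(df[c].to_numpy(dtype=float), rate, label=str(c))
        for c in df.columns[1:]
    ]


def write_trace_table(traces: list[FluorescenceTrace], path) -> None:
    """Write traces as tabular text; round-trips with :func:`load_trace_table`."""
    if not traces:
        raise ValueError("no traces to write")
    rate = traces[0].sample_rate
    n = traces[0].n_samples
    for tr in traces[1:]:
        if tr.sample_rate != rate or tr.n_samples != n:
            raise ValueError("all traces must share sample rate and length")
    path = Path(path)
    data = {"time_s": np.arange(n) / rate}
    for i, tr in enumerate(traces):
        data[tr.label or f"trace_{i}"] = tr.values
    pd.DataFrame(data).to_csv(path, sep=_infer_sep(path), index=False, float_format="%.9g")


def read_stack(path, frame_interval: float = 1.0) -> ImageStack:
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames.astype(float), frame_interval)


def write_stack(stack: ImageStack, path) -> None:
    tifffile.imwrite(str(path), stack.frames.astype(np.float32))


def read_roi_mask(path, label: str | None = None) -> ROI:
    """Read an ROI mask image (nonzero pixels are members)."""
    mask = tifffile.imread(str(path))
    if mask.ndim != 2:
        raise ValueError("ROI mask image must be 2-D")
    return ROI(label or Path(path).stem, mask != 0)
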