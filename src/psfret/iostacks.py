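"""Image-stack I/O, Dual-View mosaic handling, ROIs and background subtraction.

All pixel data are held as floating-point *photoelectrons* from the moment a
file is read (raw camera ADU times the manufacturer gain factor).  Downstream
curve fitting weights residuals by the observed signal, which is only a
sensible variance estimate in electron units, so the conversion happens here
and nowhere else.

Coordinate convention is ``(t, y, x)``, 0-based, y increasing downwards.  ROI
masks share the frame coordinates of the stacks they are applied to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile

__all__ = [
    "CHANNELS",
    "ImageStack",
    "DualViewGeometry",
    "RoiMask",
    "BackgroundSeries",
    "read_stack",
    "write_stack",
    "split_dualview",
    "compose_dualview",
    "register_halves",
    "subtract_background",
    "extract_trace",
]

#: Recognised channel roles: donor emission under donor excitation (the
#: photoswitching readout), acceptor emission under donor excitation (the
#: "FRET" channel) and acceptor emission under acceptor excitation.
CHANNELS = (
    "donor_em_donor_exc",
    "acceptor_em_donor_exc",
    "acceptor_em_acceptor_exc",
)


@dataclass
class ImageStack:
    """A ``(T, Y, X)`` stack of photoelectron counts with frame timestamps.

    Parameters
    ----------
    data
        Photoelectron counts, shape ``(T, Y, X)``, floating point.
    times
        Seconds from the start of the photoswitching cycle, length ``T``,
        strictly increasing.
    channel
        One of :data:`CHANNELS`.
    meta
        Free-form acquisition annotations (gain, construct label, ...).
    """

    data: np.ndarray
    times: np.ndarray
    channel: str = "donor_em_donor_exc"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"stack data must be (T, Y, X), got shape {self.data.shape}")
        if self.data.shape[0] < 4:
            raise ValueError(
                "a photoswitching stack needs at least 4 frames "
                "(more time points than the 3 fit parameters)"
            )
        if self.times.shape != (self.data.shape[0],):
            raise ValueError("times must have one entry per frame")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("frame times must be strictly increasing")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass(frozen=True)
class DualViewGeometry:
    """How a Dual-View mosaic maps onto its two spectral halves.

    ``shift`` is the integer ``(dy, dx)`` translation that takes the red
    (acceptor) half onto the green (donor) half: after alignment,
    ``red_aligned[y, x] = red_raw[y + dy, x + dx]``.
    """

    split_axis: str = "vertical"  # "vertical": left/right halves; "horizontal": top/bottom
    green_half: str = "first"
    shift: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.split_axis not in ("vertical", "horizontal"):
            raise ValueError("split_axis must be 'vertical' or 'horizontal'")
        if self.green_half not in ("first", "second"):
            raise ValueError("green_half must be 'first' or 'second'")
        dy, dx = self.shift
        if dy != int(dy) or dx != int(dx):
            raise ValueError("shift must be integer (dy, dx)")


@dataclass
class RoiMask:
    """A boolean region-of-interest image sharing frame coordinates."""

    mask: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be a 2-D image")
        if not self.mask.any():
            raise ValueError("ROI mask has no pixels")


@dataclass
class BackgroundSeries:
    """Mean background photoelectrons, per frame (length T) or scalar.

    Measured on a separate image series collected on areas containing no
    cells; subtracted frame-wise from the sample stacks.
    """

    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.atleast_1d(np.asarray(self.means, dtype=float))
        if self.means.ndim != 1:
            raise ValueError("background means must be scalar or a 1-D per-frame vector")
        if not np.all(np.isfinite(self.means)) or np.any(self.means < 0):
            raise ValueError("background means must be finite and non-negative")


def read_stack(
    path: str | Path,
    gain_e_per_adu: float,
    times: float | Iterable[float],
    channel: str = "donor_em_donor_exc",
) -> ImageStack:
    """Read a multi-page TIFF and convert camera ADU to photoelectrons.

    Parameters
    ----------
    path
        Multi-page TIFF file.
    gain_e_per_adu
        Camera conversion factor (electrons per digital unit), > 0.
    times
        Either the constant frame interval in seconds, or a vector of frame
        times (length must match the frame count).
    """
    if gain_e_per_adu <= 0:
        raise ValueError("gain_e_per_adu must be positive")
    raw = tifffile.imread(str(path))
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim != 3:
        raise ValueError(f"expected a (T, Y, X) TIFF, got shape {raw.shape}")
    t = np.atleast_1d(np.asarray(times, dtype=float))
    if t.size == 1:
        t = np.arange(raw.shape[0]) * float(t[0])
    elif t.size != raw.shape[0]:
        raise ValueError(f"{t.size} times supplied for {raw.shape[0]} frames")
    data = raw.astype(float) * float(gain_e_per_adu)
    meta = {"source": str(path), "gain_e_per_adu": float(gain_e_per_adu)}
    return ImageStack(data=data, times=t, channel=channel, meta=meta)


def write_stack(stack: ImageStack, path: str | Path, dtype: str = "float32") -> Path:
    """Write a stack as a multi-page TIFF (32-bit float by default)."""
    path = Path(path)
    tifffile.imwrite(str(path), stack.data.astype(dtype))
    return path


def _align_red(data: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate the red half onto the green half; out-of-bounds -> NaN."""
    dy, dx = int(shift[0]), int(shift[1])
    T, Y, X = data.shape
    out = np.full_like(data, np.nan, dtype=float)
    ys = slice(max(0, -dy), min(Y, Y - dy))
    xs = slice(max(0, -dx), min(X, X - dx))
    ys_src = slice(max(0, dy), min(Y, Y + dy))
    xs_src = slice(max(0, dx), min(X, X + dx))
    out[:, ys, xs] = data[:, ys_src, xs_src]
    return out


def split_dualview(
    mosaic: ImageStack, geom: DualViewGeometry
) -> tuple[ImageStack, ImageStack]:
    """Split a side-by-side Dual-View mosaic into co-registered channel stacks.

    Returns ``(green, red)`` where green is the donor-emission half and red
    the acceptor-emission ("FRET" channel) half, translated by ``geom.shift``
    so pixel ``(y, x)`` corresponds across the two.  Pixels that fall outside
    the red half after the shift are NaN.
    """
    axis = 2 if geom.split_axis == "vertical" else 1
    extent = mosaic.data.shape[axis]
    if extent % 2:
        raise ValueError(f"mosaic extent {extent} along split axis is odd; cannot halve")
    half = extent // 2
    dy, dx = geom.shift
    if abs(dy) >= mosaic.data.shape[1] // (2 if axis == 1 else 1) or abs(dx) >= (
        half if axis == 2 else mosaic.data.shape[2]
    ):
        raise ValueError("shift exceeds half-image extent")
    first = np.take(mosaic.data, range(half), axis=axis)
    second = np.take(mosaic.data, range(half, extent), axis=axis)
    green_raw, red_raw = (first, second) if geom.green_half == "first" else (second, first)
    red_aligned = _align_red(red_raw, geom.shift)
    green = ImageStack(green_raw.copy(), mosaic.times.copy(), "donor_em_donor_exc", dict(mosaic.meta))
    red = ImageStack(red_aligned, mosaic.times.copy(), "acceptor_em_donor_exc", dict(mosaic.meta))
    return green, red


def compose_dualview(
    green: ImageStack, red: ImageStack, geom: DualViewGeometry
) -> ImageStack:
    """Inverse of :func:`split_dualview` for zero-shift geometries.

    Used by the simulator to emit mosaics as a camera would record them; a
    nonzero ``geom.shift`` places the red half so that splitting with the
    same geometry re-aligns it.
    """
    if green.data.shape != red.data.shape:
        raise ValueError("halves must share shape")
    dy, dx = geom.shift
    red_raw = _align_red(red.data, (-dy, -dx))
    red_raw = np.nan_to_num(red_raw, nan=0.0)
    axis = 2 if geom.split_axis == "vertical" else 1
    halves = (green.data, red_raw) if geom.green_half == "first" else (red_raw, green.data)
    data = np.concatenate(halves, axis=axis)
    return ImageStack(data, green.times.copy(), "donor_em_donor_exc", dict(green.meta))


def register_halves(
    green: ImageStack, red: ImageStack, window: int = 10
) -> DualViewGeometry:
    """Find the integer shift aligning the red half onto the green half.

    Maximizes the normalized cross-correlation between the time-averaged
    frames over all integer shifts within ``±window`` pixels.  Ties break
    toward the smallest shift, so identical halves register at (0, 0).

    Raises
    ------
    ValueError
        If either half is (near-)constant, in which case the correlation is
        undefined and there is no structure to register on.
    """
    if green.frame_shape != red.frame_shape:
        raise ValueError("halves must share (Y, X) shape")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)  # all-NaN pixels
        g = np.nanmean(green.data, axis=0)
        r = np.nanmean(red.data, axis=0)
    if np.nanstd(g) < 1e-12 * max(1.0, abs(float(np.nanmean(g)))) or np.nanstd(r) < 1e-12 * max(
        1.0, abs(float(np.nanmean(r)))
    ):
        raise ValueError("cannot register: one or both halves have no structure")

    best: tuple[float, int, int, int] | None = None  # (-corr, |dy|+|dx|, dy, dx)
    Y, X = g.shape
    for dy in range(-window, window + 1):
        for dx in range(-window, window + 1):
            ys = slice(max(0, -dy), min(Y, Y - dy))
            xs = slice(max(0, -dx), min(X, X - dx))
            ys_src = slice(max(0, dy), min(Y, Y + dy))
            xs_src = slice(max(0, dx), min(X, X + dx))
            a = g[ys, xs].ravel()
            b = r[ys_src, xs_src].ravel()
            ok = np.isfinite(a) & np.isfinite(b)
            if ok.sum() < 9:
                continue
            a, b = a[ok], b[ok]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            corr = float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
            key = (-corr, abs(dy) + abs(dx), dy, dx)
            if best is None or key < best:
                best = key
    if best is None:
        raise ValueError("cannot register: no valid overlap within the search window")
    _, _, dy, dx = best
    return DualViewGeometry(split_axis="vertical", green_half="first", shift=(dy, dx))


def subtract_background(stack: ImageStack, bg: BackgroundSeries) -> ImageStack:
    """Subtract per-frame scalar background means; negatives are retained.

    Clamping would bias the fitted offset, so values are left as-is.
    """
    means = bg.means
    if means.size == 1:
        means = np.full(stack.n_frames, means[0])
    elif means.size != stack.n_frames:
        raise ValueError(f"{means.size} background means for {stack.n_frames} frames")
    data = stack.data - means[:, None, None]
    return ImageStack(data, stack.times.copy(), stack.channel, dict(stack.meta))


def extract_trace(stack: ImageStack, roi: RoiMask):
    """Mean pixel value inside the ROI at each time point, as a DecayTrace."""
    from .decayfit import DecayTrace  # deferred: decayfit imports this module

    if roi.mask.shape != stack.frame_shape:
        raise ValueError(
            f"ROI shape {roi.mask.shape} does not match frame shape {stack.frame_shape}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        values = np.nanmean(stack.data[:, roi.mask], axis=1)
    return DecayTrace(times=stack.times.copy(), values=values)
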