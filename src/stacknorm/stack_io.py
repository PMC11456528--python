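"""Reading, writing and basic geometry of Z-stacks stored as TIFF sequences.

A Z-stack is an ordered series of equally sized grayscale optical
sections; section index 0 is the shallowest focal plane and the index
increases with depth, matching how confocal acquisitions scan from the
top of a specimen downward.  Stacks are exchanged on disk as a
directory of one single-channel TIFF per section, ordered by a
natural-numeric sort of the filenames (``s2.tif`` before ``s10.tif``),
which is how confocal export software numbers frames.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

__all__ = [
    "ZStack",
    "NormalizedZStack",
    "load_stack",
    "save_stack",
    "to_grayscale",
    "crop_stack",
    "natural_sort_key",
]

#: ITU-R 601 luma coefficients for RGB -> grayscale reduction.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class ZStack:
    """An integer-valued Z-stack with a declared bit depth.

    Parameters
    ----------
    data
        Array of shape ``(n_sections, height, width)`` holding native
        integer intensities.
    bit_depth
        8 or 16; every pixel must lie in ``[0, 2**bit_depth - 1]``.
    """

    data: np.ndarray
    bit_depth: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3-D (z, y, x); got shape {self.data.shape}"
            )
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit depth must be 8 or 16, got {self.bit_depth}")
        dtype = np.uint8 if self.bit_depth == 8 else np.uint16
        if self.data.dtype != dtype:
            if self.data.min(initial=0) < 0 or self.data.max(initial=0) > self.dtype_max:
                raise ValueError(
                    f"pixel values outside [0, {self.dtype_max}] for "
                    f"{self.bit_depth}-bit stack"
                )
            self.data = self.data.astype(dtype)

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def dtype_max(self) -> int:
        return (1 << self.bit_depth) - 1

    def sections(self) -> Iterable[np.ndarray]:
        """Iterate over 2-D sections from shallowest to deepest."""
        return iter(self.data)


@dataclass
class NormalizedZStack:
    """A real-valued stack produced by normalization.

    Values are non-negative ratios (or rescaled ratios) with no dtype
    ceiling; ``source_bit_depth`` remembers the integer range the stack
    will be clipped back into on export.
    """

    data: np.ndarray
    source_bit_depth: int

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(
                f"stack data must be 3-D (z, y, x); got shape {self.data.shape}"
            )
        if self.source_bit_depth not in (8, 16):
            raise ValueError(
                f"bit depth must be 8 or 16, got {self.source_bit_depth}"
            )
        if np.any(self.data < 0):
            raise ValueError("normalized stack contains negative values")

    @property
    def n_sections(self) -> int:
        return self.data.shape[0]

    @property
    def height(self) -> int:
        return self.data.shape[1]

    @property
    def width(self) -> int:
        return self.data.shape[2]

    @property
    def dtype_max(self) -> int:
        return (1 << self.source_bit_depth) - 1

    def sections(self) -> Iterable[np.ndarray]:
        return iter(self.data)


def natural_sort_key(name: str) -> tuple:
    """Sort key treating digit runs as numbers, so s2 sorts before s10."""
    parts = re.split(r"(\d+)", name)
    return tuple(int(p) if p.isdigit() else p.lower() for p in parts)


def to_grayscale(frame: np.ndarray) -> np.ndarray:
    """Reduce a frame to single-channel grayscale.

    Single-channel frames pass through unchanged.  3-channel frames are
    assumed RGB and reduced with the standard luma weights
    ``0.299 R + 0.587 G + 0.114 B``, rounded to the nearest integer in
    the frame's own dtype.
    """
    frame = np.asarray(frame)
    if frame.ndim == 2:
        return frame
    if frame.ndim == 3 and frame.shape[2] == 1:
        return frame[:, :, 0]
    if frame.ndim == 3 and frame.shape[2] == 3:
        gray = frame.astype(np.float64) @ _LUMA_WEIGHTS
        return np.rint(gray).astype(frame.dtype)
    raise ValueError(
        f"unsupported channel layout: expected 1 or 3 channels, got shape {frame.shape}"
    )


def _bit_depth_of(dtype: np.dtype) -> int:
    if dtype == np.uint8:
        return 8
    if dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported TIFF dtype {dtype}; expected uint8 or uint16")


def load_stack(directory: str | Path) -> ZStack:
    """Load a Z-stack from a directory of per-section TIFF files.

    Files are ordered by natural-numeric filename sort.  Multichannel
    frames are converted to grayscale; all frames must share one shape
    and one dtype.
    """
    directory = Path(directory)
    files = sorted(
        (p for p in directory.iterdir() if p.suffix.lower() in _TIFF_SUFFIXES),
        key=lambda p: natural_sort_key(p.name),
    )
    if not files:
        raise FileNotFoundError(f"no images found in {directory}")
    frames = []
    for path in files:
        frame = to_grayscale(tifffile.imread(path))
        frames.append(frame)
    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent section shape across {directory}: {sorted(shapes)}")
    dtypes = {f.dtype for f in frames}
    if len(dtypes) > 1:
        raise ValueError(
            f"inconsistent bit depth across {directory}: {sorted(map(str, dtypes))}"
        )
    data = np.stack(frames)
    return ZStack(data, bit_depth=_bit_depth_of(data.dtype))


def save_stack(stack: ZStack | NormalizedZStack, directory: str | Path) -> list[Path]:
    """Write one uncompressed grayscale TIFF per section.

    Filenames are zero-padded (``section_000.tif`` ...) so that a
    subsequent :func:`load_stack` restores the original order.  A
    :class:`NormalizedZStack` is clipped to the source integer range
    and rounded to the source dtype before writing, restoring the
    native bit depth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if isinstance(stack, NormalizedZStack):
        dtype = np.uint8 if stack.source_bit_depth == 8 else np.uint16
        data = np.rint(np.clip(stack.data, 0, stack.dtype_max)).astype(dtype)
    else:
        data = stack.data
    width = max(3, len(str(stack.n_sections - 1)))
    paths = []
    for z, section in enumerate(data):
        path = directory / f"section_{z:0{width}d}.tif"
        tifffile.imwrite(path, section)
        paths.append(path)
    return paths


def crop_stack(stack: ZStack, roi: Sequence[int]) -> ZStack:
    """Crop every section to the half-open rectangle ``(x0, y0, x1, y1)``.

    Coordinates are 0-based with y = row and x = column; the upper
    bounds are exclusive.  Cropping is used to restrict analysis to a
    region of interest, e.g. to exclude a surrounding cell monolayer
    whose signal is not attenuated by overlying tissue.
    """
    x0, y0, x1, y1 = roi
    if not (0 <= x0 < x1 <= stack.width and 0 <= y0 < y1 <= stack.height):
        raise ValueError(
            f"invalid ROI {tuple(roi)} for {stack.height}x{stack.width} sections"
        )
    return ZStack(stack.data[:, y0:y1, x0:x1].copy(), bit_depth=stack.bit_depth)
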