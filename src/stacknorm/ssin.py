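"""Section-specific intensity normalization (SsIN).

The core correction: the reference (NS) channel's mean intensity is
computed at every optical section after excluding zero pixels, and each
signal-of-interest (SOI) pixel is divided by the NS mean at its own
depth.  Because both channels are attenuated by the same overlying
tissue, the per-section NS means track the depth loss, and the division
cancels it while leaving genuine spatial structure of the SOI intact.

Thresholding is deliberately asymmetric: a user-selected intensity
window gates which SOI pixels are analyzed (out-of-window pixels are
treated as background or artifact and set to zero), while the NS mean
excludes only zero pixels — much of the depth-loss information lives in
the low NS pixel values and must not be thresholded away.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .stack_io import NormalizedZStack, ZStack

__all__ = [
    "ThresholdRange",
    "SectionMeans",
    "analysis_mask",
    "masked_mean",
    "section_means",
    "ssin_normalize",
]


@dataclass(frozen=True)
class ThresholdRange:
    """Inclusive intensity window ``[lo, hi]`` in native pixel units."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo < 0 or self.lo > self.hi:
            raise ValueError(f"invalid threshold range [{self.lo}, {self.hi}]")

    @classmethod
    def full(cls, dtype_max: float) -> "ThresholdRange":
        """The permissive window covering the whole dynamic range."""
        return cls(0, dtype_max)


@dataclass
class SectionMeans:
    """Per-section non-zero mean intensities of the NS channel."""

    means: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        if self.means.ndim != 1:
            raise ValueError("section means must be a 1-D sequence")
        if np.any(self.means <= 0):
            raise ValueError("section means must be strictly positive")

    @property
    def n_sections(self) -> int:
        return self.means.shape[0]

    @property
    def max(self) -> float:
        return float(self.means.max())


def _section_data(stack) -> np.ndarray:
    if isinstance(stack, (ZStack, NormalizedZStack)):
        return stack.data
    return np.asarray(stack)


def analysis_mask(section: np.ndarray, threshold: ThresholdRange) -> np.ndarray:
    """Boolean mask of pixels that participate in analysis.

    True exactly where ``lo <= pixel <= hi`` and the pixel is non-zero;
    zero pixels are always excluded because they carry no signal.
    """
    section = np.asarray(section)
    return (section >= threshold.lo) & (section <= threshold.hi) & (section != 0)


def masked_mean(section: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of the pixels selected by ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no analyzable pixels in section")
    return float(np.asarray(section, dtype=np.float64)[mask].mean())


def section_means(ns_stack: ZStack) -> SectionMeans:
    """Per-section non-zero means of the normalization channel.

    No user threshold is applied to the NS: only zero pixels are
    excluded.  An all-zero section is an error — there is no sensible
    mean to normalize against at that depth.
    """
    data = _section_data(ns_stack)
    means = np.empty(data.shape[0])
    for z, section in enumerate(data):
        nonzero = section != 0
        if not nonzero.any():
            raise ValueError(f"no analyzable pixels in NS section {z}")
        means[z] = section[nonzero].mean(dtype=np.float64)
    return SectionMeans(means)


def ssin_normalize(
    soi_stack: ZStack,
    ns_means: SectionMeans,
    soi_threshold: ThresholdRange | None = None,
    rescale_mode: Literal["none", "max_mean"] = "max_mean",
) -> NormalizedZStack:
    """Divide every SOI pixel by the NS mean at its focal depth.

    Parameters
    ----------
    soi_stack
        Signal-of-interest stack; must have one section per NS mean and
        come from the same sample at the same section thickness and
        resolution as the NS.
    ns_means
        Output of :func:`section_means` on the NS stack.
    soi_threshold
        Intensity window gating SOI pixels; pixels outside it (and zero
        pixels) are set to 0 in the output, preserving image geometry.
        Defaults to the full dynamic range.
    rescale_mode
        ``"max_mean"`` (default) multiplies the ratios by the maximum
        NS mean, putting the output back on an intensity-like scale so
        it survives native-bit-depth export: the brightest-NS section is
        left approximately unchanged and deeper sections are brightened.
        ``"none"`` keeps the raw ratios.

    Returns
    -------
    NormalizedZStack
        Real-valued normalized stack at the SOI's source bit depth.
    """
    data = _section_data(soi_stack)
    if data.shape[0] != ns_means.n_sections:
        raise ValueError(
            "channel stacks not aligned: "
            f"SOI has {data.shape[0]} sections, NS has {ns_means.n_sections}"
        )
    if soi_threshold is None:
        if isinstance(soi_stack, ZStack):
            soi_threshold = ThresholdRange.full(soi_stack.dtype_max)
        else:
            soi_threshold = ThresholdRange(0, np.inf)
    if rescale_mode not in ("none", "max_mean"):
        raise ValueError(f"unknown rescale mode {rescale_mode!r}")

    out = np.zeros(data.shape, dtype=np.float64)
    scale = ns_means.max if rescale_mode == "max_mean" else 1.0
    for z, section in enumerate(data):
        keep = analysis_mask(section, soi_threshold)
        out[z][keep] = section[keep].astype(np.float64) / ns_means.means[z] * scale
    bit_depth = soi_stack.bit_depth if isinstance(soi_stack, ZStack) else 8
    return NormalizedZStack(out, source_bit_depth=bit_depth)
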