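"""Depth-loss and pixel-distribution diagnostics.

Two views of depth-dependent intensity loss: a depth profile (the
masked mean pixel value of every optical section as a percentage of the
stack's maximum section mean) and a histogram cube (a per-section
histogram of analyzable pixel values, rendered as a section x bin
heatmap with a log color scale).  Both are computed before and after
normalization to show what the correction did.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ssin import ThresholdRange, analysis_mask, masked_mean
from .stack_io import NormalizedZStack, ZStack

__all__ = [
    "DepthProfile",
    "HistogramCube",
    "depth_profile",
    "histogram_cube",
    "render_depth_plot",
    "render_histogram_cube",
]


@dataclass
class DepthProfile:
    """Per-section mean intensity as a percentage of the maximum.

    ``section_means`` keeps the raw masked means alongside, since some
    workflows want absolute rather than relative units.
    """

    percent_of_max: np.ndarray
    section_means: np.ndarray

    def __post_init__(self) -> None:
        self.percent_of_max = np.asarray(self.percent_of_max, dtype=np.float64)
        self.section_means = np.asarray(self.section_means, dtype=np.float64)

    @property
    def n_sections(self) -> int:
        return self.percent_of_max.shape[0]

    def to_csv(self, path: str | Path) -> None:
        rows = np.column_stack(
            [np.arange(self.n_sections), self.section_means, self.percent_of_max]
        )
        np.savetxt(
            path,
            rows,
            delimiter=",",
            header="section,mean,percent_of_max",
            comments="",
            fmt=("%d", "%.6f", "%.6f"),
        )


@dataclass
class HistogramCube:
    """Per-section histograms of analyzable pixel values.

    ``counts`` has one row per optical section and one column per
    intensity bin; a row sums to the number of in-threshold non-zero
    pixels of that section.
    """

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)

    @property
    def n_sections(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    def to_csv(self, path: str | Path) -> None:
        header = "section," + ",".join(
            f"bin_{lo:g}_{hi:g}" for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:])
        )
        rows = np.column_stack([np.arange(self.n_sections), self.counts])
        np.savetxt(path, rows, delimiter=",", header=header, comments="", fmt="%d")


def _stack_data(stack) -> np.ndarray:
    if isinstance(stack, (ZStack, NormalizedZStack)):
        return stack.data
    return np.asarray(stack)


def _default_threshold(stack) -> ThresholdRange:
    if isinstance(stack, ZStack):
        return ThresholdRange.full(stack.dtype_max)
    return ThresholdRange(0, np.inf)


def depth_profile(stack, threshold: ThresholdRange | None = None) -> DepthProfile:
    """Masked per-section means, normalized to percent of the maximum.

    Every section must contain at least one analyzable (in-threshold,
    non-zero) pixel.  The maximum entry of the profile is exactly 100.
    """
    data = _stack_data(stack)
    if threshold is None:
        threshold = _default_threshold(stack)
    means = np.empty(data.shape[0])
    for z, section in enumerate(data):
        mask = analysis_mask(section, threshold)
        if not mask.any():
            raise ValueError(f"no analyzable pixels in section {z}")
        means[z] = masked_mean(section, mask)
    return DepthProfile(percent_of_max=means / means.max() * 100.0, section_means=means)


def histogram_cube(
    stack,
    n_bins: int = 256,
    threshold: ThresholdRange | None = None,
) -> HistogramCube:
    """Histogram the analyzable pixels of every section over uniform bins.

    Integer stacks are binned over the full dynamic range
    ``[0, 2**bit_depth - 1]``; real-valued normalized stacks have no
    dtype ceiling, so they are binned over ``[0, observed max]``.  The
    final bin is right-closed.
    """
    if n_bins < 2:
        raise ValueError(f"invalid bin count {n_bins}")
    data = _stack_data(stack)
    if threshold is None:
        threshold = _default_threshold(stack)
    if isinstance(stack, ZStack):
        top = float(stack.dtype_max)
    else:
        top = float(data.max())
        if top <= 0:
            top = 1.0
    edges = np.linspace(0.0, top, n_bins + 1)
    counts = np.empty((data.shape[0], n_bins), dtype=np.int64)
    for z, section in enumerate(data):
        mask = analysis_mask(section, threshold)
        counts[z] = np.histogram(section[mask], bins=edges)[0]
    return HistogramCube(counts=counts, bin_edges=edges)


def render_depth_plot(
    pre: DepthProfile,
    post: DepthProfile | None,
    out: str | Path,
    title: str = "Depth-dependent intensity loss",
) -> Path:
    """Line plot of percent-of-max section means, pre vs post correction."""
    if post is not None and post.n_sections != pre.n_sections:
        raise ValueError(
            f"profile length mismatch: {pre.n_sections} vs {post.n_sections}"
        )
    out = Path(out)
    fig, ax = plt.subplots(figsize=(6, 4))
    sections = np.arange(pre.n_sections)
    ax.plot(sections, pre.percent_of_max, marker="o", ms=3, label="pre-normalization")
    if post is not None:
        ax.plot(
            sections, post.percent_of_max, marker="s", ms=3, label="post-normalization"
        )
    ax.set_xlabel("optical section (top → bottom)")
    ax.set_ylabel("mean pixel value (% of max section)")
    ax.set_ylim(0, 105)
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out


def render_histogram_cube(
    cube: HistogramCube,
    out: str | Path,
    colormap: str = "viridis",
    title: str = "Pixel-value distribution by section",
) -> Path:
    """Heatmap of the histogram cube with a log(1 + count) color scale.

    The +1 offset lets empty bins render at the colormap floor instead
    of being undefined on the log scale.
    """
    out = Path(out)
    fig, ax = plt.subplots(figsize=(6, 4))
    img = ax.imshow(
        np.log1p(cube.counts),
        aspect="auto",
        origin="upper",
        cmap=colormap,
        extent=(cube.bin_edges[0], cube.bin_edges[-1], cube.n_sections - 0.5, -0.5),
    )
    ax.set_xlabel("pixel value")
    ax.set_ylabel("optical section")
    ax.set_title(title)
    fig.colorbar(img, ax=ax, label="log(1 + count)")
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
    return out
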