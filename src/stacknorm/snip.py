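"""Mean-intensity orthogonal projections and min/max-scaled heatmaps (SNIP).

A stack is collapsed along each axis by plain arithmetic averaging —
exactly how a mean-intensity projection is computed — giving three
views: xy (through depth), xz (through rows) and yz (through columns).
Each view is independently min/max-scaled onto the 8-bit range so the
heatmap uses the full visual range, and the three are composed in the
conventional orthogonal layout.  Projections include every pixel,
zeros too: the zero-exclusion rule belongs to the mean calculations
feeding normalization and depth profiles, not to projections.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile

from .stack_io import NormalizedZStack, ZStack

__all__ = ["ProjectionSet", "mean_projection", "minmax_scale", "snip_heatmap"]

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}


@dataclass
class ProjectionSet:
    """The three mean projections, raw and min/max-scaled to 8-bit.

    ``xy`` is height x width (mean over z, at the input's spatial
    resolution), ``xz`` is sections x width (mean over y), ``yz`` is
    height x sections (mean over x).
    """

    xy: np.ndarray
    xz: np.ndarray
    yz: np.ndarray
    xy_scaled: np.ndarray
    xz_scaled: np.ndarray
    yz_scaled: np.ndarray

    def save(self, directory: str | Path, stem: str = "projection") -> list[Path]:
        """Export scaled projections as TIFF and raw projections as CSV."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name in ("xy", "xz", "yz"):
            tif = directory / f"{stem}_{name}_scaled.tif"
            tifffile.imwrite(tif, getattr(self, f"{name}_scaled"))
            csv = directory / f"{stem}_{name}_raw.csv"
            np.savetxt(csv, getattr(self, name), delimiter=",", fmt="%.6f")
            written += [tif, csv]
        return written


def _stack_data(stack) -> np.ndarray:
    if isinstance(stack, (ZStack, NormalizedZStack)):
        return stack.data
    return np.asarray(stack)


def mean_projection(stack, axis: str) -> np.ndarray:
    """Arithmetic mean of all pixels along one axis of the stack.

    ``axis="z"`` gives the xy view (height x width), ``axis="y"`` the
    xz view (sections x width) and ``axis="x"`` the yz view
    (height x sections).  No thresholding is applied.
    """
    data = _stack_data(stack)
    if data.size == 0:
        raise ValueError("cannot project an empty stack")
    if axis not in _AXIS_INDEX:
        raise ValueError(f"axis must be one of {sorted(_AXIS_INDEX)}, got {axis!r}")
    proj = data.mean(axis=_AXIS_INDEX[axis], dtype=np.float64)
    if axis == "x":
        proj = proj.T  # (z, y) -> (y, z) so rows stay image rows
    return proj


def minmax_scale(img: np.ndarray) -> np.ndarray:
    """Affinely map an image onto the full 8-bit range.

    The smallest value maps to 0 and the largest to 255; ties are
    rounded half away from zero.  A constant image has no contrast to
    stretch and maps to all zeros.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot scale an empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.uint8)
    scaled = (img - lo) / (hi - lo) * 255.0
    return np.floor(scaled + 0.5).astype(np.uint8)  # half away from zero (values >= 0)


def snip_heatmap(
    stack,
    colormap: str = "inferno",
    out: str | Path | None = None,
    title: str = "Orthogonal mean-projection heatmap",
) -> ProjectionSet:
    """Compute all three projections and render the composite heatmap.

    The xy view sits at the center, the xz view below it (depth running
    downward) and the yz view to its right, each min/max-scaled
    independently to 8-bit; a shared colorbar shows the scaled range.
    Returns the :class:`ProjectionSet`; writes the figure if ``out``
    is given.
    """
    xy = mean_projection(stack, "z")
    xz = mean_projection(stack, "y")
    yz = mean_projection(stack, "x")
    pset = ProjectionSet(
        xy=xy,
        xz=xz,
        yz=yz,
        xy_scaled=minmax_scale(xy),
        xz_scaled=minmax_scale(xz),
        yz_scaled=minmax_scale(yz),
    )
    if out is not None:
        _render_composite(pset, colormap, Path(out), title)
    return pset


def _render_composite(
    pset: ProjectionSet, colormap: str, out: Path, title: str
) -> None:
    h, w = pset.xy.shape
    z = pset.xz.shape[0]
    fig, axes = plt.subplots(
        2,
        2,
        figsize=(7, 7 * (h + z) / (w + z)),
        gridspec_kw={
            "width_ratios": [w, z],
            "height_ratios": [h, z],
            "wspace": 0.05,
            "hspace": 0.05,
        },
    )
    im = axes[0, 0].imshow(pset.xy_scaled, cmap=colormap, vmin=0, vmax=255)
    axes[0, 1].imshow(pset.yz_scaled, cmap=colormap, vmin=0, vmax=255, aspect="auto")
    axes[1, 0].imshow(pset.xz_scaled, cmap=colormap, vmin=0, vmax=255, aspect="auto")
    axes[0, 0].set_ylabel("y")
    axes[1, 0].set_xlabel("x")
    axes[1, 0].set_ylabel("z")
    axes[0, 1].set_xlabel("z")
    for ax in axes.flat:
        ax.set_xticks([])
        ax.set_yticks([])
    axes[1, 1].axis("off")
    fig.suptitle(title)
    fig.colorbar(im, ax=axes[1, 1], location="left", label="scaled intensity")
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
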