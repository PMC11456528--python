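"""Linear brightness/contrast adjustment of normalized stacks.

Dividing by the NS mean can leave a normalized stack dim; this optional
post-processing step maps a user-selected intensity window
``[user_min, user_max]`` linearly onto the full dynamic range: each
pixel becomes ``clip(round(alpha * p - beta), 0, dtype_max)`` with
``alpha = dtype_max / (user_max - user_min)`` and
``beta = user_min * alpha``, so ``user_min`` lands exactly on 0 and
``user_max`` exactly on ``dtype_max``; values outside the window
saturate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack_io import NormalizedZStack, ZStack

__all__ = ["ScaleParams", "compute_scale", "apply_scale", "window_stats"]


@dataclass(frozen=True)
class ScaleParams:
    """Scale factor alpha and offset beta for a contrast window."""

    alpha: float
    beta: float
    user_min: float
    user_max: float
    dtype_max: int


def compute_scale(user_min: float, user_max: float, dtype_max: int) -> ScaleParams:
    """Derive alpha/beta from an intensity window.

    ``alpha`` is the dynamic-range maximum divided by the window width;
    ``beta`` is the window minimum times alpha.
    """
    if not (0 <= user_min < user_max <= dtype_max):
        raise ValueError(
            f"empty intensity window [{user_min}, {user_max}] for dtype max {dtype_max}"
        )
    alpha = dtype_max / (user_max - user_min)
    return ScaleParams(
        alpha=alpha,
        beta=user_min * alpha,
        user_min=user_min,
        user_max=user_max,
        dtype_max=int(dtype_max),
    )


def apply_scale(stack: ZStack | NormalizedZStack, params: ScaleParams) -> ZStack:
    """Apply the linear transform pixel-wise and quantize.

    ``out = clip(round(alpha * p - beta), 0, dtype_max)``, rounding half
    away from zero; the result is an integer stack at the bit depth
    implied by ``dtype_max``.
    """
    data = stack.data.astype(np.float64)
    out = params.alpha * data - params.beta
    out = np.clip(np.floor(out + 0.5), 0, params.dtype_max)
    bit_depth = 8 if params.dtype_max <= 255 else 16
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return ZStack(out.astype(dtype), bit_depth=bit_depth)


def window_stats(stack: ZStack | NormalizedZStack) -> np.ndarray:
    """Per-section min / max / percentile table to guide window choice.

    Returns an array with columns (section, min, p1, p50, p99, max)
    over non-zero pixels; sections with no non-zero pixels report all
    zeros.  Printed by the CLI in place of an interactive picker.
    """
    rows = []
    for z, section in enumerate(stack.data):
        vals = section[section != 0]
        if vals.size == 0:
            rows.append((z, 0.0, 0.0, 0.0, 0.0, 0.0))
        else:
            p1, p50, p99 = np.percentile(vals, [1, 50, 99])
            rows.append((z, float(vals.min()), p1, p50, p99, float(vals.max())))
    return np.asarray(rows)
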