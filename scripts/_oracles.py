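"""Per-pixel reference implementations used as independent cross-checks."""

import numpy as np


def brute_force_ssin(soi, means, lo, hi, scale):
    out = np.zeros(soi.shape, dtype=np.float64)
    for z in range(soi.shape[0]):
        for y in range(soi.shape[1]):
            for x in range(soi.shape[2]):
                p = float(soi[z, y, x])
                if p != 0 and lo <= p <= hi:
                    out[z, y, x] = p / means[z] * scale
    return out


def brute_force_projection(data, axis_name):
    z, h, w = data.shape
    if axis_name == "z":
        return np.array([[data[:, y, x].mean() for x in range(w)] for y in range(h)])
    if axis_name == "y":
        return np.array([[data[k, :, x].mean() for x in range(w)] for k in range(z)])
    return np.array([[data[k, y, :].mean() for k in range(z)] for y in range(h)])


def brute_force_rescale(data, alpha, beta, dtype_max):
    out = np.empty(data.shape, dtype=np.int64)
    for idx in np.ndindex(data.shape):
        v = alpha * float(data[idx]) - beta
        v = np.floor(v + 0.5) if v >= 0 else np.ceil(v - 0.5)
        out[idx] = min(max(v, 0), dtype_max)
    return out
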