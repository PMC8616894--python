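"""Independent brute-force oracles used to verify the package's numerics.

Everything here is deliberately written as plain scalar loops (or direct
closed-form evaluation) so it shares no code path with the implementation
it checks.
"""

import math

import numpy as np


def spin_echo_scalar(pd, t1, t2, te, tr):
    if pd == 0:
        return 0.0
    return pd * (1.0 - math.exp(-tr / t1)) * math.exp(-te / t2)


def nmse_loops(x, xp):
    num = den = 0.0
    for a, b in zip(x.ravel(), xp.ravel()):
        num += (a - b) ** 2
        den += a * a
    return num / den


def psnr_loops(x, xp):
    n = x.size
    mse = 0.0
    for a, b in zip(x.ravel(), xp.ravel()):
        mse += (a - b) ** 2
    mse /= n
    max_range = max(x.max(), xp.max()) - min(x.min(), xp.min())
    return 10.0 * math.log10(max_range ** 2 / mse)


def gaussian_window_loops(size=11, sigma=1.5):
    w = np.empty((size, size))
    half = (size - 1) / 2.0
    for i in range(size):
        for j in range(size):
            w[i, j] = math.exp(-((i - half) ** 2 + (j - half) ** 2) / (2 * sigma ** 2))
    return w / w.sum()


def ssim_global_loops(x, xp, data_range=None):
    n = x.size
    if data_range is None:
        data_range = max(x.max(), xp.max()) - min(x.min(), xp.min())
        if data_range == 0:
            data_range = 1.0
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mx = sum(x.ravel()) / n
    my = sum(xp.ravel()) / n
    vx = vy = cxy = 0.0
    for a, b in zip(x.ravel(), xp.ravel()):
        vx += (a - mx) ** 2
        vy += (b - my) ** 2
        cxy += (a - mx) * (b - my)
    vx /= n
    vy /= n
    cxy /= n
    return ((2 * mx * my + c1) * (2 * cxy + c2)
            / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))


def _local_stats_loops(x, xp, w):
    """Per-window Gaussian-weighted moments (valid positions)."""
    k = w.shape[0]
    H, W = x.shape
    oh, ow = H - k + 1, W - k + 1
    stats = np.empty((oh, ow, 5))
    for i in range(oh):
        for j in range(ow):
            mx = my = 0.0
            for a in range(k):
                for b in range(k):
                    mx += w[a, b] * x[i + a, j + b]
                    my += w[a, b] * xp[i + a, j + b]
            vx = vy = cxy = 0.0
            for a in range(k):
                for b in range(k):
                    vx += w[a, b] * x[i + a, j + b] ** 2
                    vy += w[a, b] * xp[i + a, j + b] ** 2
                    cxy += w[a, b] * x[i + a, j + b] * xp[i + a, j + b]
            stats[i, j] = (mx, my, vx - mx * mx, vy - my * my, cxy - mx * my)
    return stats


def ssim_windowed_loops(x, xp, data_range=None):
    """Mean 11x11-Gaussian-windowed local SSIM, scalar loops throughout."""
    if data_range is None:
        data_range = max(x.max(), xp.max()) - min(x.min(), xp.min())
        if data_range == 0:
            data_range = 1.0
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    w = gaussian_window_loops()
    stats = _local_stats_loops(x, xp, w)
    total = 0.0
    for i in range(stats.shape[0]):
        for j in range(stats.shape[1]):
            mx, my, vx, vy, cxy = stats[i, j]
            total += ((2 * mx * my + c1) * (2 * cxy + c2)
                      / ((mx ** 2 + my ** 2 + c1) * (vx + vy + c2)))
    return total / (stats.shape[0] * stats.shape[1])


def ms_ssim_single_scale_loops(x, xp, data_range=None):
    """Single-scale MS-SSIM equals the windowed SSIM mean."""
    return ssim_windowed_loops(x, xp, data_range=data_range)


def bilinear_resize_loops(image, out_h, out_w):
    """Bilinear resize under the half-pixel-center convention, edge-clamped."""
    in_h, in_w = image.shape
    out = np.empty((out_h, out_w))
    for i in range(out_h):
        for j in range(out_w):
            y = (i + 0.5) * in_h / out_h - 0.5
            x = (j + 0.5) * in_w / out_w - 0.5
            y0, x0 = math.floor(y), math.floor(x)
            dy, dx = y - y0, x - x0
            vals = 0.0
            for (yy, wy) in ((y0, 1 - dy), (y0 + 1, dy)):
                for (xx, wx) in ((x0, 1 - dx), (x0 + 1, dx)):
                    yc = min(max(yy, 0), in_h - 1)
                    xc = min(max(xx, 0), in_w - 1)
                    vals += wy * wx * image[yc, xc]
            out[i, j] = vals
    return out


def ema_closed_form(s0, c, decay, k):
    """Shadow after k EMA steps with constant current value c."""
    return s0 * decay ** k + c * (1 - decay ** k)


def numeric_gradient(f, x, eps=1e-4):
    """Central-difference gradient of scalar f at array x."""
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy()
        xp[idx] += eps
        xm = x.copy()
        xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
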