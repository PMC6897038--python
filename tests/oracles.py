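"""Independent brute-force reference implementations used only by tests.

Everything here is written as explicit per-pixel / per-cell Python loops,
deliberately sharing no code with the package, so agreement between the two
routes is meaningful.
"""

import math

import numpy as np

EPS = 1e-12


def gradients_oracle(patch):
    """Centred (-1 0 1) differences with edge replication, per-pixel loops."""
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    ix = np.zeros((h, w))
    iy = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            ix[y, x] = patch[y, min(x + 1, w - 1)] - patch[y, max(x - 1, 0)]
            iy[y, x] = patch[min(y + 1, h - 1), x] - patch[max(y - 1, 0), x]
    mag = np.sqrt(ix ** 2 + iy ** 2)
    theta = np.zeros((h, w))
    for y in range(h):
        for x in range(w):
            if mag[y, x] > 0:
                theta[y, x] = math.atan2(iy[y, x], ix[y, x]) % (2 * math.pi)
    return ix, iy, mag, theta


def _vote(hist, theta, weight, n_bins, period):
    """Magnitude-weighted vote split between the two nearest bin centres."""
    width = period / n_bins
    pos = theta / width - 0.5
    lower = math.floor(pos)
    frac = pos - lower
    hist[lower % n_bins] += weight * (1.0 - frac)
    hist[(lower + 1) % n_bins] += weight * frac


def hog_oracle(patch, cell=4, block_cells=2, stride_px=4, n_bins=9):
    """HOG by explicit cell/block loops (unsigned orientation)."""
    patch = np.asarray(patch, dtype=float)
    h = patch.shape[0]
    _, _, mag, theta = gradients_oracle(patch)
    n_cells = h // cell
    hists = np.zeros((n_cells, n_cells, n_bins))
    for y in range(h):
        for x in range(h):
            _vote(hists[y // cell, x // cell], theta[y, x] % math.pi,
                  mag[y, x], n_bins, math.pi)
    stride_cells = stride_px // cell
    n_blocks = (n_cells - block_cells) // stride_cells + 1
    out = []
    for by in range(n_blocks):
        for bx in range(n_blocks):
            v = []
            for cy in range(block_cells):
                for cx in range(block_cells):
                    v.extend(hists[by * stride_cells + cy, bx * stride_cells + cx])
            v = np.asarray(v)
            norm = math.sqrt(float(np.sum(v ** 2)))
            out.extend(v / norm if norm > EPS else np.zeros_like(v))
    return np.asarray(out)


def exhog_signed_hist_oracle(patch, grid=6, n_bins=18):
    """Unnormalised signed orientation histograms per cell of a grid x grid layout."""
    patch = np.asarray(patch, dtype=float)
    h = patch.shape[0]
    _, _, mag, theta = gradients_oracle(patch)
    hists = np.zeros((grid, grid, n_bins))
    for y in range(h):
        for x in range(h):
            _vote(hists[(grid * y) // h, (grid * x) // h], theta[y, x],
                  mag[y, x], n_bins, 2 * math.pi)
    return hists


def exhog_oracle(patch, grid=6, n_bins=18, clip=0.2):
    """ExHOG: fold opposite bins into |difference| then sum, clip-normalise."""
    hists = exhog_signed_hist_oracle(patch, grid, n_bins)
    half = n_bins // 2
    out = []
    for cy in range(grid):
        for cx in range(grid):
            hcell = hists[cy, cx]
            v = np.concatenate([
                np.abs(hcell[:half] - hcell[half:]),
                hcell[:half] + hcell[half:],
            ])
            norm = math.sqrt(float(np.sum(v ** 2)))
            v = v / norm if norm > EPS else np.zeros_like(v)
            v = np.minimum(v, clip)
            norm = math.sqrt(float(np.sum(v ** 2)))
            v = v / norm if norm > EPS else np.zeros_like(v)
            out.extend(v)
    return np.asarray(out)


#: clockwise-from-top-left neighbour offsets, least significant bit first
LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1)]


def lbp_oracle(patch):
    """256-bin normalised LBP histogram by explicit per-pixel loops."""
    patch = np.asarray(patch, dtype=float)
    h, w = patch.shape
    hist = np.zeros(256)
    count = 0
    for y in range(1, h - 1):
        for x in range(1, w - 1):
            code = 0
            for bit, (dy, dx) in enumerate(LBP_OFFSETS):
                if patch[y + dy, x + dx] >= patch[y, x]:
                    code += 2 ** bit
            hist[code] += 1
            count += 1
    return hist / count


def conv_oracle(x, weights, bias):
    """Valid cross-correlation by an explicit quadruple loop per output pixel."""
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    n, c, h, w = x.shape
    o, _, k1, k2 = weights.shape
    oh, ow = h - k1 + 1, w - k2 + 1
    out = np.zeros((n, o, oh, ow))
    for ni in range(n):
        for oi in range(o):
            for yy in range(oh):
                for xx in range(ow):
                    acc = 0.0
                    for ci in range(c):
                        for i in range(k1):
                            for j in range(k2):
                                acc += weights[oi, ci, i, j] * x[ni, ci, yy + i, xx + j]
                    out[ni, oi, yy, xx] = acc + bias[oi]
    return out


def kappa_oracle(y_true, y_pred):
    """Cohen's kappa straight from the label vectors (fractions, not percent)."""
    y_true = list(y_true)
    y_pred = list(y_pred)
    n = len(y_true)
    classes = sorted(set(y_true) | set(y_pred))
    p_a = sum(t == p for t, p in zip(y_true, y_pred)) / n
    p_e = sum(
        (y_true.count(c) / n) * (y_pred.count(c) / n) for c in classes
    )
    return (p_a - p_e) / (1.0 - p_e)
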