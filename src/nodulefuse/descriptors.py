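"""Hand-crafted patch descriptors: HOG, ExHOG and LBP.

All three are computed from scratch with the exact geometry this package
standardises on:

* **HOG** (1296-dim on a 28x28 patch): unsigned gradient orientation
  (9 bins over [0, 180)), 4x4-pixel cells, blocks of 2x2 cells taken at a
  4-pixel stride (6x6 block positions), per-block L2 normalisation.
* **ExHOG** (648-dim on a 28x28 patch): signed orientation (18 bins over
  [0, 360)) accumulated per cell of a 6x6 grid; opposite bins i and i+9 are
  folded into 9 absolute-difference bins and 9 sum bins (18 per cell),
  removing the bright/dark edge-polarity ambiguity of plain HOG; per-cell
  L2 normalisation with clipping at 0.2 and renormalisation.
* **LBP** (256-dim): per-pixel 8-bit code comparing each of the eight
  neighbours against the centre (ties count as 1), histogrammed over the
  256 patterns and normalised to sum 1.

Orientation votes are magnitude-weighted with linear interpolation between
the two nearest bin centres (centres at (i + 1/2) * bin width, wrapping).

The transformer classes follow scikit-learn conventions (stateless
``fit``/``transform``) and accept either a single patch, a stack of patches
``(n, h, w)``, or flattened rows ``(n, h*w)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

#: canonical descriptor lengths at the standard working sizes
DESCRIPTOR_LENGTHS = {"HOG": 1296, "ExHOG": 648, "LBP": 256, "CNN": 40}

_EPS = 1e-12


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

@dataclass
class GradientField:
    """Per-pixel gradients of a patch.

    ``ix``/``iy`` come from centred (-1 0 1) differences (edge-replicated at
    the borders), ``magnitude`` = sqrt(ix^2 + iy^2), ``theta_signed`` lies in
    [0, 2*pi) and ``theta_unsigned`` in [0, pi); both angles are defined as 0
    wherever the magnitude vanishes.
    """

    ix: np.ndarray
    iy: np.ndarray
    magnitude: np.ndarray
    theta_signed: np.ndarray
    theta_unsigned: np.ndarray


def _batch_gradients(patches: np.ndarray):
    """(n, h, w) -> ix, iy, magnitude, theta_signed for the whole batch."""
    padded = np.pad(patches, ((0, 0), (1, 1), (1, 1)), mode="edge")
    ix = padded[:, 1:-1, 2:] - padded[:, 1:-1, :-2]
    iy = padded[:, 2:, 1:-1] - padded[:, :-2, 1:-1]
    magnitude = np.hypot(ix, iy)
    theta = np.mod(np.arctan2(iy, ix), 2.0 * np.pi)
    theta[magnitude == 0] = 0.0
    return ix, iy, magnitude, theta


def compute_gradients(patch: np.ndarray) -> GradientField:
    """Gradient field of a single 2-D patch (at least 3x3)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or min(patch.shape) < 3:
        raise ValueError(f"patch must be 2-D and at least 3x3, got shape {patch.shape}")
    ix, iy, magnitude, theta = _batch_gradients(patch[None])
    return GradientField(
        ix=ix[0],
        iy=iy[0],
        magnitude=magnitude[0],
        theta_signed=theta[0],
        theta_unsigned=np.mod(theta[0], np.pi),
    )


def _interp_votes(theta: np.ndarray, n_bins: int, period: float):
    """Linear-interpolation vote split: returns (bin0, bin1, w0, w1).

    Bin centres sit at (i + 0.5) * period / n_bins; a vote at angle theta is
    shared between the two nearest centres proportionally to distance,
    wrapping around the period.
    """
    width = period / n_bins
    pos = theta / width - 0.5
    lower = np.floor(pos)
    frac = pos - lower
    b0 = lower.astype(np.int64) % n_bins
    b1 = (b0 + 1) % n_bins
    return b0, b1, 1.0 - frac, frac


def _accumulate_cells(cell_y, cell_x, b, w, shape):
    """Scatter-add weighted votes into an (n, cy, cx, bins) histogram."""
    n, ncy, ncx, n_bins = shape
    hist = np.zeros(n * ncy * ncx * n_bins)
    sample = np.broadcast_to(np.arange(n)[:, None, None], b.shape)
    flat = ((sample * ncy + cell_y) * ncx + cell_x) * n_bins + b
    np.add.at(hist, flat.ravel(), w.ravel())
    return hist.reshape(shape)


def _as_patch_stack(X, size: int | None = None) -> np.ndarray:
    """Coerce input to (n, h, w) float64; flattened rows must be square."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 2 and size is not None and X.shape == (size, size):
        X = X[None]
    elif X.ndim == 2 and size is None and X.shape[0] == X.shape[1]:
        X = X[None]
    elif X.ndim == 2:
        side = int(round(np.sqrt(X.shape[1])))
        if side * side != X.shape[1]:
            raise ValueError(
                f"flattened rows of length {X.shape[1]} are not square patches"
            )
        X = X.reshape(X.shape[0], side, side)
    elif X.ndim != 3:
        raise ValueError(f"expected patches of dimension 2 or 3, got shape {X.shape}")
    if size is not None and X.shape[1:] != (size, size):
        raise ValueError(
            f"expected {size}x{size} patches, got {X.shape[1]}x{X.shape[2]}"
        )
    return X


# ---------------------------------------------------------------------------
# HOG
# ---------------------------------------------------------------------------

class HOGDescriptor(TransformerMixin, BaseEstimator):
    """Histogram of oriented gradients with overlapping-block normalisation.

    Parameters
    ----------
    patch_size : int, default 28
        Side of the square input patch; must be a multiple of ``cell_size``.
    cell_size : int, default 4
        Cell side in pixels.
    block_cells : int, default 2
        Block side in cells (2 -> 2x2-cell blocks).
    block_stride : int, default 4
        Block stride in pixels; must be a multiple of ``cell_size``.
    n_bins : int, default 9
        Unsigned orientation bins over [0, 180) degrees.

    With the defaults, a 28x28 patch yields 6x6 block positions x 4 cells
    x 9 bins = 1296 features.
    """

    def __init__(self, patch_size: int = 28, cell_size: int = 4,
                 block_cells: int = 2, block_stride: int = 4, n_bins: int = 9):
        self.patch_size = patch_size
        self.cell_size = cell_size
        self.block_cells = block_cells
        self.block_stride = block_stride
        self.n_bins = n_bins

    def _geometry(self):
        if self.patch_size % self.cell_size:
            raise ValueError("patch_size must be a multiple of cell_size")
        if self.block_stride % self.cell_size:
            raise ValueError("block_stride must be a multiple of cell_size")
        n_cells = self.patch_size // self.cell_size
        stride_cells = self.block_stride // self.cell_size
        n_blocks = (n_cells - self.block_cells) // stride_cells + 1
        if n_blocks < 1:
            raise ValueError("patch too small for the block geometry")
        return n_cells, stride_cells, n_blocks

    @property
    def n_features_(self) -> int:
        _, _, n_blocks = self._geometry()
        return n_blocks * n_blocks * self.block_cells ** 2 * self.n_bins

    def fit(self, X, y=None):
        self._geometry()
        return self

    def transform(self, X) -> np.ndarray:
        patches = _as_patch_stack(X, self.patch_size)
        n_cells, stride_cells, n_blocks = self._geometry()
        n = patches.shape[0]
        _, _, mag, theta = _batch_gradients(patches)
        theta_u = np.mod(theta, np.pi)
        b0, b1, w0, w1 = _interp_votes(theta_u, self.n_bins, np.pi)
        yy, xx = np.mgrid[0:self.patch_size, 0:self.patch_size]
        cy = np.broadcast_to(yy // self.cell_size, mag.shape)
        cx = np.broadcast_to(xx // self.cell_size, mag.shape)
        shape = (n, n_cells, n_cells, self.n_bins)
        hist = _accumulate_cells(cy, cx, b0, mag * w0, shape)
        hist += _accumulate_cells(cy, cx, b1, mag * w1, shape)

        out = np.empty((n, self.n_features_))
        block_len = self.block_cells ** 2 * self.n_bins
        pos = 0
        for by in range(n_blocks):
            for bx in range(n_blocks):
                y0, x0 = by * stride_cells, bx * stride_cells
                v = hist[:, y0:y0 + self.block_cells,
                         x0:x0 + self.block_cells, :].reshape(n, block_len)
                norm = np.linalg.norm(v, axis=1, keepdims=True)
                out[:, pos:pos + block_len] = np.where(norm > _EPS, v / np.maximum(norm, _EPS), 0.0)
                pos += block_len
        return out


# ---------------------------------------------------------------------------
# ExHOG
# ---------------------------------------------------------------------------

class ExHOGDescriptor(TransformerMixin, BaseEstimator):
    """Extended HOG: folded signed-orientation histograms with clipping.

    A signed 18-bin histogram per cell of a ``grid`` x ``grid`` cell layout
    (pixels are assigned to cell ``floor(grid * y / h)``, so the patch side
    need not divide evenly).  Opposite bins i and i+9 are folded into
    absolute-difference bins |h_i - h_{i+9}| followed by sum bins
    h_i + h_{i+9}; each 18-value cell vector is L2-normalised, clipped at
    ``clip`` and renormalised.  Defaults give 6x6 cells x 18 = 648 features.
    """

    def __init__(self, patch_size: int = 28, grid: int = 6, n_bins: int = 18,
                 clip: float = 0.2):
        self.patch_size = patch_size
        self.grid = grid
        self.n_bins = n_bins
        self.clip = clip

    @property
    def n_features_(self) -> int:
        return self.grid * self.grid * self.n_bins

    def fit(self, X, y=None):
        if self.n_bins % 2:
            raise ValueError("n_bins must be even (folding pairs opposite bins)")
        return self

    def signed_histograms(self, X) -> np.ndarray:
        """Unnormalised signed orientation histograms, shape (n, grid, grid, n_bins)."""
        patches = _as_patch_stack(X, self.patch_size)
        n = patches.shape[0]
        _, _, mag, theta = _batch_gradients(patches)
        b0, b1, w0, w1 = _interp_votes(theta, self.n_bins, 2.0 * np.pi)
        h = patches.shape[1]
        yy, xx = np.mgrid[0:h, 0:h]
        cy = np.broadcast_to((self.grid * yy) // h, mag.shape)
        cx = np.broadcast_to((self.grid * xx) // h, mag.shape)
        shape = (n, self.grid, self.grid, self.n_bins)
        hist = _accumulate_cells(cy, cx, b0, mag * w0, shape)
        hist += _accumulate_cells(cy, cx, b1, mag * w1, shape)
        return hist

    def transform(self, X) -> np.ndarray:
        if self.n_bins % 2:
            raise ValueError("n_bins must be even (folding pairs opposite bins)")
        hist = self.signed_histograms(X)
        half = self.n_bins // 2
        diff = np.abs(hist[..., :half] - hist[..., half:])
        total = hist[..., :half] + hist[..., half:]
        cells = np.concatenate([diff, total], axis=-1)

        norm = np.linalg.norm(cells, axis=-1, keepdims=True)
        cells = np.where(norm > _EPS, cells / np.maximum(norm, _EPS), 0.0)
        cells = np.minimum(cells, self.clip)
        norm = np.linalg.norm(cells, axis=-1, keepdims=True)
        cells = np.where(norm > _EPS, cells / np.maximum(norm, _EPS), 0.0)
        return cells.reshape(cells.shape[0], self.n_features_)


# ---------------------------------------------------------------------------
# LBP
# ---------------------------------------------------------------------------

#: neighbour offsets clockwise from the top-left, LSB first
_LBP_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, 1),
                (1, 1), (1, 0), (1, -1), (0, -1)]


class LBPDescriptor(TransformerMixin, BaseEstimator):
    """8-neighbour local binary pattern histogram (256 bins, sum 1).

    For every interior pixel the code is sum_p s(g_p - g_c) * 2^p with
    s(u) = 1 iff u >= 0 (ties count as 1) and neighbours enumerated
    clockwise from the top-left.  Exactly invariant under monotone affine
    intensity maps with positive slope.
    """

    n_features_ = 256

    def fit(self, X, y=None):
        return self

    def codes(self, X) -> np.ndarray:
        """Per-pixel LBP codes for the interior, shape (n, h-2, w-2)."""
        patches = _as_patch_stack(X)
        if min(patches.shape[1:]) < 3:
            raise ValueError(
                f"patch must be at least 3x3, got {patches.shape[1]}x{patches.shape[2]}"
            )
        center = patches[:, 1:-1, 1:-1]
        codes = np.zeros(center.shape, dtype=np.int64)
        h, w = patches.shape[1:]
        for bit, (dy, dx) in enumerate(_LBP_OFFSETS):
            neighbour = patches[:, 1 + dy:h - 1 + dy, 1 + dx:w - 1 + dx]
            codes += (neighbour >= center).astype(np.int64) << bit
        return codes

    def transform(self, X) -> np.ndarray:
        codes = self.codes(X)
        n = codes.shape[0]
        per_sample = codes.reshape(n, -1)
        offset = per_sample + 256 * np.arange(n)[:, None]
        hist = np.bincount(offset.ravel(), minlength=256 * n).reshape(n, 256)
        return hist.astype(np.float64) / per_sample.shape[1]


# ---------------------------------------------------------------------------
# single-patch wrappers (canonical working sizes)
# ---------------------------------------------------------------------------

def hog(patch28: np.ndarray) -> np.ndarray:
    """1296-dim HOG of a single 28x28 patch."""
    return HOGDescriptor().transform(_as_patch_stack(patch28, 28))[0]


def exhog(patch28: np.ndarray) -> np.ndarray:
    """648-dim ExHOG of a single 28x28 patch."""
    return ExHOGDescriptor().transform(_as_patch_stack(patch28, 28))[0]


def lbp(patch: np.ndarray) -> np.ndarray:
    """256-bin normalised LBP histogram of a single patch (any size >= 3x3)."""
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim == 2:
        patch = patch[None]
    return LBPDescriptor().transform(patch)[0]
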