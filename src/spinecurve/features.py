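"""Multi-feature descriptors for vertebra sub-windows.

Three complementary descriptors are computed on a canonical grayscale
window and concatenated into one fused vector:

* **Haar-like** rectangle contrasts (white-minus-black sums over an
  integral image) capture coarse intensity structure;
* **LBP** (local binary pattern) 256-bin histograms over a subregion grid
  capture texture;
* **HOG** (histogram of oriented gradients) block-normalized cell
  histograms capture edge orientation and shape.

The fused vector is standardized per feature with statistics learned on the
training set (stored alongside the detector model), so the three blocks
live on comparable scales.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import FeatureConfig

HAAR_KINDS = (
    "edge-horizontal",
    "edge-vertical",
    "line-horizontal",
    "line-vertical",
    "line-diag1",
    "line-diag2",
    "center-surround-1",
    "center-surround-2",
)

# Neighbor offsets for the 8-bit LBP code, bit p = 2**p, clockwise from the
# top-left corner of the 3x3 neighborhood.
LBP_OFFSETS = (
    (-1, -1),
    (-1, 0),
    (-1, 1),
    (0, 1),
    (1, 1),
    (1, 0),
    (1, -1),
    (0, -1),
)


@dataclass(frozen=True)
class HaarTemplate:
    """One Haar-like template: a kind plus a placement box in the window.

    ``(top, left, height, width)`` is the placement box; the white/black
    sub-rectangles are derived from the kind by :func:`template_rects`.
    """

    kind: str
    top: int
    left: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.kind not in HAAR_KINDS:
            raise ValueError(f"unknown Haar kind {self.kind!r}")
        if self.height < 2 or self.width < 2:
            raise ValueError("placement box must be at least 2x2")


# ---------------------------------------------------------------------------
# Integral image
# ---------------------------------------------------------------------------


def compute_integral_image(patch: np.ndarray) -> np.ndarray:
    """Summed-area table with a zero-padded first row and column.

    For a patch of shape ``(R, C)`` the result has shape ``(R+1, C+1)`` and
    the sum of any axis-aligned rectangle is four table lookups
    (:func:`rect_sum`).
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2 or patch.size == 0:
        raise ValueError("patch must be a non-empty 2-D array")
    ii = np.zeros((patch.shape[0] + 1, patch.shape[1] + 1), dtype=np.float64)
    np.cumsum(np.cumsum(patch, axis=0), axis=1, out=ii[1:, 1:])
    return ii


def rect_sum(integral: np.ndarray, top: int, left: int, height: int, width: int) -> float:
    """Pixel sum over the half-open rectangle ``[top, top+height) x [left, left+width)``."""
    return float(
        integral[top + height, left + width]
        - integral[top, left + width]
        - integral[top + height, left]
        + integral[top, left]
    )


# ---------------------------------------------------------------------------
# Haar-like features
# ---------------------------------------------------------------------------


def template_rects(template: HaarTemplate) -> list[tuple[float, int, int, int, int]]:
    """Decompose a template into weighted rectangles ``(weight, top, left, h, w)``.

    The feature value is ``sum(white) - sum(black)``; white rectangles carry
    weight +1 and black rectangles weight -1.  The two center-surround kinds
    are encoded as a +1 full box plus a double-weighted inner box, which is
    algebraically the same white-minus-black difference.
    """
    t, l, h, w = template.top, template.left, template.height, template.width
    kind = template.kind
    if kind == "edge-horizontal":
        h2 = h // 2
        return [(1.0, t, l, h2, w), (-1.0, t + h2, l, h2, w)]
    if kind == "edge-vertical":
        w2 = w // 2
        return [(1.0, t, l, h, w2), (-1.0, t, l + w2, h, w2)]
    if kind == "line-horizontal":
        h3 = h // 3
        return [
            (1.0, t, l, h3, w),
            (-1.0, t + h3, l, h3, w),
            (1.0, t + 2 * h3, l, h3, w),
        ]
    if kind == "line-vertical":
        w3 = w // 3
        return [
            (1.0, t, l, h, w3),
            (-1.0, t, l + w3, h, w3),
            (1.0, t, l + 2 * w3, h, w3),
        ]
    if kind in ("line-diag1", "line-diag2"):
        h2, w2 = h // 2, w // 2
        sign = 1.0 if kind == "line-diag1" else -1.0
        return [
            (sign, t, l, h2, w2),
            (-sign, t, l + w2, h2, w2),
            (-sign, t + h2, l, h2, w2),
            (sign, t + h2, l + w2, h2, w2),
        ]
    if kind == "center-surround-1":
        # Surround white, inner third black: full box minus twice the inner box.
        h3, w3 = h // 3, w // 3
        return [(1.0, t, l, 3 * h3, 3 * w3), (-2.0, t + h3, l + w3, h3, w3)]
    if kind == "center-surround-2":
        # Inner half white, surround black.
        h2, w2 = h // 2, w // 2
        ti, li = t + (h - h2) // 2, l + (w - w2) // 2
        return [(-1.0, t, l, h, w), (2.0, ti, li, h2, w2)]
    raise ValueError(f"unknown Haar kind {kind!r}")  # pragma: no cover


def haar_feature(integral: np.ndarray, template: HaarTemplate) -> float:
    """Evaluate one Haar-like feature on an integral image."""
    rows, cols = integral.shape[0] - 1, integral.shape[1] - 1
    if (
        template.top < 0
        or template.left < 0
        or template.top + template.height > rows
        or template.left + template.width > cols
    ):
        raise ValueError(
            f"placement {template} outside the {rows}x{cols} patch"
        )
    return sum(
        weight * rect_sum(integral, rt, rl, rh, rw)
        for weight, rt, rl, rh, rw in template_rects(template)
    )


def haar_pool(config: FeatureConfig) -> list[HaarTemplate]:
    """Enumerate the Haar template pool for a window.

    All 8 kinds are placed on a coarse grid: placement boxes of each
    configured scale, strided by ``haar_stride_frac`` of the window in each
    direction.  Box sides are rounded down to even numbers so the edge and
    diagonal kinds split into equal-area halves.
    """
    rows, cols = config.window
    sr = max(1, int(round(rows * config.haar_stride_frac)))
    sc = max(1, int(round(cols * config.haar_stride_frac)))
    pool: list[HaarTemplate] = []
    for scale in config.haar_scales:
        h = max(2, int(rows * scale) // 2 * 2)
        w = max(2, int(cols * scale) // 2 * 2)
        for top in range(0, rows - h + 1, sr):
            for left in range(0, cols - w + 1, sc):
                for kind in HAAR_KINDS:
                    pool.append(HaarTemplate(kind, top, left, h, w))
    return pool


# ---------------------------------------------------------------------------
# Local binary patterns
# ---------------------------------------------------------------------------


def lbp_code(neighborhood: np.ndarray) -> int:
    """8-bit LBP code of a single 3x3 neighborhood.

    Bit ``p`` is set when neighbor ``p`` is >= the center value (ties count
    as set); neighbors are indexed clockwise from the top-left corner.
    """
    block = np.asarray(neighborhood, dtype=np.float64)
    if block.shape != (3, 3):
        raise ValueError("neighborhood must be 3x3")
    center = block[1, 1]
    code = 0
    for p, (dr, dc) in enumerate(LBP_OFFSETS):
        if block[1 + dr, 1 + dc] >= center:
            code |= 1 << p
    return code


def _lbp_code_image(patch: np.ndarray) -> np.ndarray:
    """LBP codes of every interior pixel (vectorized), shape ``(R-2, C-2)``."""
    center = patch[1:-1, 1:-1]
    codes = np.zeros(center.shape, dtype=np.int64)
    for p, (dr, dc) in enumerate(LBP_OFFSETS):
        neighbor = patch[1 + dr : patch.shape[0] - 1 + dr, 1 + dc : patch.shape[1] - 1 + dc]
        codes |= (neighbor >= center).astype(np.int64) << p
    return codes


def _grid_edges(size: int, n: int) -> np.ndarray:
    """Split ``size`` pixels into ``n`` near-equal contiguous runs (edge indices)."""
    base, extra = divmod(size, n)
    sizes = np.full(n, base, dtype=np.int64)
    sizes[:extra] += 1
    return np.concatenate(([0], np.cumsum(sizes)))


def lbp_descriptor(patch: np.ndarray, grid: tuple[int, int] = (4, 4)) -> np.ndarray:
    """Concatenated per-subregion 256-bin LBP histograms.

    The patch is divided into a ``grid`` of subregions; codes are computed
    with full 3x3 neighborhoods taken from the whole patch, so only pixels
    on the outer patch border are skipped.  Each subregion's histogram sums
    to the number of its pixels that are patch-interior.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    gr, gc = grid
    if patch.shape[0] // gr < 3 or patch.shape[1] // gc < 3:
        raise ValueError(f"grid {grid} yields subregions smaller than 3x3")
    codes = _lbp_code_image(patch)
    row_edges = _grid_edges(patch.shape[0], gr)
    col_edges = _grid_edges(patch.shape[1], gc)
    # Subregion index of each interior pixel (interior pixel (i,j) sits at
    # patch coordinates (i+1, j+1)).
    row_region = np.searchsorted(row_edges, np.arange(1, patch.shape[0] - 1), side="right") - 1
    col_region = np.searchsorted(col_edges, np.arange(1, patch.shape[1] - 1), side="right") - 1
    region = row_region[:, None] * gc + col_region[None, :]
    combined = region * 256 + codes
    hist = np.bincount(combined.ravel(), minlength=gr * gc * 256)
    return hist.astype(np.float64)


# ---------------------------------------------------------------------------
# Histogram of oriented gradients
# ---------------------------------------------------------------------------


def hog_gradient(patch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference gradient ``(f_x, f_y)`` of the patch.

    ``f_x`` is the derivative along columns and ``f_y`` along rows; both use
    central differences in the interior and one-sided differences on the
    border.
    """
    patch = np.asarray(patch, dtype=np.float64)
    fy, fx = np.gradient(patch)
    return fx, fy


def hog_descriptor(
    patch: np.ndarray, cell: int = 8, bins: int = 9, block: int = 2
) -> np.ndarray:
    """Block-normalized cell histograms of unsigned gradient orientation.

    The patch is tiled with ``cell x cell`` cells (incomplete trailing cells
    are dropped); each cell accumulates a ``bins``-bin magnitude-weighted
    histogram of the gradient orientation folded to ``[0, pi)``.  Blocks of
    ``block x block`` neighboring cells are L2-normalized (zero blocks stay
    zero) and concatenated.
    """
    patch = np.asarray(patch, dtype=np.float64)
    if patch.ndim != 2:
        raise ValueError("patch must be 2-D")
    if patch.shape[0] < cell or patch.shape[1] < cell:
        raise ValueError(f"patch {patch.shape} smaller than one {cell}x{cell} cell")
    fx, fy = hog_gradient(patch)
    mag = np.hypot(fx, fy)
    theta = np.mod(np.arctan2(fy, fx), np.pi)
    bin_idx = np.minimum((theta / np.pi * bins).astype(np.int64), bins - 1)

    n_cr, n_cc = patch.shape[0] // cell, patch.shape[1] // cell
    mag = mag[: n_cr * cell, : n_cc * cell]
    bin_idx = bin_idx[: n_cr * cell, : n_cc * cell]
    rr = np.arange(n_cr * cell) // cell
    cc = np.arange(n_cc * cell) // cell
    cell_id = rr[:, None] * n_cc + cc[None, :]
    combined = cell_id * bins + bin_idx
    hists = np.bincount(
        combined.ravel(), weights=mag.ravel(), minlength=n_cr * n_cc * bins
    ).reshape(n_cr, n_cc, bins)

    br = max(n_cr - block + 1, 1)
    bc = max(n_cc - block + 1, 1)
    eb_r = min(block, n_cr)
    eb_c = min(block, n_cc)
    out = []
    for i in range(br):
        for j in range(bc):
            v = hists[i : i + eb_r, j : j + eb_c].ravel()
            norm = np.linalg.norm(v)
            out.append(v / norm if norm > 1e-12 else v)
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# Fusion
# ---------------------------------------------------------------------------


class Normalizer:
    """Per-feature z-scoring with statistics learned on a training set.

    Constant features get unit scale so they pass through unchanged;
    z-scoring is monotone per feature, so decision-stump training is
    unaffected while the descriptor blocks end up on comparable scales.
    """

    def __init__(self, mean: np.ndarray | None = None, std: np.ndarray | None = None):
        self.mean = None if mean is None else np.asarray(mean, dtype=np.float64)
        self.std = None if std is None else np.asarray(std, dtype=np.float64)

    def fit(self, X: np.ndarray) -> "Normalizer":
        X = np.asarray(X, dtype=np.float64)
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std < 1e-12] = 1.0
        self.std = std
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean is None or self.std is None:
            raise ValueError("normalizer has not been fitted")
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.std

    def to_dict(self) -> dict:
        return {"mean": self.mean.tolist(), "std": self.std.tolist()}

    @classmethod
    def from_dict(cls, data: dict) -> "Normalizer":
        return cls(np.asarray(data["mean"]), np.asarray(data["std"]))


class FeatureExtractor:
    """Fused Haar+LBP+HOG extraction on the canonical window.

    All index bookkeeping (Haar rectangle corners, LBP subregion map, HOG
    cell map) is precomputed at construction so per-patch extraction is a
    handful of vectorized operations.  Extraction is a pure function of the
    patch: identical patches yield identical vectors.
    """

    def __init__(self, config: FeatureConfig):
        self.config = config
        rows, cols = config.window
        self.templates = haar_pool(config)

        # Flatten every template into corner-lookup arrays.
        r0, c0, r1, c1, weights, ids = [], [], [], [], [], []
        for fid, tpl in enumerate(self.templates):
            for weight, rt, rl, rh, rw in template_rects(tpl):
                r0.append(rt)
                c0.append(rl)
                r1.append(rt + rh)
                c1.append(rl + rw)
                weights.append(weight)
                ids.append(fid)
        self._hr0 = np.asarray(r0)
        self._hc0 = np.asarray(c0)
        self._hr1 = np.asarray(r1)
        self._hc1 = np.asarray(c1)
        self._hw = np.asarray(weights, dtype=np.float64)
        self._hid = np.asarray(ids)
        self.n_haar = len(self.templates)

        gr, gc = config.lbp_grid
        self.n_lbp = gr * gc * 256
        row_edges = _grid_edges(rows, gr)
        col_edges = _grid_edges(cols, gc)
        row_region = np.searchsorted(row_edges, np.arange(1, rows - 1), side="right") - 1
        col_region = np.searchsorted(col_edges, np.arange(1, cols - 1), side="right") - 1
        self._lbp_region = row_region[:, None] * gc + col_region[None, :]

        # HOG geometry (sizes only; the descriptor itself is recomputed per
        # patch by hog_descriptor, which is already vectorized).
        probe = hog_descriptor(
            np.zeros(config.window), config.hog_cell, config.hog_bins, config.hog_block
        )
        self.n_hog = probe.size
        self.n_features = self.n_haar + self.n_lbp + self.n_hog
        self.block_offsets = {
            "haar": 0,
            "lbp": self.n_haar,
            "hog": self.n_haar + self.n_lbp,
        }

    def extract(self, patch: np.ndarray) -> np.ndarray:
        """Raw (un-normalized) fused feature vector of one window-sized patch."""
        patch = np.asarray(patch, dtype=np.float64)
        if patch.shape != tuple(self.config.window):
            raise ValueError(
                f"patch shape {patch.shape} != window {tuple(self.config.window)}"
            )
        ii = compute_integral_image(patch)
        sums = (
            ii[self._hr1, self._hc1]
            - ii[self._hr0, self._hc1]
            - ii[self._hr1, self._hc0]
            + ii[self._hr0, self._hc0]
        )
        f_haar = np.bincount(self._hid, weights=self._hw * sums, minlength=self.n_haar)

        codes = _lbp_code_image(patch)
        combined = self._lbp_region * 256 + codes
        f_lbp = np.bincount(combined.ravel(), minlength=self.n_lbp).astype(np.float64)

        f_hog = hog_descriptor(
            patch, self.config.hog_cell, self.config.hog_bins, self.config.hog_block
        )
        return np.concatenate([f_haar, f_lbp, f_hog])

    def extract_many(self, patches) -> np.ndarray:
        """Stacked raw feature vectors of an iterable of patches."""
        return np.stack([self.extract(p) for p in patches])


def extract_feature_vector(
    patch: np.ndarray, config: FeatureConfig, normalizer: Normalizer | None = None
) -> np.ndarray:
    """One fused feature vector; standardized when a fitted normalizer is given."""
    vec = FeatureExtractor(config).extract(patch)
    if normalizer is not None:
        vec = normalizer.transform(vec[None, :])[0]
    return vec
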