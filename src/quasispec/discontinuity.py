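"""Edge state and pairwise discontinuousness weights between neighbour pixels.

The spatial regularizer couples each pixel to its neighbours with a weight

    G_mn = (1 / L_mn) * prod_k [ E_k = 0 ] + [ E_k != 0 ] (1 - T_b)(1 - D_k)

taken over the raster line joining the two pixels, where ``E`` is a binary
edge map, ``D`` a normalized gradient magnitude and ``T_b`` a bias (default
0.9) controlling how strongly an edge blocks smoothing.  On the first
mean-field iteration edges come from the image itself (first principal
component, central gradients); on later iterations from the current spectral
field via zero-lag cross-correlation of flanking spectra.

By default the edge product runs over the Bresenham points *including* the
two endpoint pixels: with the default neighbourhood radius T_ED = 1 the
strictly-interior point set is always empty, and including the endpoints is
what lets a detected edge actually attenuate couplings into and out of edge
pixels.  Set ``include_endpoints=False`` for the strictly-interior variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import thin

from .spectra import ChannelImage, TransparencyField

__all__ = [
    "GradientField",
    "EdgeState",
    "CouplingWeights",
    "grayscale_first_pc",
    "image_gradient",
    "spectral_gradient",
    "detect_edges",
    "bresenham_line",
    "coupling_weight",
    "neighbor_offsets",
    "build_couplings",
]


@dataclass
class GradientField:
    """Per-pixel discontinuity evidence D_k, normalized to [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("gradient field must be 2-D")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("gradient values must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class EdgeState:
    """Binary edge classification aligned with the gradient it came from.

    ``edges`` is the thinned 1-pixel edge map used in the couplings;
    ``mask`` the hysteresis mask before thinning (useful for diagnostics —
    its size is monotone in the hysteresis thresholds, the skeleton's is
    not).
    """

    edges: np.ndarray
    gradient: GradientField
    iteration: int = 1
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        e = np.asarray(self.edges, dtype=bool)
        if e.shape != self.gradient.shape:
            raise ValueError("edge map must match the gradient geometry")
        self.edges = e
        if self.mask is None:
            self.mask = e.copy()


@dataclass
class CouplingWeights:
    """Sparse symmetric neighbour couplings over the pixel grid.

    ``offsets`` lists the relative neighbour displacements (dr, dc) within
    Euclidean radius T_ED (self excluded, both signs present); ``weights``
    has shape (H, W, len(offsets)) with NaN where the neighbour falls
    outside the image.
    """

    offsets: tuple[tuple[int, int], ...]
    weights: np.ndarray
    t_ed: float = 1.0
    t_b: float = 0.9

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape[:2]

    def neighbors(self, row: int, col: int):
        """Yield ((r, c), G) for every in-bounds neighbour of a pixel."""
        h, w = self.shape
        for j, (dr, dc) in enumerate(self.offsets):
            r, c = row + dr, col + dc
            if 0 <= r < h and 0 <= c < w:
                yield (r, c), float(self.weights[row, col, j])

    def weight(self, m: tuple[int, int], n: tuple[int, int]) -> float:
        dr, dc = n[0] - m[0], n[1] - m[1]
        j = self.offsets.index((dr, dc))
        return float(self.weights[m[0], m[1], j])


# ---------------------------------------------------------------------------
# gradients
# ---------------------------------------------------------------------------

def grayscale_first_pc(image: ChannelImage) -> np.ndarray:
    """Project channel vectors onto their first principal axis.

    Returns a single-channel image scaled to [0, 1]; the principal axis is
    that of the pixel-wise channel covariance, so the projection keeps the
    maximal-variance grayscale summary of the colour data.  A constant image
    has no principal axis and maps to zeros (with a warning).
    """
    if image.n_channels < 2:
        raise ValueError("PCA grayscale needs at least 2 channels")
    x = image.data.reshape(-1, image.n_channels)
    mu = x.mean(axis=0)
    xc = x - mu
    cov = xc.T @ xc / max(1, x.shape[0] - 1)
    if not np.any(cov):
        warnings.warn("constant image: zero covariance, returning zeros")
        return np.zeros(image.data.shape[:2])
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, -1]
    # sign convention: positive correlation with channel mean
    if axis.sum() < 0:
        axis = -axis
    scores = xc @ axis
    lo, hi = scores.min(), scores.max()
    if hi - lo < 1e-300:
        return np.zeros(image.data.shape[:2])
    return ((scores - lo) / (hi - lo)).reshape(image.data.shape[:2])


def image_gradient(gray: np.ndarray) -> GradientField:
    """Central-difference gradient magnitude, max-normalized to [0, 1].

    Interior pixels use central differences; borders one-sided differences.
    Vertical and horizontal components are merged by the Euclidean norm.
    """
    g = np.asarray(gray, dtype=float)
    gy, gx = np.gradient(g)
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak > 0:
        mag = mag / peak
    return GradientField(mag)


def _flank_dissimilarity(field_data: np.ndarray, axis: int,
                         complement: bool = True) -> np.ndarray:
    """Per-axis spectral discontinuity from zero-lag cross-correlation.

    For each pixel k the spectra of the two flanking pixels along ``axis``
    are compared by their normalized zero-lag cross-correlation rho (cosine
    of the spectra).  ``complement=True`` converts the similarity into a
    dissimilarity (1 - rho) / 2 in [0, 1]; zero-norm spectra count as fully
    similar (no evidence of a discontinuity).  Borders get 0.
    """
    prev = np.roll(field_data, 1, axis=axis)
    nxt = np.roll(field_data, -1, axis=axis)
    num = np.sum(prev * nxt, axis=-1)
    norm = np.linalg.norm(prev, axis=-1) * np.linalg.norm(nxt, axis=-1)
    rho = np.ones_like(num)
    ok = norm > 0
    rho[ok] = num[ok] / norm[ok]
    rho = np.clip(rho, -1.0, 1.0)
    d = (1.0 - rho) / 2.0 if complement else (1.0 + rho) / 2.0
    # flanks undefined at the two borders along this axis
    sl = [slice(None)] * d.ndim
    sl[axis] = 0
    d[tuple(sl)] = 0.0
    sl[axis] = -1
    d[tuple(sl)] = 0.0
    return d


def spectral_gradient(field: TransparencyField, axis: int | None = None,
                      complement: bool = True) -> GradientField:
    """Discontinuity evidence from the current spectral field.

    Zero-lag cross-correlation of the flanking spectra along each image axis,
    mapped to a dissimilarity, merged across axes by the Euclidean norm and
    max-normalized.  ``axis`` restricts the computation to one axis (0 =
    vertical, 1 = horizontal); ``complement=False`` uses the raw correlation
    direction instead of its complement.
    """
    data = field.data
    if axis is not None:
        d = _flank_dissimilarity(data, axis, complement)
    else:
        dy = _flank_dissimilarity(data, 0, complement)
        dx = _flank_dissimilarity(data, 1, complement)
        d = np.hypot(dy, dx)
    d[d < 1e-9] = 0.0          # numerically-uniform flanks carry no evidence
    peak = d.max()
    if peak > 0:
        d = d / peak
    return GradientField(np.clip(d, 0.0, 1.0))


# ---------------------------------------------------------------------------
# edges
# ---------------------------------------------------------------------------

def detect_edges(grad: GradientField, sigma: float = 0.5,
                 high_quantile: float = 0.9, low_ratio: float = 0.4,
                 iteration: int = 1) -> EdgeState:
    """Canny-style edge classification of a gradient matrix.

    The input is already a gradient magnitude, so the Canny stages are
    applied to it directly: 2-D Gaussian smoothing (sigma = 0.5 by
    default), double-threshold hysteresis, and thinning of the surviving
    mask to 1-pixel lines.  Hysteresis thresholds are auto-derived: high at
    ``high_quantile`` of the nonzero smoothed values, low =
    ``low_ratio`` * high.
    """
    g = grad.values
    if not np.any(g):
        return EdgeState(np.zeros(g.shape, dtype=bool), grad, iteration)
    smoothed = ndimage.gaussian_filter(g, sigma)
    nz = smoothed[smoothed > 0]
    high = float(np.percentile(nz, 100.0 * high_quantile)) if nz.size else 0.0
    low = low_ratio * high
    strong = smoothed >= high
    weak = smoothed >= low
    labels, _ = ndimage.label(weak, structure=np.ones((3, 3)))
    seeded = np.unique(labels[strong])
    mask = weak & np.isin(labels, seeded[seeded > 0])
    edges = thin(mask)
    return EdgeState(edges, grad, iteration, mask=mask)


# ---------------------------------------------------------------------------
# couplings
# ---------------------------------------------------------------------------

def bresenham_line(m: tuple[int, int], n: tuple[int, int]
                   ) -> list[tuple[int, int]]:
    """Intermediate raster points strictly between two pixels.

    Endpoints are canonically ordered (lexicographically) before
    rasterization so the result is symmetric under endpoint swap, then the
    endpoints themselves are dropped.  8-adjacent pixels yield an empty list.
    """
    if tuple(m) == tuple(n):
        raise ValueError("endpoints must differ")
    a, b = sorted((tuple(int(v) for v in m), tuple(int(v) for v in n)))
    r0, c0 = a
    r1, c1 = b
    dr, dc = abs(r1 - r0), abs(c1 - c0)
    sr = 1 if r1 >= r0 else -1
    sc = 1 if c1 >= c0 else -1
    err = dr - dc
    pts: list[tuple[int, int]] = []
    r, c = r0, c0
    while (r, c) != (r1, c1):
        if (r, c) != (r0, c0):
            pts.append((r, c))
        e2 = 2 * err
        if e2 > -dc:
            err -= dc
            r += sr
        if e2 < dr:
            err += dr
            c += sc
    return pts


def _edge_factor(k: tuple[int, int], edges: np.ndarray,
                 grad: np.ndarray, t_b: float) -> float:
    if edges[k]:
        return (1.0 - t_b) * (1.0 - grad[k])
    return 1.0


def coupling_weight(m: tuple[int, int], n: tuple[int, int],
                    edges: EdgeState, grad: GradientField | None = None,
                    t_b: float = 0.9,
                    include_endpoints: bool = True) -> float:
    """Discontinuousness-aware coupling G_mn between two pixels.

    ``G_mn = (1/L_mn) * prod_k f(k)`` over the raster line joining m and n,
    with ``f(k) = 1`` off edges and ``(1 - t_b)(1 - D_k)`` on edge pixels;
    ``L_mn`` is the Euclidean distance.  ``include_endpoints`` extends the
    product to m and n themselves (the default; see module docstring).
    """
    g = (grad or edges.gradient).values
    e = edges.edges
    l_mn = float(np.hypot(m[0] - n[0], m[1] - n[1]))
    pts = bresenham_line(m, n)
    if include_endpoints:
        pts = [tuple(m), *pts, tuple(n)]
    prod = 1.0
    for k in pts:
        prod *= _edge_factor(k, e, g, t_b)
    return prod / l_mn


def neighbor_offsets(t_ed: float) -> tuple[tuple[int, int], ...]:
    """Relative displacements within Euclidean radius t_ed (self excluded)."""
    r = int(np.floor(t_ed))
    offs = []
    for dr in range(-r, r + 1):
        for dc in range(-r, r + 1):
            if (dr, dc) != (0, 0) and np.hypot(dr, dc) <= t_ed + 1e-12:
                offs.append((dr, dc))
    return tuple(offs)


def build_couplings(shape: tuple[int, int], edges: EdgeState,
                    grad: GradientField | None = None,
                    t_ed: float = 1.0, t_b: float = 0.9,
                    include_endpoints: bool = True) -> CouplingWeights:
    """All neighbour couplings of an image, vectorized per offset.

    For a fixed displacement the Bresenham pattern of intermediate points is
    the same for every pixel pair, so the product in G_mn reduces to shifted
    multiplications of a per-pixel edge factor map.
    """
    h, w = shape
    g = (grad or edges.gradient).values
    e = edges.edges
    factor = np.where(e, (1.0 - t_b) * (1.0 - g), 1.0)
    offsets = neighbor_offsets(t_ed)
    weights = np.full((h, w, len(offsets)), np.nan)
    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for j, (dr, dc) in enumerate(offsets):
        l_mn = float(np.hypot(dr, dc))
        # canonical-order rasterization: pattern relative to the lexicographic
        # smaller endpoint, which is m when (dr, dc) > (0, 0)
        if (dr, dc) > (0, 0):
            rel = bresenham_line((0, 0), (dr, dc))
            anchor = "m"
        else:
            rel = bresenham_line((0, 0), (-dr, -dc))
            anchor = "n"
        rr = rows + dr
        cc = cols + dc
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        prod = np.ones((h, w))
        if include_endpoints:
            prod *= factor
            shifted = np.full((h, w), np.nan)
            shifted[inside] = factor[np.clip(rr, 0, h - 1),
                                     np.clip(cc, 0, w - 1)][inside]
            prod = prod * shifted
        else:
            shifted = np.where(inside, 1.0, np.nan)
            prod = prod * shifted
        for (pr, pc) in rel:
            if anchor == "n":
                pr, pc = dr + pr, dc + pc
            kr = rows + pr
            kc = cols + pc
            kin = (kr >= 0) & (kr < h) & (kc >= 0) & (kc < w)
            fk = np.where(kin, factor[np.clip(kr, 0, h - 1),
                                      np.clip(kc, 0, w - 1)], 1.0)
            prod = prod * fk
        weights[:, :, j] = prod / l_mn
    return CouplingWeights(offsets, weights, t_ed=t_ed, t_b=t_b)
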