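"""Unsupervised evaluation of spectral cubes.

Clustering uses spherical k-means: vectors are L2-normalized, assignment is
by maximal cosine similarity, and each centroid is the normalized mean of
its members.  The cosine metric is the natural choice for transparency
spectra because sample thickness scales spectral magnitude but not shape.
Cluster-count quality is judged by the gap statistic (within-cluster cosine
dispersion against uniform reference draws over the data bounding box), and
"digital staining" projects spectra onto a few dimensionality-reduction
components for false-colour display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from sklearn.decomposition import NMF, PCA, FactorAnalysis

from .spectra import Spectrum, TransparencyField, WavelengthGrid

__all__ = ["ClusterResult", "GapCurve", "cluster_spectra", "gap_statistic",
           "select_k", "digital_stain", "class_mean_spectra",
           "cube_vectors"]


@dataclass
class ClusterResult:
    """Spherical k-means partition of pixel spectra."""

    labels: np.ndarray              # flat labels, -1 where excluded
    centroids: np.ndarray           # (k, w), unit norm
    k: int
    inertia: float                  # sum of (1 - cos) to own centroid
    metric: str = "cosine"
    seed: int = 0

    def label_image(self, shape: tuple[int, int]) -> np.ndarray:
        return self.labels.reshape(shape)


@dataclass
class GapCurve:
    """Gap statistic over candidate cluster counts."""

    ks: np.ndarray
    gap: np.ndarray
    se: np.ndarray                  # standard error sqrt(1 + 1/B) * sd
    log_w: np.ndarray
    b: int
    seed: int = 0

    def best_k(self) -> int:
        """First-max rule: smallest k with Gap(k) >= Gap(k+1) - se(k+1)."""
        for i in range(len(self.ks) - 1):
            if self.gap[i] >= self.gap[i + 1] - self.se[i + 1]:
                return int(self.ks[i])
        return int(self.ks[-1])


def _normalize_rows(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    norms = np.linalg.norm(x, axis=1)
    ok = norms > 0
    xn = np.zeros_like(x, dtype=float)
    xn[ok] = x[ok] / norms[ok, None]
    return xn, ok


def _kmeanspp(xn: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding under cosine distance d = 1 - x.c."""
    n = xn.shape[0]
    centers = np.empty((k, xn.shape[1]))
    centers[0] = xn[rng.integers(n)]
    d = 1.0 - xn @ centers[0]
    for j in range(1, k):
        p = np.clip(d, 0.0, None)
        tot = p.sum()
        if tot <= 0:
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=p / tot)
        centers[j] = xn[idx]
        d = np.minimum(d, 1.0 - xn @ centers[j])
    return centers


def _spherical_kmeans_once(xn: np.ndarray, k: int, rng: np.random.Generator,
                           max_iter: int = 100, tol: float = 1e-7
                           ) -> tuple[np.ndarray, np.ndarray, float]:
    centers = _kmeanspp(xn, k, rng)
    prev = np.inf
    for _ in range(max_iter):
        sims = xn @ centers.T
        labels = np.argmax(sims, axis=1)
        inertia = float(np.sum(1.0 - sims[np.arange(len(xn)), labels]))
        for j in range(k):
            members = xn[labels == j]
            if len(members) == 0:
                # re-seed an empty cluster at the worst-fit point
                worst = int(np.argmin(sims[np.arange(len(xn)), labels]))
                centers[j] = xn[worst]
                continue
            m = members.sum(axis=0)
            norm = np.linalg.norm(m)
            centers[j] = m / norm if norm > 0 else centers[j]
        if prev - inertia < tol:
            break
        prev = inertia
    sims = xn @ centers.T
    labels = np.argmax(sims, axis=1)
    inertia = float(np.sum(1.0 - sims[np.arange(len(xn)), labels]))
    return labels, centers, inertia


def cluster_spectra(vectors: np.ndarray, k: int, metric: str = "cosine",
                    seed: int = 0, n_restarts: int = 5) -> ClusterResult:
    """Spherical k-means over per-pixel spectra (or raw channel vectors).

    Zero-norm vectors are excluded (label -1).  The best of ``n_restarts``
    k-means++ starts is kept; ties break toward the earliest restart, so the
    result is deterministic per seed.
    """
    if metric != "cosine":
        raise ValueError("only the cosine metric is supported")
    x = np.asarray(vectors, dtype=float)
    xn, ok = _normalize_rows(x)
    if not np.all(ok):
        warnings.warn(f"excluding {np.sum(~ok)} zero-norm vectors")
    xv = xn[ok]
    if k < 1 or len(np.unique(xv, axis=0)) < k:
        raise ValueError("need at least k distinct non-degenerate vectors")
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(r,)))
        labels, centers, inertia = _spherical_kmeans_once(xv, k, rng)
        if best is None or inertia < best[2] - 1e-12:
            best = (labels, centers, inertia)
    labels_v, centers, inertia = best
    labels = np.full(len(x), -1, dtype=int)
    labels[ok] = labels_v
    return ClusterResult(labels, centers, k, inertia, metric, seed)


def _within_dispersion(xn: np.ndarray, labels: np.ndarray, k: int) -> float:
    """W_k = sum_r (1 / 2 n_r) sum_{i,i' in r} (1 - x_i . x_i').

    For unit vectors the pairwise sum collapses to n_r^2 - ||sum x||^2,
    so W_k is O(n) to evaluate.
    """
    w = 0.0
    for j in range(k):
        members = xn[labels == j]
        n_r = len(members)
        if n_r < 2:
            continue
        s = members.sum(axis=0)
        w += (n_r ** 2 - float(s @ s)) / (2.0 * n_r)
    return w


def gap_statistic(vectors: np.ndarray, ks, b: int = 20,
                  metric: str = "cosine", seed: int = 0) -> GapCurve:
    """Gap statistic with uniform bounding-box references.

    Gap(k) = mean_b log W*_kb - log W_k, with W the within-cluster cosine
    dispersion; the standard error is sd_b(log W*) * sqrt(1 + 1/B).
    """
    if b < 1:
        raise ValueError("B must be >= 1")
    x = np.asarray(vectors, dtype=float)
    xn, ok = _normalize_rows(x)
    xv = xn[ok]
    lo = x[ok].min(axis=0)
    hi = x[ok].max(axis=0)
    ks = np.asarray(list(ks), dtype=int)
    log_w = np.empty(len(ks))
    gap = np.empty(len(ks))
    se = np.empty(len(ks))
    ref_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(999,)))
    refs = [ref_rng.uniform(lo, hi, size=x[ok].shape) for _ in range(b)]
    refs_n = [_normalize_rows(r)[0] for r in refs]
    for i, k in enumerate(ks):
        res = cluster_spectra(x[ok], k, metric, seed=seed, n_restarts=3)
        log_w[i] = np.log(max(_within_dispersion(xv, res.labels, k), 1e-300))
        log_w_ref = np.empty(b)
        for j, rn in enumerate(refs_n):
            r_res = cluster_spectra(refs[j], k, metric,
                                    seed=seed + 1 + j, n_restarts=1)
            log_w_ref[j] = np.log(
                max(_within_dispersion(rn, r_res.labels, k), 1e-300))
        gap[i] = log_w_ref.mean() - log_w[i]
        se[i] = np.std(log_w_ref) * np.sqrt(1.0 + 1.0 / b)
    return GapCurve(ks, gap, se, log_w, b, seed)


def select_k(curve: GapCurve) -> int:
    return curve.best_k()


def cube_vectors(field: TransparencyField) -> tuple[np.ndarray, np.ndarray]:
    """Valid-pixel spectra as an (n, w) matrix plus the flat validity mask."""
    flat = field.flat()
    valid = field.valid.reshape(-1)
    return flat[valid], valid


def digital_stain(field: TransparencyField, method: str = "pca",
                  n_components: int = 3, seed: int = 0) -> np.ndarray:
    """False-colour image from a low-dimensional spectral projection.

    Spectra are projected onto ``n_components`` PCA / factor-analysis / NMF
    components; each component is min-max scaled to [0, 1] and mapped to a
    display channel.  Invalid pixels come out black.
    """
    vectors, valid = cube_vectors(field)
    if method == "pca":
        model = PCA(n_components=n_components, random_state=seed)
    elif method == "factor_analysis":
        model = FactorAnalysis(n_components=n_components, random_state=seed)
    elif method == "nmf":
        if np.any(vectors < 0):
            raise ValueError("NMF requires non-negative data")
        model = NMF(n_components=n_components, random_state=seed,
                    init="nndsvda", max_iter=500)
    else:
        raise ValueError(f"unknown staining method: {method!r}")
    comps = model.fit_transform(vectors)
    lo = comps.min(axis=0)
    span = comps.max(axis=0) - lo
    # degenerate components (numerical noise on rank-deficient data) must
    # not be min-max amplified into full-range channels
    dead = span < 1e-6 * max(span.max(), 1e-300)
    span[span == 0] = 1.0
    scaled = (comps - lo) / span
    scaled[:, dead] = 0.0
    out = np.zeros((len(valid), n_components))
    out[valid] = scaled
    return out.reshape(field.height, field.width, n_components)


def class_mean_spectra(result: ClusterResult, field: TransparencyField
                       ) -> list[Spectrum]:
    """Arithmetic mean spectrum of each cluster, on the working grid.

    Empty classes are omitted with a warning.
    """
    flat = field.flat()
    out = []
    for j in range(result.k):
        members = flat[result.labels == j]
        if len(members) == 0:
            warnings.warn(f"class {j} is empty; omitted")
            continue
        out.append(Spectrum(field.grid, members.mean(axis=0),
                            name=f"class_{j}"))
    return out
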