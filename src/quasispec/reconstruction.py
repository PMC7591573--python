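"""Per-pixel loss, its CMA-ES minimization, and the mean-field outer loop.

Each pixel m carries an unknown transparency spectrum t in [0, 1]^w.  Its
loss combines an exponential data-fit against the observed channel
intensities with an edge-aware quadratic coupling to the neighbours'
spectra:

    F_m = sum_c exp(|integral(L_c t) - I_mc|) - C
          + (1/N) sum_{n in N_m} G_mn sum_i (t_i - T_n,i)^2

The field is solved by mean-field iteration: neighbour spectra are frozen
from the previous sweep (Jacobi style, so the result is independent of the
sweep order), every pixel is minimized by CMA-ES down to the current loss
tolerance, and the tolerance decreases linearly over the first 10 outer
iterations before staying constant.  The loop stops when the relative change
of the mean per-pixel cost drops below 0.01; 20-40 outer iterations are a
typical budget for real images, small phantoms converge earlier.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import cmaes
from .discontinuity import (CouplingWeights, EdgeState, build_couplings,
                            detect_edges, grayscale_first_pc, image_gradient,
                            spectral_gradient)
from .spectra import (ChannelImage, EffectiveLight, PixelSpectrum,
                      TransparencyField, WavelengthGrid)

__all__ = ["SolverConfig", "IterationTrace", "pixel_loss", "solve_pixel",
           "initialize_field", "run_reconstruction"]


@dataclass
class SolverConfig:
    """All tunables of the mean-field reconstruction loop.

    Tolerances are values of the per-pixel loss F_m (dimensionless, O(1)
    with intensities normalized to [0, 1]).  The schedule decreases linearly
    from ``tol_initial`` to ``tol_final`` over ``tol_horizon`` outer
    iterations and is constant afterwards.
    """

    max_iterations: int = 40
    tol_initial: float = 0.5          # 10 x tol_final by default
    tol_final: float = 0.05
    tol_horizon: int = 10
    change_threshold: float = 0.01    # relative change of mean cost
    sigma0: float = 0.15              # CMA-ES initial step in [0,1] units
    popsize: int | None = None        # None -> 4 + 3 ln w
    budget: int = 500                 # CMA-ES evaluations per pixel per sweep
    seed: int = 0
    t_ed: float = 1.0                 # neighbourhood Euclidean radius
    t_b: float = 0.9                  # edge bias in G_mn
    include_endpoints: bool = True    # edge product over B_mn with endpoints
    complement_correlation: bool = True  # spectral D_k = (1 - rho)/2
    white_level: Sequence[float] | None = None  # per-channel, in [0,1] units
    bright_percentile: float | None = None  # optional pre-mask of bright px
    quadrature: str = "simpson"

    def __post_init__(self) -> None:
        if self.tol_initial <= 0 or self.tol_final <= 0:
            raise ValueError("tolerances must be positive")
        if self.budget < 1:
            raise ValueError("evaluation budget must be >= 1")

    def tolerance(self, iteration: int) -> float:
        """Loss tolerance for a 1-based outer iteration."""
        if iteration >= self.tol_horizon:
            return self.tol_final
        frac = (iteration - 1) / (self.tol_horizon - 1)
        return self.tol_initial + frac * (self.tol_final - self.tol_initial)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["white_level"] is not None:
            d["white_level"] = [float(v) for v in d["white_level"]]
        return d


@dataclass
class IterationTrace:
    """Per-iteration diagnostics of the outer loop."""

    mean_cost: list[float] = field(default_factory=list)
    variation_coefficient: list[float] = field(default_factory=list)
    tolerance: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def n_iterations(self) -> int:
        return len(self.mean_cost)

    def record(self, costs: np.ndarray, tol: float) -> None:
        m = float(np.mean(costs))
        self.mean_cost.append(m)
        self.variation_coefficient.append(
            float(np.std(costs) / m) if m > 0 else 0.0)
        self.tolerance.append(float(tol))

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({
            "iteration": np.arange(1, self.n_iterations + 1),
            "mean_cost": self.mean_cost,
            "variation_coefficient": self.variation_coefficient,
            "tolerance": self.tolerance,
        })


# ---------------------------------------------------------------------------
# per-pixel loss
# ---------------------------------------------------------------------------

def _batch_loss(T: np.ndarray, kernel: np.ndarray, obs: np.ndarray,
                nbr_spectra: np.ndarray, nbr_weights: np.ndarray
                ) -> np.ndarray:
    """Vectorized F_m for a population of candidate spectra T (m, w)."""
    pred = T @ kernel.T                      # (m, C)
    fid = np.sum(np.exp(np.abs(pred - obs)), axis=1) - obs.size
    if nbr_spectra.size:
        diff = T[:, None, :] - nbr_spectra[None, :, :]   # (m, k, w)
        sm = np.einsum("mkw,k->m", diff * diff, nbr_weights)
        sm /= nbr_spectra.shape[0]
    else:
        sm = 0.0
    return fid + sm


def pixel_loss(m: tuple[int, int], t: PixelSpectrum,
               field_prev: TransparencyField, light: EffectiveLight,
               observed: Sequence[float], couplings: CouplingWeights,
               method: str = "simpson") -> float:
    """Loss F_m of candidate spectrum ``t`` at pixel ``m``.

    Neighbour spectra are read from ``field_prev`` (the previous mean-field
    sweep); ``observed`` are the pixel's channel intensities on the same
    scale as ``integral(L_c)``.
    """
    if t.grid != field_prev.grid or t.grid != light.grid:
        raise ValueError("grids do not match")
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (light.n_channels,):
        raise ValueError("observed must have one intensity per channel")
    kernel = light.values * light.grid.quadrature_weights(method)
    nbrs, g = [], []
    for (r, c), w in couplings.neighbors(*m):
        nbrs.append(field_prev.data[r, c])
        g.append(w)
    nbr_spectra = np.asarray(nbrs) if nbrs else np.empty((0, t.grid.w))
    nbr_weights = np.asarray(g) if g else np.empty(0)
    return float(_batch_loss(t.values[None, :], kernel, obs,
                             nbr_spectra, nbr_weights)[0])


def solve_pixel(init: PixelSpectrum, kernel: np.ndarray, observed: np.ndarray,
                nbr_spectra: np.ndarray, nbr_weights: np.ndarray,
                tolerance: float, config: SolverConfig,
                seed: int) -> tuple[np.ndarray, float, int, bool]:
    """Minimize one pixel's loss by CMA-ES down to ``tolerance``.

    Returns (spectrum, loss, n_evals, reached).  If the initial spectrum
    already satisfies the tolerance it is returned untouched with zero
    evaluations; otherwise the best candidate found within the budget is
    returned (never worse than the initial one) with ``reached`` saying
    whether the tolerance was met.
    """
    x0 = init.values
    f0 = float(_batch_loss(x0[None, :], kernel, observed,
                           nbr_spectra, nbr_weights)[0])
    if f0 <= tolerance:
        return x0.copy(), f0, 0, True

    def objective(X: np.ndarray) -> np.ndarray:
        return _batch_loss(X, kernel, observed, nbr_spectra, nbr_weights)

    res = cmaes.minimize(objective, x0, config.sigma0, config.budget,
                         target=tolerance, seed=seed,
                         popsize=config.popsize, bounds=(0.0, 1.0))
    if res.fun < f0:  # accept only if better than the warm start
        return res.x, res.fun, res.n_evals, res.reached
    return x0.copy(), f0, res.n_evals, False


# ---------------------------------------------------------------------------
# outer loop
# ---------------------------------------------------------------------------

def _white_level(intensities: np.ndarray, valid: np.ndarray,
                 config: SolverConfig) -> np.ndarray:
    if config.white_level is not None:
        white = np.asarray(config.white_level, dtype=float)
        if white.shape != (intensities.shape[2],):
            raise ValueError("white_level needs one value per channel")
        return white
    flat = intensities[valid]
    return np.percentile(flat, 99, axis=0)


def initialize_field(image: ChannelImage, light: EffectiveLight,
                     white: Sequence[float] | None = None
                     ) -> TransparencyField:
    """Flat-spectrum initial guess from the channel-mean brightness ratio.

    Each pixel starts at t_i = alpha with alpha = mean_c(I_c / white_c),
    clipped to [0, 1] — the transparency of a spectrally neutral medium that
    would produce the observed overall brightness.
    """
    intensities = image.normalized()
    if white is None:
        white = light.integrals()
    white = np.asarray(white, dtype=float)
    alpha = np.clip(np.mean(intensities / white, axis=2), 0.0, 1.0)
    data = np.repeat(alpha[:, :, None], light.grid.w, axis=2)
    return TransparencyField(light.grid, data, valid=~image.saturated)


def _pixel_seed(seed: int, iteration: int, pixel: int) -> np.random.Generator:
    # deterministic, collision-free stream per (seed, iteration, pixel)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(iteration, pixel)))


def run_reconstruction(image: ChannelImage, light: EffectiveLight,
                       config: SolverConfig | None = None,
                       ) -> tuple[TransparencyField, IterationTrace,
                                  np.ndarray, EdgeState]:
    """Full mean-field reconstruction of a transparency field.

    Returns ``(field, trace, costs, edges)`` where ``costs`` holds the final
    per-pixel loss (NaN at masked pixels) and ``edges`` the last edge state.
    Saturated pixels are excluded from optimization and marked invalid in
    the output field.
    """
    config = config or SolverConfig()
    grid = light.grid
    intensities = image.normalized()
    h, w_img, n_ch = intensities.shape

    valid = ~image.saturated
    if config.bright_percentile is not None:
        thresh = np.percentile(intensities[valid].max(axis=1),
                               config.bright_percentile)
        valid &= ~(intensities.max(axis=2) > thresh)

    white = _white_level(intensities, valid, config)
    light_scaled = light.scaled_to_white(white)
    kernel = light_scaled.values * grid.quadrature_weights(config.quadrature)

    field_obj = initialize_field(image, light_scaled, white=white)
    field_obj.valid = valid.copy()
    field = field_obj.data
    n_px = h * w_img
    flat_obs = intensities.reshape(n_px, n_ch)
    flat_valid = valid.reshape(n_px)

    trace = IterationTrace()
    costs = np.full(n_px, np.nan)
    edges: EdgeState | None = None
    prev_mean: float | None = None

    for it in range(1, config.max_iterations + 1):
        if it == 1:
            gray = grayscale_first_pc(
                ChannelImage(intensities, bit_depth=1,
                             channels=image.channels))
            grad = image_gradient(gray)
        else:
            grad = spectral_gradient(
                TransparencyField(grid, field, valid=valid),
                complement=config.complement_correlation)
        edges = detect_edges(grad, iteration=it)
        couplings = build_couplings((h, w_img), edges, grad,
                                    t_ed=config.t_ed, t_b=config.t_b,
                                    include_endpoints=config.include_endpoints)
        tol = config.tolerance(it)

        new_field = field.copy()
        flat_field = field.reshape(n_px, -1)
        off = couplings.offsets
        gw = couplings.weights.reshape(n_px, len(off))
        for p in range(n_px):
            if not flat_valid[p]:
                continue
            r, c = divmod(p, w_img)
            nbrs, wts = [], []
            for j, (dr, dc) in enumerate(off):
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w_img and valid[rr, cc]:
                    nbrs.append(flat_field[rr * w_img + cc])
                    wts.append(gw[p, j])
            nbr_spectra = (np.asarray(nbrs) if nbrs
                           else np.empty((0, grid.w)))
            nbr_weights = np.asarray(wts) if wts else np.empty(0)
            init = PixelSpectrum(grid, flat_field[p])
            rng = _pixel_seed(config.seed, it, p)
            x0 = init.values
            f0 = float(_batch_loss(x0[None, :], kernel, flat_obs[p],
                                   nbr_spectra, nbr_weights)[0])
            if f0 <= tol:
                costs[p] = f0
                continue

            def objective(X: np.ndarray) -> np.ndarray:
                return _batch_loss(X, kernel, flat_obs[p],
                                   nbr_spectra, nbr_weights)

            res = cmaes.minimize(objective, x0, config.sigma0,
                                 config.budget, target=tol, seed=rng,
                                 popsize=config.popsize, bounds=(0.0, 1.0))
            if res.fun < f0:
                new_field.reshape(n_px, -1)[p] = res.x
                costs[p] = res.fun
            else:
                costs[p] = f0
        field = new_field

        valid_costs = costs[flat_valid]
        trace.record(valid_costs, tol)
        mean_cost = trace.mean_cost[-1]
        # the stopping rule belongs to the constant-tolerance phase: while
        # the tolerance still decreases, cost changes track the schedule
        if (it > config.tol_horizon
                and prev_mean is not None
                and abs(mean_cost - prev_mean) / max(prev_mean, 1e-12)
                < config.change_threshold):
            trace.converged = True
            break
        prev_mean = mean_cost

    out = TransparencyField(grid, field, valid=valid)
    cost_map = costs.reshape(h, w_img)
    assert edges is not None
    return out, trace, cost_map, edges
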