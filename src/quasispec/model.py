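"""Model / Results front-end for the quasi-spectral reconstruction.

`QuasiSpectralModel` bundles the data (a raw channel image and the
effective incoming light) with the solver configuration; `fit()` runs the
mean-field reconstruction and returns a `QuasiSpectralResults` object that
carries the spectral cube, the iteration trace, per-pixel diagnostics, and
convenience methods for rendering, clustering and staining.

    >>> model = QuasiSpectralModel(image, light)
    >>> res = model.fit(seed=42)
    >>> print(res.summary())
    >>> color = res.render(temperature=5800)
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import analysis, rendering
from .discontinuity import EdgeState
from .reconstruction import (IterationTrace, SolverConfig, run_reconstruction)
from .spectra import (ChannelImage, EffectiveLight, TransparencyField,
                      forward_image)

__all__ = ["QuasiSpectralModel", "QuasiSpectralResults"]


class QuasiSpectralModel:
    """Per-pixel transparency-spectrum model of a raw bright-field image.

    Parameters
    ----------
    image : ChannelImage
        Raw (unprocessed) sensor intensities, 8-16 bit.
    light : EffectiveLight
        Per-channel effective illumination L_c = S * F_c on the working
        wavelength grid; absolute scale is irrelevant (the solver rescales
        to the white level).
    config : SolverConfig, optional
        Solver tunables; defaults follow the method's stated operating
        point (T_ED = 1, T_b = 0.9, linear tolerance decrease over 10
        iterations, stopping change 0.01).
    """

    def __init__(self, image: ChannelImage, light: EffectiveLight,
                 config: SolverConfig | None = None):
        if image.n_channels != light.n_channels:
            raise ValueError("image and light disagree on channel count")
        self.image = image
        self.light = light
        self.config = config or SolverConfig()

    @classmethod
    def from_arrays(cls, intensities: np.ndarray, wavelengths: np.ndarray,
                    light_values: np.ndarray, bit_depth: int = 16,
                    **config_kwargs) -> "QuasiSpectralModel":
        """Build a model from plain arrays (intensities, grid, light)."""
        from .spectra import WavelengthGrid
        grid = WavelengthGrid(np.asarray(wavelengths, dtype=float))
        image = ChannelImage(np.asarray(intensities, dtype=float),
                             bit_depth=bit_depth)
        light = EffectiveLight(grid, np.asarray(light_values, dtype=float))
        cfg = SolverConfig(**config_kwargs) if config_kwargs else None
        return cls(image, light, cfg)

    def fit(self, seed: int | None = None, **overrides
            ) -> "QuasiSpectralResults":
        """Run the mean-field reconstruction loop.

        ``seed`` and any SolverConfig field can be overridden per fit; the
        run is fully deterministic given the resulting configuration.
        """
        cfg = self.config
        if seed is not None:
            overrides["seed"] = seed
        if overrides:
            cfg = replace(cfg, **overrides)
        field, trace, costs, edges = run_reconstruction(
            self.image, self.light, cfg)
        return QuasiSpectralResults(self, cfg, field, trace, costs, edges)


class QuasiSpectralResults:
    """Fitted transparency cube plus diagnostics."""

    def __init__(self, model: QuasiSpectralModel, config: SolverConfig,
                 field: TransparencyField, trace: IterationTrace,
                 costs: np.ndarray, edges: EdgeState):
        self.model = model
        self.config = config
        self.field = field
        self.trace = trace
        self.costs = costs          # (H, W) final per-pixel loss, NaN masked
        self.edges = edges

    # -- scalar diagnostics -------------------------------------------------

    @property
    def n_iterations(self) -> int:
        return self.trace.n_iterations

    @property
    def converged(self) -> bool:
        return self.trace.converged

    @property
    def mean_cost(self) -> float:
        return self.trace.mean_cost[-1]

    def reprojection(self) -> ChannelImage:
        """Cube pushed back through the forward model, in [0, 1] units."""
        white = self._white()
        light = self.model.light.scaled_to_white(white)
        return forward_image(self.field, light)

    def _white(self) -> np.ndarray:
        from .reconstruction import _white_level
        return _white_level(self.model.image.normalized(), self.field.valid,
                            self.config)

    def reprojection_error(self, exclude_edges: bool = True) -> np.ndarray:
        """Mean per-channel |reprojected - observed| over trusted pixels."""
        obs = self.model.image.normalized()
        pred = self.reprojection().data
        mask = self.field.valid.copy()
        if exclude_edges:
            mask &= ~self.edges.edges
        return np.abs(pred - obs)[mask].mean(axis=0)

    def anomalous_pixels(self, percentile: float = 99.9) -> np.ndarray:
        """Pixels whose converged cost exceeds a percentile of the rest.

        Model-violating objects (micro-lenses: bubbles, vacuoles) cannot
        satisfy the transparency bound and keep an abnormally high cost.
        """
        c = self.costs
        ok = np.isfinite(c)
        thresh = np.percentile(c[ok], percentile)
        return ok & (c > thresh)

    # -- downstream conveniences -------------------------------------------

    def render(self, illuminant: rendering.Illuminant | None = None,
               temperature: float = 5800.0) -> rendering.ColorImage:
        if illuminant is None:
            illuminant = rendering.planck_spectrum(temperature,
                                                   self.field.grid)
        return rendering.render(self.field, illuminant)

    def cluster(self, k: int, seed: int = 0) -> analysis.ClusterResult:
        vectors, valid = analysis.cube_vectors(self.field)
        res = analysis.cluster_spectra(vectors, k, seed=seed)
        labels = np.full(valid.shape, -1, dtype=int)
        labels[valid] = res.labels
        res.labels = labels
        return res

    def digital_stain(self, method: str = "pca", seed: int = 0) -> np.ndarray:
        return analysis.digital_stain(self.field, method=method, seed=seed)

    def plot_trace(self, ax=None):
        """Mean cost and variation coefficient against iteration."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        it = np.arange(1, self.n_iterations + 1)
        ax.plot(it, self.trace.mean_cost, "o-", label="mean cost")
        ax.plot(it, self.trace.variation_coefficient, "s--",
                label="variation coefficient")
        ax.plot(it, self.trace.tolerance, ":", label="tolerance")
        ax.set_xlabel("outer iteration")
        ax.legend()
        return ax

    def summary(self) -> str:
        """Plain-text fit report."""
        err = self.reprojection_error()
        h, w = self.field.height, self.field.width
        n_valid = int(self.field.valid.sum())
        lines = [
            "Quasi-spectral reconstruction results",
            "=" * 45,
            f"{'Image size:':<28}{h} x {w} px",
            f"{'Channels:':<28}{self.model.image.n_channels}",
            f"{'Wavelength samples:':<28}{self.field.grid.w} "
            f"({self.field.grid.lam_min:.0f}-{self.field.grid.lam_max:.0f} nm)",
            f"{'Valid pixels:':<28}{n_valid} / {h * w}",
            f"{'Outer iterations:':<28}{self.n_iterations}",
            f"{'Converged:':<28}{self.converged}",
            f"{'Final mean cost:':<28}{self.mean_cost:.5f}",
            f"{'Final cost CV:':<28}"
            f"{self.trace.variation_coefficient[-1]:.4f}",
            f"{'Final tolerance:':<28}{self.trace.tolerance[-1]:.4f}",
            "{:<28}{}".format(
                "Reprojection error:",
                ", ".join(f"{c}={e:.4f}" for c, e in
                          zip(self.model.image.channels, err))),
            f"{'Seed:':<28}{self.config.seed}",
            "=" * 45,
        ]
        return "\n".join(lines)
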