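"""Wavelength grids, spectra, and the linear measurement forward model.

The measurement model for an unsaturated, linear-response camera reduces to

    I_c = integral L_c(lambda) * T(lambda) d lambda,

where ``L_c = S * F_c`` is the *effective incoming light* of channel ``c``
(source spectrum times channel quantum efficiency) and ``T`` is the per-pixel
transparency spectrum, bounded to [0, 1].  Everything downstream — the
per-pixel loss, calibration integrals, and CIE rendering — goes through the
same quadrature, exposed here as a per-grid weight vector so that the forward
model is a plain dot product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np

__all__ = [
    "WavelengthGrid",
    "Spectrum",
    "EffectiveLight",
    "PixelSpectrum",
    "TransparencyField",
    "ChannelImage",
    "forward_integrate",
    "forward_image",
    "fidelity_term",
]

#: default number of wavelength samples
DEFAULT_W = 48
#: default span in nm — the instrument's UV long-pass / IR short-pass window
DEFAULT_SPAN = (450.0, 775.0)


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered discrete wavelengths (nm) shared by all spectra in a run."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        lam = np.asarray(self.wavelengths, dtype=float)
        if lam.ndim != 1 or lam.size < 3:
            raise ValueError("a wavelength grid needs at least 3 samples")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", lam)

    @classmethod
    def default(cls, w: int = DEFAULT_W,
                span: tuple[float, float] = DEFAULT_SPAN) -> "WavelengthGrid":
        return cls(np.linspace(span[0], span[1], w))

    @property
    def w(self) -> int:
        return self.wavelengths.size

    @property
    def lam_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def lam_max(self) -> float:
        return float(self.wavelengths[-1])

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.allclose(d, d[0], rtol=rtol))

    @cached_property
    def simpson_weights(self) -> np.ndarray:
        """Quadrature weights for composite Simpson integration.

        With an even number of intervals this is classic composite Simpson
        (exact for cubics).  With an odd interval count — the default grid
        has 48 points, hence 47 intervals — Simpson covers the first even
        block and the last interval is closed with a trapezoid.  Non-uniform
        grids fall back to trapezoid weights.
        """
        lam = self.wavelengths
        n = lam.size
        if not self.is_uniform():
            return self.trapezoid_weights
        h = lam[1] - lam[0]
        n_int = n - 1
        wts = np.zeros(n)
        m = n_int if n_int % 2 == 0 else n_int - 1  # even Simpson block
        if m >= 2:
            wts[0] += h / 3.0
            wts[m] += h / 3.0
            wts[1:m:2] += 4.0 * h / 3.0
            wts[2:m:2] += 2.0 * h / 3.0
        if m < n_int:  # trapezoid tail over the last interval
            wts[-2] += h / 2.0
            wts[-1] += h / 2.0
        return wts

    @cached_property
    def trapezoid_weights(self) -> np.ndarray:
        lam = self.wavelengths
        wts = np.zeros(lam.size)
        d = np.diff(lam)
        wts[:-1] += d / 2.0
        wts[1:] += d / 2.0
        return wts

    def quadrature_weights(self, method: str = "simpson") -> np.ndarray:
        if method == "simpson":
            return self.simpson_weights
        if method == "trapezoid":
            return self.trapezoid_weights
        raise ValueError(f"unknown quadrature method: {method!r}")

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, WavelengthGrid)
                and self.wavelengths.shape == other.wavelengths.shape
                and np.array_equal(self.wavelengths, other.wavelengths))

    def __hash__(self) -> int:
        return hash(self.wavelengths.tobytes())


def _check_grid(a_grid: WavelengthGrid, b_grid: WavelengthGrid) -> None:
    if a_grid != b_grid:
        raise ValueError("wavelength grids do not match")


@dataclass(frozen=True)
class Spectrum:
    """A single spectral curve on a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.w,):
            raise ValueError("spectrum length must match the grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        object.__setattr__(self, "values", v)

    def integral(self, method: str = "simpson") -> float:
        return float(self.grid.quadrature_weights(method) @ self.values)


@dataclass(frozen=True)
class EffectiveLight:
    """Per-channel effective illumination L_c(lambda) = S(lambda) * F_c(lambda)."""

    grid: WavelengthGrid
    values: np.ndarray            # shape (C, w)
    channels: tuple[str, ...] = ("R", "G", "B")

    def __post_init__(self) -> None:
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[1] != self.grid.w:
            raise ValueError("light curves must match the grid length")
        if v.shape[0] < 1:
            raise ValueError("need at least one channel")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("light curves must be finite and non-negative")
        object.__setattr__(self, "values", v)
        if len(self.channels) != v.shape[0]:
            object.__setattr__(
                self, "channels",
                tuple(f"ch{i}" for i in range(v.shape[0])))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    def integrals(self, method: str = "simpson") -> np.ndarray:
        """Per-channel integral of L_c — the white-background intensity."""
        return self.values @ self.grid.quadrature_weights(method)

    def scaled_to_white(self, white: Sequence[float]) -> "EffectiveLight":
        """Rescale each channel so that integral(L_c) equals ``white[c]``."""
        white = np.asarray(white, dtype=float)
        cur = self.integrals()
        if np.any(cur <= 0):
            raise ValueError("cannot rescale a channel with zero integral")
        return EffectiveLight(self.grid, self.values * (white / cur)[:, None],
                              self.channels)


@dataclass(frozen=True)
class PixelSpectrum:
    """Transparency spectrum of one pixel, bounded to [0, 1]."""

    grid: WavelengthGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.w,):
            raise ValueError("spectrum length must match the grid")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum values must be finite")
        if v.min() < -1e-9 or v.max() > 1 + 1e-9:
            raise ValueError("transparency must lie in [0, 1]")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


@dataclass
class TransparencyField:
    """Per-pixel transparency spectra: the unknown of the inverse problem.

    ``data`` has shape (height, width, w); ``valid`` marks pixels whose
    spectra are trustworthy (saturated / model-violating pixels are False).
    """

    grid: WavelengthGrid
    data: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim != 3 or d.shape[2] != self.grid.w:
            raise ValueError("field must have shape (H, W, w)")
        if not np.all(np.isfinite(d)):
            raise ValueError("field values must be finite")
        if d.min() < -1e-9 or d.max() > 1 + 1e-9:
            raise ValueError("transparency must lie in [0, 1]")
        self.data = np.clip(d, 0.0, 1.0)
        if self.valid is None:
            self.valid = np.ones(d.shape[:2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != d.shape[:2]:
                raise ValueError("valid mask must match field geometry")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    def pixel(self, row: int, col: int) -> PixelSpectrum:
        return PixelSpectrum(self.grid, self.data[row, col])

    def flat(self) -> np.ndarray:
        """(H*W, w) view of the spectra, row-major."""
        return self.data.reshape(-1, self.grid.w)


@dataclass
class ChannelImage:
    """Per-pixel per-channel intensities as recorded by the sensor.

    Intensities are raw counts (no white balance, no gamma); ``bit_depth``
    gives the ADC full scale and ``saturated`` flags clipped pixels.
    """

    data: np.ndarray              # (H, W, C)
    bit_depth: int = 16
    channels: tuple[str, ...] = ("R", "G", "B")
    saturated: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.ndim == 2:
            d = d[:, :, None]
        if d.ndim != 3:
            raise ValueError("image must have shape (H, W, C)")
        if np.any(d < 0):
            raise ValueError("intensities must be non-negative")
        self.data = d
        if len(self.channels) != d.shape[2]:
            self.channels = tuple(f"ch{i}" for i in range(d.shape[2]))
        if self.saturated is None:
            self.saturated = np.zeros(d.shape[:2], dtype=bool)
        else:
            self.saturated = np.asarray(self.saturated, dtype=bool)
            if self.saturated.shape != d.shape[:2]:
                raise ValueError("saturation mask must match image geometry")

    @property
    def height(self) -> int:
        return self.data.shape[0]

    @property
    def width(self) -> int:
        return self.data.shape[1]

    @property
    def n_channels(self) -> int:
        return self.data.shape[2]

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1

    def normalized(self) -> np.ndarray:
        """Intensities scaled by the bit-depth full scale into [0, 1]."""
        return self.data / self.max_count


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def forward_integrate(t: PixelSpectrum, light: EffectiveLight,
                      channel: int, method: str = "simpson") -> float:
    """Predicted intensity of one channel: integral of L_c * T over the grid."""
    _check_grid(t.grid, light.grid)
    wts = light.grid.quadrature_weights(method)
    return float((light.values[channel] * wts) @ t.values)


def forward_image(field: TransparencyField, light: EffectiveLight,
                  method: str = "simpson") -> ChannelImage:
    """Apply the forward model pixel-wise: an ideal noise-free camera."""
    _check_grid(field.grid, light.grid)
    wts = field.grid.quadrature_weights(method)
    kernel = light.values * wts            # (C, w)
    data = np.einsum("hwl,cl->hwc", field.data, kernel)
    return ChannelImage(data, bit_depth=16, channels=light.channels)


def fidelity_term(t: PixelSpectrum, light: EffectiveLight,
                  observed: Sequence[float], method: str = "simpson") -> float:
    """Exponential data-fit part of the per-pixel loss.

    ``sum_c exp(|predicted_c - observed_c|) - C``: zero iff every channel is
    matched exactly, and strictly increasing in each channel's residual.
    ``observed`` must be on the same intensity scale as ``integral(L_c)``
    (see the solver's white-level normalization).
    """
    obs = np.asarray(observed, dtype=float)
    if obs.shape != (light.n_channels,):
        raise ValueError("observed must have one intensity per channel")
    wts = light.grid.quadrature_weights(method)
    pred = (light.values * wts) @ t.values
    return float(np.sum(np.exp(np.abs(pred - obs))) - light.n_channels)
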