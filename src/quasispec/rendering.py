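"""Artificial re-illumination of spectral cubes and display handling.

A reconstructed transparency cube can be viewed under any illuminant: per
pixel the spectrum is multiplied by the illuminant and the CIE 1931
2-degree colour-matching functions, integrated (same Simpson quadrature as
the forward model) to XYZ tristimulus values, and converted to sRGB for
display.  The default illuminant is a Planck black body (the sun-like
5800 K is the conventional choice).

The packaged colour-matching table (``data/cie1931_2deg_synthetic.csv``) is
generated from the piecewise-Gaussian analytic fit of Wyman, Sloan &
Shirley (2013) and renormalized to the CIE equal-area convention, so the
equal-energy illuminant maps to x = y = 1/3.  It is an analytic
approximation of the standard observer, adequate for visualization and the
chromaticity checks here, not a replacement for the official tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import numpy as np

from .spectra import ChannelImage, TransparencyField, WavelengthGrid

__all__ = ["Illuminant", "ColorImage", "planck_spectrum", "cie_cmfs",
           "render", "xyz_to_srgb", "rescale_bright"]

# Planck's second radiation constant hc/k in nm*K
_C2_NM_K = 1.438777e7

# linear sRGB (D65) from XYZ, IEC 61966-2-1
_XYZ_TO_SRGB = np.array([
    [3.2406, -1.5372, -0.4986],
    [-0.9689, 1.8758, 0.0415],
    [0.0557, -0.2040, 1.0570],
])


@dataclass(frozen=True)
class Illuminant:
    """Spectral power distribution aligned with a wavelength grid."""

    grid: WavelengthGrid
    values: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (self.grid.w,):
            raise ValueError("illuminant must match the grid")
        if np.any(v < 0):
            raise ValueError("spectral power must be non-negative")
        object.__setattr__(self, "values", v)

    @classmethod
    def equal_energy(cls, grid: WavelengthGrid) -> "Illuminant":
        return cls(grid, np.ones(grid.w), "equal_energy")


@dataclass
class ColorImage:
    """Tristimulus image plus its display encoding."""

    xyz: np.ndarray          # (H, W, 3), CIE XYZ
    rgb: np.ndarray          # (H, W, 3), display sRGB in [0, 1]

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("XYZ must be finite")
        if self.rgb.min() < 0 or self.rgb.max() > 1:
            raise ValueError("display RGB must lie in [0, 1]")

    def chromaticity(self) -> np.ndarray:
        """(H, W, 2) CIE xy chromaticity; undefined (NaN) for black pixels."""
        s = self.xyz.sum(axis=2, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            xy = self.xyz[:, :, :2] / s
        return np.where(s > 0, xy, np.nan)


def planck_spectrum(temperature: float, grid: WavelengthGrid) -> Illuminant:
    """Black-body spectral radiance shape, normalized to unit maximum."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    lam = grid.wavelengths
    # relative spectral radiance: lambda^-5 / (exp(c2 / (lambda T)) - 1)
    x = _C2_NM_K / (lam * temperature)
    vals = lam ** -5.0 / np.expm1(x)
    return Illuminant(grid, vals / vals.max(), f"planck_{temperature:g}K")


@lru_cache(maxsize=1)
def _cmf_table() -> np.ndarray:
    ref = resources.files("quasispec.data") / "cie1931_2deg_synthetic.csv"
    return np.loadtxt(str(ref), delimiter=",")


def cie_cmfs(grid: WavelengthGrid) -> np.ndarray:
    """CIE 1931 2-degree matching curves resampled to a grid; shape (3, w)."""
    tab = _cmf_table()
    return np.stack([
        np.interp(grid.wavelengths, tab[:, 0], tab[:, j], left=0.0, right=0.0)
        for j in (1, 2, 3)])


def xyz_to_srgb(xyz: np.ndarray) -> np.ndarray:
    """XYZ to display sRGB: linear matrix, clip to gamut, gamma encode."""
    lin = np.einsum("ij,...j->...i", _XYZ_TO_SRGB, xyz)
    lin = np.clip(lin, 0.0, 1.0)
    return np.where(lin <= 0.0031308, 12.92 * lin,
                    1.055 * lin ** (1 / 2.4) - 0.055)


def render(field: TransparencyField, illuminant: Illuminant,
           normalize: bool = True) -> ColorImage:
    """Re-illuminate a cube and project it to CIE 1931 colour.

    Per pixel: X, Y, Z = integral T(l) E(l) cmf(l) dl with the shared
    Simpson quadrature.  ``normalize=True`` scales XYZ so a fully
    transparent pixel has Y = 1 (relative luminance against the open
    illuminant).
    """
    if field.grid != illuminant.grid:
        raise ValueError("cube and illuminant must share the grid")
    cmf = cie_cmfs(field.grid)
    wts = field.grid.simpson_weights
    kernel = cmf * illuminant.values * wts          # (3, w)
    xyz = np.einsum("hwl,cl->hwc", field.data, kernel)
    if normalize:
        y_white = float(kernel[1].sum())
        if y_white > 0:
            xyz = xyz / y_white
    return ColorImage(xyz, xyz_to_srgb(xyz))


def rescale_bright(image: ChannelImage, percentile: float = 99.0
                   ) -> ChannelImage:
    """Flag very bright pixels as saturated and rescale the rest.

    Light-condensing objects (bubbles, vacuoles acting as micro-lenses)
    violate the transparency bound and show up as abnormally bright pixels;
    for visualization they are detected at the given intensity percentile,
    treated as saturated, and the remaining intensities are linearly
    rescaled to the original range.
    """
    data = image.data
    peak = data.max(axis=2)
    thresh = np.percentile(peak, percentile)
    bright = peak > thresh
    keep = data[~bright]
    out = data.copy()
    if keep.size:
        lo, hi = keep.min(), keep.max()
        full = data.max()
        if hi > lo:
            out = np.clip((data - lo) / (hi - lo), 0.0, 1.0) * full
        # degenerate case (all kept intensities equal): leave unchanged
    return ChannelImage(out, bit_depth=image.bit_depth,
                        channels=image.channels,
                        saturated=image.saturated | bright)
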