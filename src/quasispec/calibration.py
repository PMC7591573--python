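"""Per-pixel sensor calibration from ND-filter stacks.

Sensor pixels respond inhomogeneously (gain dispersion, Bayer channel
identity).  Calibration photographs a uniform background through a set of
neutral-density layers; a fibre spectrometer records the transmitted
spectrum for each layer.  For every pixel this yields knot pairs
``(M_i, S_i)`` — recorded intensity vs the QE-weighted spectral integral

    S_i = integral spectrum_i(lambda) * F_c(pixel)(lambda) d lambda

— and the per-pixel response map S(M) is the piecewise-linear interpolant
through those knots.  Applying S(M) to a raw image equalizes pixel
responses so that equal incident spectral energy gives equal output.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .spectra import ChannelImage, EffectiveLight, Spectrum, WavelengthGrid

__all__ = ["CalibrationInput", "CalibrationTable", "build_calibration",
           "apply_calibration", "demosaic_bilinear"]


@dataclass
class CalibrationInput:
    """One raw flat image + one measured spectrum per ND filter, plus QE."""

    images: list[ChannelImage]       # single-plane mosaic frames
    spectra: list[Spectrum]          # transmitted-light spectra, same order
    qe: EffectiveLight               # per-channel quantum efficiency F_c
    bayer: str = "RGGB"              # Bayer pattern, or "mono"

    def __post_init__(self) -> None:
        if len(self.images) < 2:
            raise ValueError("calibration needs at least 2 filters")
        if len(self.images) != len(self.spectra):
            raise ValueError("one spectrum per filter image required")
        shapes = {im.data.shape[:2] for im in self.images}
        if len(shapes) != 1:
            raise ValueError("all filter images must share geometry")


@dataclass
class CalibrationTable:
    """Per-pixel knots of the piecewise-linear response map S(M).

    ``m_knots``/``s_knots`` have shape (H, W, K), sorted by M per pixel;
    ``channel_map`` records each pixel's Bayer channel identity.
    """

    m_knots: np.ndarray
    s_knots: np.ndarray
    channel_map: np.ndarray
    channels: tuple[str, ...] = ("R", "G", "B")

    def __post_init__(self) -> None:
        if self.m_knots.shape != self.s_knots.shape:
            raise ValueError("knot arrays must share shape")
        if self.m_knots.shape[2] < 2:
            raise ValueError("each pixel needs at least 2 knots")
        if np.any(self.s_knots < 0):
            raise ValueError("spectral integrals must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.m_knots.shape[:2]

    @property
    def n_knots(self) -> int:
        return self.m_knots.shape[2]

    def save(self, path) -> None:
        """Structured container: npz payload with a JSON header."""
        header = json.dumps({"format": "qcal-1", "channels": list(self.channels),
                             "shape": list(self.m_knots.shape)})
        np.savez(path, header=np.array(header), m_knots=self.m_knots,
                 s_knots=self.s_knots, channel_map=self.channel_map)

    @classmethod
    def load(cls, path) -> "CalibrationTable":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            return cls(z["m_knots"], z["s_knots"], z["channel_map"],
                       tuple(header["channels"]))


def _bayer_channel_map(pattern: str, shape: tuple[int, int]) -> np.ndarray:
    from .phantoms import BAYER_PATTERNS  # shared tile definitions
    if pattern.lower() == "mono":
        return np.zeros(shape, dtype=int)
    tile = BAYER_PATTERNS[pattern.upper()]
    h, w = shape
    return np.tile(tile, (h // 2 + 1, w // 2 + 1))[:h, :w]


def _resample(spec: Spectrum, grid: WavelengthGrid) -> np.ndarray:
    if spec.grid == grid:
        return spec.values
    return np.interp(grid.wavelengths, spec.grid.wavelengths, spec.values,
                     left=0.0, right=0.0)


def build_calibration(cal: CalibrationInput,
                      grid: WavelengthGrid | None = None) -> CalibrationTable:
    """Knot tables from an ND stack.

    Per filter, the transmitted spectrum is multiplied by the pixel
    channel's QE curve and integrated (Simpson, shared quadrature) to give
    the S knot; the pixel's recorded intensity in that frame gives the M
    knot.  Knots are sorted by M per pixel; non-monotone S along sorted M
    draws a warning (a real sensor should be monotone).
    """
    grid = grid or cal.qe.grid
    shape = cal.images[0].data.shape[:2]
    cmap = _bayer_channel_map(cal.bayer, shape)
    wts = grid.quadrature_weights()
    qe = np.stack([_resample(Spectrum(cal.qe.grid, cal.qe.values[c]), grid)
                   for c in range(cal.qe.n_channels)])
    n_f = len(cal.images)
    m_knots = np.empty(shape + (n_f,))
    s_knots = np.empty(shape + (n_f,))
    for i, (im, spec) in enumerate(zip(cal.images, cal.spectra)):
        sv = _resample(spec, grid)
        s_per_channel = (qe * sv) @ wts                  # (C,)
        m_knots[:, :, i] = im.data[:, :, 0]
        s_knots[:, :, i] = s_per_channel[cmap]
    order = np.argsort(m_knots, axis=2)
    m_knots = np.take_along_axis(m_knots, order, axis=2)
    s_knots = np.take_along_axis(s_knots, order, axis=2)
    if np.any(np.diff(s_knots, axis=2) < -1e-12):
        warnings.warn("non-monotone S(M) at some pixels; knots sorted by M")
    return CalibrationTable(m_knots, s_knots, cmap, cal.qe.channels)


def apply_calibration(raw: ChannelImage, table: CalibrationTable
                      ) -> ChannelImage:
    """Map raw intensities through each pixel's own S(M) interpolant.

    Linear interpolation between knots; outside the measured range the
    nearest segment is continued linearly (extrapolated pixels keep their
    value but are untrusted — inspect the knot range when it matters).
    """
    if raw.data.shape[:2] != table.shape:
        raise ValueError("calibration table does not cover this image")
    m = raw.data[:, :, 0]
    mk, sk = table.m_knots, table.s_knots
    k = table.n_knots
    # segment index per pixel: count of knots strictly below m, clipped
    seg = np.sum(mk < m[:, :, None], axis=2) - 1
    seg = np.clip(seg, 0, k - 2)
    idx = seg[:, :, None]
    m0 = np.take_along_axis(mk, idx, axis=2)[:, :, 0]
    m1 = np.take_along_axis(mk, idx + 1, axis=2)[:, :, 0]
    s0 = np.take_along_axis(sk, idx, axis=2)[:, :, 0]
    s1 = np.take_along_axis(sk, idx + 1, axis=2)[:, :, 0]
    dm = m1 - m0
    slope = np.where(dm > 0, (s1 - s0) / np.where(dm > 0, dm, 1.0), 0.0)
    s = s0 + slope * (m - m0)
    return ChannelImage(np.maximum(s, 0.0)[:, :, None],
                        bit_depth=raw.bit_depth, channels=("S",),
                        saturated=raw.saturated)


def demosaic_bilinear(mosaic: ChannelImage, pattern: str = "RGGB"
                      ) -> ChannelImage:
    """Bilinear demosaicking of a Bayer frame into 3 channels."""
    from scipy import ndimage
    cmap = _bayer_channel_map(pattern, mosaic.data.shape[:2])
    m = mosaic.data[:, :, 0]
    out = np.empty(m.shape + (3,))
    kernel = np.array([[0.25, 0.5, 0.25], [0.5, 1.0, 0.5], [0.25, 0.5, 0.25]])
    for c in range(3):
        mask = (cmap == c).astype(float)
        num = ndimage.convolve(m * mask, kernel, mode="mirror")
        den = ndimage.convolve(mask, kernel, mode="mirror")
        out[:, :, c] = num / np.where(den > 0, den, 1.0)
    return ChannelImage(out, bit_depth=mosaic.bit_depth,
                        channels=("R", "G", "B"), saturated=mosaic.saturated)
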