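"""Synthetic ground truth: phantom fields, simulated cameras, ND stacks.

Every stage of the pipeline is testable without an instrument: a phantom is
a transparency field that is smooth inside regions and discontinuous across
region borders (the sample assumptions of the method — localized gradients,
reasonable flatness, linear response — hold by construction); a simulated
camera applies the forward model, per-pixel gain dispersion, offset,
additive noise, optional Bayer mosaicking and quantization; a simulated ND
stack exercises the per-pixel calibration round trip.

Region spectra are mixtures of Gaussian bumps over the wavelength grid.
Because the inverse problem is underdetermined (C equations, w unknowns per
pixel), phantom-based acceptance targets forward consistency and region
recovery rather than pointwise spectral equality.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .calibration import CalibrationInput
from .rendering import planck_spectrum
from .spectra import (ChannelImage, EffectiveLight, Spectrum,
                      TransparencyField, WavelengthGrid, forward_image)

__all__ = ["CameraModel", "PhantomSpec", "default_light", "region_spectra",
           "make_phantom", "simulate_camera", "simulate_calibration_stack",
           "two_region_scene", "micro_lens_scene"]

BAYER_PATTERNS = {
    "RGGB": np.array([[0, 1], [1, 2]]),
    "BGGR": np.array([[2, 1], [1, 0]]),
    "GRBG": np.array([[1, 0], [2, 1]]),
    "GBRG": np.array([[1, 2], [0, 1]]),
}


@dataclass
class CameraModel:
    """Linear sensor with per-pixel gain dispersion.

    counts = gain_px * scale * S + offset + noise, quantized to bit_depth.
    ``fill_fraction`` sets where a fully transparent pixel (T = 1) lands on
    the ADC scale; ``noise_sigma`` is the additive Gaussian sigma as a
    fraction of that white level.
    """

    bit_depth: int = 12
    gain_cv: float = 0.0
    offset: float = 0.0
    noise_sigma: float = 0.0
    fill_fraction: float = 0.7
    bayer: str | None = None      # None = demosaiced 3-channel output

    @property
    def max_count(self) -> int:
        return 2 ** self.bit_depth - 1


@dataclass
class PhantomSpec:
    """Recipe for a seeded synthetic scene."""

    height: int = 24
    width: int = 24
    n_regions: int = 2
    geometry: str = "disc"         # disc | halves | voronoi
    bump_width: float = 35.0       # nm, width of spectral Gaussian bumps
    baseline: float = 0.08         # transparency floor of region spectra
    amplitude: float = 0.85        # bump height above the floor
    contrast: float = 1.0          # 1 = fully distinct region spectra;
                                   # < 1 mixes regions toward their mean
    modulation: float = 0.03       # within-region smooth modulation amp
    noise_sigma: float = 0.05      # camera noise (fraction of white level)
    gain_cv: float = 0.0
    bit_depth: int = 12
    bayer: str | None = None
    micro_lens: tuple[int, int] | None = None  # pixel violating T <= 1
    micro_lens_factor: float = 1.3
    seed: int = 0
    grid: WavelengthGrid = dc_field(default_factory=WavelengthGrid.default)

    def camera(self) -> CameraModel:
        return CameraModel(bit_depth=self.bit_depth, gain_cv=self.gain_cv,
                           noise_sigma=self.noise_sigma, bayer=self.bayer)


def default_light(grid: WavelengthGrid | None = None,
                  temperature: float = 5800.0) -> EffectiveLight:
    """A plausible RGB effective light: black-body lamp times Gaussian QE.

    Channel quantum efficiencies are Gaussians centred at 610 (R), 540 (G)
    and 465 nm (B) with 28 nm sigma, multiplied by a Planck lamp spectrum.
    Units are arbitrary: the solver rescales to the measured white level.
    """
    grid = grid or WavelengthGrid.default()
    lam = grid.wavelengths
    lamp = planck_spectrum(temperature, grid).values
    centers = (610.0, 540.0, 465.0)
    curves = np.stack([lamp * np.exp(-0.5 * ((lam - c) / 28.0) ** 2)
                       for c in centers])
    return EffectiveLight(grid, curves, ("R", "G", "B"))


def region_spectra(grid: WavelengthGrid, n_regions: int,
                   bump_width: float = 35.0, baseline: float = 0.08,
                   amplitude: float = 0.85,
                   contrast: float = 1.0) -> np.ndarray:
    """Near-orthogonal Gaussian-bump base spectra, one per region.

    Bump centres are spread evenly over the grid span so that distinct
    regions peak in different bands.  ``contrast < 1`` pulls every spectrum
    toward the common mean, producing low-contrast variants whose raw RGB
    responses are hard to separate while the spectra keep their shape.
    """
    lam = grid.wavelengths
    centers = np.linspace(lam[0] + 0.15 * (lam[-1] - lam[0]),
                          lam[-1] - 0.15 * (lam[-1] - lam[0]), n_regions)
    spectra = np.stack([
        baseline + amplitude * np.exp(-0.5 * ((lam - c) / bump_width) ** 2)
        for c in centers])
    if contrast < 1.0:
        mean = spectra.mean(axis=0, keepdims=True)
        spectra = mean + contrast * (spectra - mean)
    return np.clip(spectra, 0.0, 1.0)


def _region_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w]
    if spec.geometry == "halves":
        edges = np.linspace(0, w, spec.n_regions + 1)
        return np.clip(np.searchsorted(edges[1:-1], cols, side="right"),
                       0, spec.n_regions - 1)
    if spec.geometry == "disc":
        labels = np.zeros((h, w), dtype=int)
        radius = 0.30 * min(h, w)
        centers = [(h / 2, w / 2)]
        if spec.n_regions > 2:
            ang = np.linspace(0, 2 * np.pi, spec.n_regions - 1,
                              endpoint=False)
            centers = [(h / 2 + 0.22 * h * np.sin(a),
                        w / 2 + 0.22 * w * np.cos(a)) for a in ang]
            radius = 0.18 * min(h, w)
        for i, (cy, cx) in enumerate(centers, start=1):
            inside = (rows - cy) ** 2 + (cols - cx) ** 2 <= radius ** 2
            labels[inside] = i
        return labels
    if spec.geometry == "voronoi":
        seeds = rng.uniform(0, [h, w], size=(spec.n_regions, 2))
        d = ((rows[None] - seeds[:, 0, None, None]) ** 2
             + (cols[None] - seeds[:, 1, None, None]) ** 2)
        return np.argmin(d, axis=0)
    raise ValueError(f"unknown geometry: {spec.geometry!r}")


def make_phantom(spec: PhantomSpec
                 ) -> tuple[TransparencyField, np.ndarray]:
    """Ground-truth field and region label map for a phantom recipe.

    The field is smooth inside regions (a low-frequency multiplicative
    modulation of the region base spectrum) and discontinuous across region
    borders.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=spec.seed, spawn_key=(1,)))
    labels = _region_labels(spec, rng)
    base = region_spectra(spec.grid, spec.n_regions, spec.bump_width,
                          spec.baseline, spec.amplitude, spec.contrast)
    h, w = spec.height, spec.width
    rows, cols = np.mgrid[0:h, 0:w]
    phase = rng.uniform(0, 2 * np.pi, size=2)
    mod = 1.0 + spec.modulation * (
        np.sin(2 * np.pi * rows / max(h, 2) + phase[0])
        * np.cos(2 * np.pi * cols / max(w, 2) + phase[1]))
    data = base[labels] * mod[:, :, None]
    if data.min() < 0 or data.max() > 1:
        raise ValueError("modulation pushes spectra outside [0, 1]")
    return TransparencyField(spec.grid, data), labels


def _mosaic_channel_map(pattern: str, shape: tuple[int, int]) -> np.ndarray:
    tile = BAYER_PATTERNS[pattern.upper()]
    h, w = shape
    return np.tile(tile, (h // 2 + 1, w // 2 + 1))[:h, :w]


def simulate_camera(field: TransparencyField, light: EffectiveLight,
                    camera: CameraModel, seed: int = 0,
                    ) -> tuple[ChannelImage, np.ndarray]:
    """Record a phantom through a simulated sensor.

    Returns ``(image, white_level)`` with ``white_level`` the per-channel
    intensity (in [0, 1] full-scale units) a fully transparent pixel would
    produce — the quantity the solver's normalization needs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(2,)))
    ideal = forward_image(field, light).data          # (H, W, C), physical
    white_phys = light.integrals()
    scale = camera.fill_fraction * camera.max_count / white_phys
    counts = ideal * scale                            # (H, W, C) in counts
    h, w, n_ch = counts.shape
    gain = np.ones((h, w))
    if camera.gain_cv > 0:
        gain = rng.normal(1.0, camera.gain_cv, size=(h, w))
        gain = np.clip(gain, 0.1, None)
    counts = counts * gain[:, :, None] + camera.offset
    if camera.noise_sigma > 0:
        sigma = camera.noise_sigma * camera.fill_fraction * camera.max_count
        counts = counts + rng.normal(0.0, sigma, size=counts.shape)
    if camera.bayer is not None:
        cmap = _mosaic_channel_map(camera.bayer, (h, w))
        counts = np.take_along_axis(counts, cmap[:, :, None], axis=2)
    counts = np.clip(np.round(counts), 0, camera.max_count)
    saturated = counts.max(axis=2) >= camera.max_count
    image = ChannelImage(counts, bit_depth=camera.bit_depth,
                         channels=(light.channels if camera.bayer is None
                                   else ("mosaic",)),
                         saturated=saturated)
    white_level = camera.fill_fraction * np.ones(n_ch)
    return image, white_level


def simulate_calibration_stack(camera: CameraModel, n_filters: int = 4,
                               seed: int = 0,
                               grid: WavelengthGrid | None = None,
                               shape: tuple[int, int] = (8, 8),
                               ) -> CalibrationInput:
    """ND-filter calibration data consistent with a simulated sensor.

    ``n_filters`` uniform-background exposures through neutral-density
    layers of decreasing transmittance, each paired with the spectrometer
    spectrum of the transmitted light, plus the per-channel QE curves —
    exactly what ``build_calibration`` needs to invert the sensor.
    """
    if n_filters < 2:
        raise ValueError("need at least 2 filters")
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(3,)))
    light = default_light(grid)
    lamp = planck_spectrum(5800.0, grid).values
    qe = light.values / np.where(lamp > 0, lamp, 1.0)   # recover QE curves
    transmittances = np.geomspace(1.0, 0.15, n_filters)
    h, w = shape
    gain = np.ones((h, w))
    if camera.gain_cv > 0:
        gain = np.clip(rng.normal(1.0, camera.gain_cv, size=(h, w)),
                       0.1, None)
    pattern = camera.bayer or "RGGB"
    cmap = _mosaic_channel_map(pattern, (h, w))
    wts = grid.simpson_weights
    white_phys = float(np.max((qe * lamp) @ wts))
    scale = camera.fill_fraction * camera.max_count / white_phys
    images, spectra = [], []
    for tr in transmittances:
        spec_phys = tr * lamp
        s_per_channel = (qe * spec_phys) @ wts          # (C,)
        counts = gain * s_per_channel[cmap] * scale + camera.offset
        if camera.noise_sigma > 0:
            sigma = camera.noise_sigma * camera.fill_fraction * camera.max_count
            counts = counts + rng.normal(0.0, sigma, size=counts.shape)
        counts = np.clip(np.round(counts), 0, camera.max_count)
        images.append(ChannelImage(counts, bit_depth=camera.bit_depth,
                                   channels=("mosaic",)))
        spectra.append(Spectrum(grid, spec_phys, name=f"filter{tr:.3f}"))
    return CalibrationInput(images=images, spectra=spectra,
                            qe=EffectiveLight(grid, qe, light.channels),
                            bayer=pattern)


def two_region_scene(size: int = 24, noise_sigma: float = 0.05,
                     contrast: float = 1.0, seed: int = 0,
                     micro_lens: tuple[int, int] | None = None,
                     grid: WavelengthGrid | None = None):
    """Convenience bundle: the canonical two-region disc phantom.

    Returns a dict with the ground-truth field, labels, effective light,
    recorded image and white level — the standard desk-scale scene used by
    the self-tests.
    """
    grid = grid or WavelengthGrid.default()
    spec = PhantomSpec(height=size, width=size, n_regions=2,
                       geometry="disc", contrast=contrast,
                       noise_sigma=noise_sigma, seed=seed, grid=grid,
                       micro_lens=micro_lens)
    field, labels = make_phantom(spec)
    light = default_light(grid)
    image, white = simulate_camera(field, light, spec.camera(), seed=seed)
    if micro_lens is not None:
        _apply_micro_lens(image, spec, micro_lens)
    return {"spec": spec, "field": field, "labels": labels,
            "light": light, "image": image, "white_level": white}


def _apply_micro_lens(image: ChannelImage, spec: PhantomSpec,
                      pos: tuple[int, int]) -> None:
    """Make one pixel brighter than the blank background.

    A light-condensing object focuses light onto the sensor, producing an
    intensity above what any transparency T <= 1 can explain — the lens
    counts are ``micro_lens_factor`` times the white level (kept below the
    ADC full scale so the pixel is not masked as saturated).
    """
    r, c = pos
    cam = spec.camera()
    lens_counts = spec.micro_lens_factor * cam.fill_fraction * cam.max_count
    image.data[r, c] = np.round(min(lens_counts, cam.max_count - 1))
    image.saturated[r, c] = False


def micro_lens_scene(size: int = 24, noise_sigma: float = 0.05,
                     seed: int = 0, lens: tuple[int, int] | None = None,
                     grid: WavelengthGrid | None = None):
    """Single-region phantom with one model-violating micro-lens pixel.

    Every normal pixel satisfies the measurement model, so the lens pixel's
    converged cost should stand far outside the cost distribution.
    """
    grid = grid or WavelengthGrid.default()
    lens = lens or (size // 3, size // 3)
    spec = PhantomSpec(height=size, width=size, n_regions=1,
                       geometry="halves", noise_sigma=noise_sigma,
                       seed=seed, grid=grid, micro_lens=lens)
    field, labels = make_phantom(spec)
    light = default_light(grid)
    image, white = simulate_camera(field, light, spec.camera(), seed=seed)
    _apply_micro_lens(image, spec, lens)
    return {"spec": spec, "field": field, "labels": labels, "light": light,
            "image": image, "white_level": white, "lens": lens}
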