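# quasispec

Per-pixel **quasi-transparency spectra** from ordinary bright-field RGB
microscopy images.

A bright-field microscope with a linear, unsaturated sensor measures, at
every pixel and colour channel *c*,

    I_c = ∫ L_c(λ) · T(λ) dλ,        L_c(λ) = S(λ) · F_c(λ),

where *S* is the source spectrum, *F_c* the channel quantum efficiency and
*T(λ) ∈ [0, 1]* the pixel's transparency spectrum over *w* = 48 discrete
wavelengths (450–775 nm by default).  Three equations, forty-eight
unknowns: the inverse problem is hopeless per pixel, but neighbouring
pixels of a flat biological sample are not independent.  `quasispec`
solves the regularized per-pixel problem

    F_m = Σ_c exp(|∫ L_c T_m dλ − I_mc|) − C
        + (1/N) Σ_{n∈N_m} G_mn Σ_i (T_m(λ_i) − T_n(λ_i))²

by mean-field iteration: every pixel's spectrum is minimized by CMA-ES
against its neighbours' spectra frozen from the previous sweep, with the
coupling weights *G_mn* attenuated across detected edges (image gradients
on the first sweep, spectral cross-correlation afterwards), a linearly
decreasing loss tolerance, and a stopping rule on the change of the mean
cost.  The recovered spectral cube supports artificial re-illumination
(Planck black body + CIE 1931), per-pixel camera calibration, cosine
k-means clustering with gap statistics, and dimensionality-reduction
"digital staining" — semantic segmentation of unstained cells without any
training data.  Because nothing here needs an instrument, the package
ships a phantom generator that emulates scenes, cameras and ND-filter
calibration stacks, and the whole pipeline is validated against it.

Intended users: microscopists and image-analysis researchers who can
access the raw (pre-white-balance, pre-gamma) camera signal and want
physically structured per-pixel features instead of RGB triplets.

Conventions: pixel coordinates are 0-based `(row, column)`, images are
row-major `(H, W, C)` arrays, intensities are raw counts against a
bit-depth full scale.

## Worked example

```python
import quasispec as q

# a synthetic scene: 24x24 two-region phantom, 5% intensity noise,
# recorded through the forward model by a simulated 12-bit camera
scene = q.two_region_scene(size=24, noise_sigma=0.05, seed=7)

model = q.QuasiSpectralModel(
    scene["image"], scene["light"],
    q.SolverConfig(white_level=scene["white_level"]))
res = model.fit(seed=1)
print(res.summary())
```

```
Quasi-spectral reconstruction results
=============================================
Image size:                 24 x 24 px
Channels:                   3
Wavelength samples:         48 (450-775 nm)
Valid pixels:               576 / 576
Outer iterations:           12
Converged:                  True
Final mean cost:            0.40243
Final cost CV:              0.6410
Final tolerance:            0.0500
Reprojection error:         R=0.0490, G=0.0285, B=0.0351
Seed:                       1
=============================================
```

The loop converged in 12 outer sweeps (the stopping rule arms once the
tolerance schedule is constant, after iteration 10).  The reprojection
error — the mean per-channel |forward-model prediction − observation| on
a [0, 1] intensity scale — ends near the noise floor and below the final
loss tolerance 0.05, i.e. the cube explains the image it was solved from.
The mean cost sits above the tolerance because pixels on the region
boundary legitimately pay for their discontinuity.

Downstream, in the same session:

```python
color = res.render(temperature=5800)       # Planck re-illumination -> sRGB
cl = res.cluster(k=2, seed=0)              # cosine k-means on the cube
from sklearn.metrics import adjusted_rand_score
print(adjusted_rand_score(scene["labels"].ravel(), cl.labels))
```

```
0.8311
```

Clustering the reconstructed spectra recovers the phantom's ground-truth
regions well (adjusted Rand index 0.83, with the disagreements on the
region boundary); on the raw
three-channel intensities of a low-contrast variant of the same scene the
identical clustering scores far lower — the point of reconstructing
spectra in the first place.

## Command line

```bash
quasispec phantom --size 24 --seed 7 --out-dir scene/
quasispec reconstruct --image scene/image.tif --light scene/light.csv \
    --out cube.tif --trace trace.csv --seed 1
quasispec render  --cube cube.tif --illuminant planck:5800 --out view.png
quasispec cluster --cube cube.tif -k 10 --gap 1:15 -B 20 --seed 7 --out-dir cl/
quasispec calibrate --manifest cal.yaml --out table.qcal.npz
quasispec correct --image raw.tif --table table.qcal.npz --out corr.tif
```

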