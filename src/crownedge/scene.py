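"""Synthetic hyperspectral scenes with known labels and a sharp guidance image.

The generator emulates the situation the pipeline targets: a four-class
forest scene (bare land, understory vegetation, shadow, damaged pine) imaged
by a low-spatial-resolution hyperspectral sensor and a sharper RGB camera.
Class regions come from thresholded smoothed Gaussian random fields, so
boundaries are irregular and crown-like. Each pixel's spectrum is its class
mean (a smooth curve over wavelength) plus band-correlated noise; a spatial
Gaussian blur of width sigma_mix then mixes spectra across boundaries,
reproducing the mixed-pixel problem that edge-preserving filtering is meant
to repair. The guidance image renders per-class colors with a much smaller
blur (and an optional sub-pixel misregistration), so its edges are sharp
where the cube's are soft.

What this scene does *not* emulate: radiative-transfer effects, 3-D canopy
structure, cast shadows (the shadow class is just another spectral class),
or the within-class illumination gradients of real crowns. Passing tests on
this scene demonstrate the machinery and the direction of the filtering
benefit, not field-scale accuracy values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .raster_io import (
    TRAINING,
    VERIFICATION,
    GuidanceImage,
    HyperspectralCube,
    LabelMap,
    SampleSet,
)

__all__ = [
    "SceneSpec",
    "DEFAULT_CLASS_NAMES",
    "generate_label_map",
    "render_cube",
    "render_guidance",
    "make_scene",
    "sample_points",
]

DEFAULT_CLASS_NAMES = (
    "bare_land",
    "understory_vegetation",
    "shadow",
    "damaged_pine",
)

# guidance colors per default class: dull soil brown, dark canopy green,
# near-black shadow, bright grey-brown defoliated crowns
_DEFAULT_COLORS = np.array(
    [
        [0.55, 0.45, 0.30],
        [0.10, 0.35, 0.12],
        [0.03, 0.03, 0.05],
        [0.80, 0.70, 0.60],
    ]
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene.

    Defaults describe the study conditions at desk scale: a 200×200 scene
    with K=4 classes and B=40 bands over 450–950 nm (enough bands for
    band-space structure without the full 125), per-pixel spectral noise
    sigma 0.05 reflectance, boundary mixing blur sigma_mix 1.5 px on the
    cube, and a much sharper guidance (0.5 px blur).
    """

    height: int = 200
    width: int = 200
    n_classes: int = 4
    n_bands: int = 40
    class_names: Sequence[str] = DEFAULT_CLASS_NAMES
    class_separation: float = 0.3      # spread of class mean reflectance levels
    noise_sigma: float = 0.05
    band_noise_corr: float = 2.0       # Gaussian width of noise correlation across bands
    sigma_mix: float = 1.5             # boundary-mixing blur on the cube, px
    shade_amp: float = 0.6             # strength of within-region shading blotches
    shade_scale: float = 2.0           # spatial scale of the shading field, px
    guidance_blur: float = 0.5         # edge softness of the guidance, px
    guidance_shift: tuple[float, float] = (0.0, 0.0)  # (row, col) misregistration, px
    region_smoothness: float = 6.0     # random-field smoothing; larger = bigger regions
    wavelength_range_nm: tuple[float, float] = (450.0, 950.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_bands < 3:
            raise ValueError("need at least 3 bands")
        if self.sigma_mix < 0 or self.guidance_blur < 0 or self.noise_sigma < 0:
            raise ValueError("blur and noise scales must be non-negative")
        if not 0 <= self.shade_amp <= 1:
            raise ValueError("shade_amp must lie in [0, 1]")
        if len(self.class_names) != self.n_classes:
            object.__setattr__(
                self, "class_names",
                tuple(f"class_{i}" for i in range(self.n_classes)),
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def wavelengths_nm(self) -> np.ndarray:
        lo, hi = self.wavelength_range_nm
        return np.linspace(lo, hi, self.n_bands)


def _rng(spec: SceneSpec, stream: int) -> np.random.Generator:
    # independent, reproducible streams per generator stage
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def generate_label_map(spec: SceneSpec) -> LabelMap:
    """K-class map from a quantile-thresholded smoothed Gaussian random field.

    Quantile thresholds put roughly equal area in each class; smoothing makes
    regions contiguous with irregular boundaries. Deterministic in the seed.
    """
    rng = _rng(spec, 0)
    noise = rng.standard_normal(spec.shape)
    fld = ndimage.gaussian_filter(noise, spec.region_smoothness, mode="reflect")
    edges = np.quantile(fld, np.linspace(0, 1, spec.n_classes + 1)[1:-1])
    labels = np.searchsorted(edges, fld, side="left").astype(np.int64)
    return LabelMap(labels, spec.class_names)


def class_mean_spectra(spec: SceneSpec) -> np.ndarray:
    """K×B matrix of smooth per-class mean spectra in [0.05, 0.95].

    Each class mean is a distinct random smooth curve: a low-order Fourier
    series over the band axis with class-specific coefficients, around
    per-class reflectance levels spread by ``class_separation``. The default
    separation keeps classes distinguishable but overlapping enough that a
    pixel-wise classifier makes boundary and shading errors at realistic
    rates, rather than solving the scene outright.
    """
    rng = _rng(spec, 1)
    t = np.linspace(0, 1, spec.n_bands)
    spectra = np.zeros((spec.n_classes, spec.n_bands))
    offsets = 0.5 + spec.class_separation * np.linspace(-0.5, 0.5, spec.n_classes)
    rng.shuffle(offsets)
    for k in range(spec.n_classes):
        curve = np.zeros_like(t)
        for harmonic in range(1, 4):
            amp = rng.uniform(0.5, 1.5) * spec.class_separation / (2 * harmonic)
            phase = rng.uniform(0, 2 * np.pi)
            curve += amp * np.sin(2 * np.pi * harmonic * t + phase)
        spectra[k] = offsets[k] + curve
    return np.clip(spectra, 0.05, 0.95)


def shading_field(spec: SceneSpec) -> np.ndarray:
    """Per-pixel mixing weight toward the shadow signature, in [0, 0.95].

    The positive part of a smoothed Gaussian field at ``shade_scale`` forms
    irregular blotches emulating within-crown branch shadows and the
    two-sided illumination of real canopies; the same field darkens both the
    cube and the guidance image, so this sub-region structure is visible to
    the edge-preserving filters. Zero when ``shade_amp`` is 0.
    """
    if spec.shade_amp == 0:
        return np.zeros(spec.shape)
    rng = _rng(spec, 5)
    field = ndimage.gaussian_filter(
        rng.standard_normal(spec.shape), spec.shade_scale, mode="reflect"
    )
    field /= field.std()
    return np.clip(np.clip(field, 0.0, None) * spec.shade_amp, 0.0, 0.95)


def _shadow_class(spec: SceneSpec) -> int | None:
    names = list(spec.class_names)
    return names.index("shadow") if "shadow" in names else None


def render_cube(labels: LabelMap, spec: SceneSpec) -> HyperspectralCube:
    """Render the hyperspectral cube for a label map.

    Pixel spectrum = class mean, shaded toward the shadow signature by the
    blotch field, plus band-correlated Gaussian noise; a band-wise spatial
    blur of width sigma_mix then emulates mixed boundary pixels; clipped to
    [0, 1].
    """
    if labels.values.shape != spec.shape:
        raise ValueError("label map shape does not match spec")
    if labels.values.max() >= spec.n_classes or labels.values.min() < 0:
        raise ValueError("label value outside spec class range")
    spectra = class_mean_spectra(spec)
    cube = spectra[labels.values]  # (H, W, B)
    if spec.shade_amp > 0:
        w = shading_field(spec)[:, :, None]
        shadow = _shadow_class(spec)
        dark = spectra[shadow] if shadow is not None else 0.0
        cube = (1 - w) * cube + w * dark
    if spec.noise_sigma > 0:
        rng = _rng(spec, 2)
        noise = rng.standard_normal(cube.shape)
        if spec.band_noise_corr > 0:
            noise = ndimage.gaussian_filter1d(
                noise, spec.band_noise_corr, axis=2, mode="reflect"
            )
            noise /= noise.std()
        cube = cube + spec.noise_sigma * noise
    if spec.sigma_mix > 0:
        cube = ndimage.gaussian_filter(
            cube, sigma=(spec.sigma_mix, spec.sigma_mix, 0), mode="reflect"
        )
    return HyperspectralCube(
        np.clip(cube, 0.0, 1.0), wavelengths_nm=spec.wavelengths_nm
    )


def render_guidance(labels: LabelMap, spec: SceneSpec) -> GuidanceImage:
    """Render the sharp 3-channel guidance image for a label map.

    Per-class colors darkened by the same shading field as the cube, a
    small edge blur (strictly below the cube's sigma_mix), and an optional
    sub-pixel misregistration shift.
    """
    if labels.values.shape != spec.shape:
        raise ValueError("label map shape does not match spec")
    colors = _DEFAULT_COLORS
    if spec.n_classes > len(colors):
        rng = _rng(spec, 3)
        extra = rng.uniform(0.1, 0.9, size=(spec.n_classes - len(colors), 3))
        colors = np.vstack([colors, extra])
    img = colors[labels.values]  # (H, W, 3)
    if spec.shade_amp > 0:
        w = shading_field(spec)[:, :, None]
        shadow = _shadow_class(spec)
        dark = colors[shadow] if shadow is not None else 0.0
        img = (1 - w) * img + w * dark
    if spec.guidance_blur > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(spec.guidance_blur, spec.guidance_blur, 0), mode="reflect"
        )
    if any(spec.guidance_shift):
        dy, dx = spec.guidance_shift
        img = ndimage.shift(img, (dy, dx, 0), order=1, mode="reflect")
    return GuidanceImage(np.clip(img, 0.0, 1.0), provenance="synthetic")


def sample_points(
    labels: LabelMap,
    n_per_class: int = 1250,
    train_fraction: float = 0.75,
    seed: int = 0,
) -> SampleSet:
    """Stratified pixel sampling with a per-class 3:1 train/verify split.

    Draws ``n_per_class`` distinct pixels from each class (without
    replacement) and assigns the first 75% of a seeded shuffle to training.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    h, w = labels.values.shape
    rows_all, cols_all, cls_all, roles_all = [], [], [], []
    for k in range(labels.n_classes):
        flat = np.flatnonzero(labels.values.ravel() == k)
        if len(flat) < n_per_class:
            raise ValueError(
                f"class {k} has only {len(flat)} pixels, need {n_per_class}"
            )
        chosen = rng.choice(flat, size=n_per_class, replace=False)
        n_train = int(round(train_fraction * n_per_class))
        roles = np.array(
            [TRAINING] * n_train + [VERIFICATION] * (n_per_class - n_train),
            dtype=object,
        )
        rows_all.append(chosen // w)
        cols_all.append(chosen % w)
        cls_all.append(np.full(n_per_class, k))
        roles_all.append(roles)
    return SampleSet(
        np.concatenate(rows_all),
        np.concatenate(cols_all),
        np.concatenate(cls_all),
        np.concatenate(roles_all),
        raster_shape=(h, w),
        legend=labels.legend,
    )


def make_scene(
    spec: SceneSpec | None = None, **overrides
) -> tuple[LabelMap, HyperspectralCube, GuidanceImage]:
    """Convenience wrapper: labels, cube and guidance for one spec."""
    if spec is None:
        spec = SceneSpec(**overrides)
    elif overrides:
        spec = replace(spec, **overrides)
    labels = generate_label_map(spec)
    return labels, render_cube(labels, spec), render_guidance(labels, spec)
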