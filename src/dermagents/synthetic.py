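"""Seeded synthetic dermoscopy-like lesion images and pseudo-sequences.

The generator draws an elliptical lesion whose boundary radius is perturbed
by a small Fourier series: a first-harmonic term produces asymmetry, higher
harmonics produce border irregularity, and interior Voronoi color sites
produce color heterogeneity. Malignant-class parameter ranges strictly
dominate the benign ranges on all three axes, so the two classes are
separable by construction and every image carries its ground-truth feature
record.

Pseudo-sequences emulate longitudinal lesion evolution from a single
timepoint: three frames (t-2, t-1, t) with a per-sequence area growth rate
drawn from 5-15% per step and an interior darkening rate from 3-10% per
step, both measured on the rasterized mask (pixel counts and interior mean
intensity) rather than on the continuous boundary, and calibrated so the
measured statistics match the drawn rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DomainError

IMAGE_SIZE = 224


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassParams:
    """Sampling ranges for one diagnostic class."""

    radius: tuple[float, float]
    eccentricity: tuple[float, float]
    border_amp: tuple[float, float]
    asymmetry: tuple[float, float]
    n_colors: tuple[int, int]
    base_color: tuple[tuple[float, float], ...]  # per-channel (lo, hi)
    structures_prob: float


BENIGN = ClassParams(
    radius=(28.0, 40.0),
    eccentricity=(1.0, 1.3),
    border_amp=(0.0, 0.05),
    asymmetry=(0.0, 0.06),
    n_colors=(1, 2),
    base_color=((0.50, 0.62), (0.34, 0.44), (0.26, 0.36)),
    structures_prob=0.10,
)

MALIGNANT = ClassParams(
    radius=(30.0, 46.0),
    eccentricity=(1.3, 2.1),
    border_amp=(0.10, 0.22),
    asymmetry=(0.15, 0.35),
    n_colors=(3, 5),
    base_color=((0.28, 0.40), (0.16, 0.26), (0.12, 0.22)),
    structures_prob=0.70,
)


@dataclass(frozen=True)
class GeneratorConfig:
    image_size: int = IMAGE_SIZE
    background_color: tuple[float, float, float] = (0.86, 0.67, 0.60)
    background_noise: float = 0.015
    texture_noise: float = 0.012
    class_params: tuple[ClassParams, ...] = (BENIGN, MALIGNANT)

    @property
    def n_classes(self) -> int:
        return len(self.class_params)


DEFAULT_CONFIG = GeneratorConfig()


# ---------------------------------------------------------------------------
# parametric lesion description
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LesionGeometry:
    """Polar boundary model: ellipse radius times Fourier perturbations."""

    center: tuple[float, float]  # (row, col)
    radius: float
    eccentricity: float
    angle: float
    border_harmonics: tuple[tuple[int, float, float], ...]  # (k, amp, phase)
    asymmetry: tuple[float, float]  # (amp, phase), first harmonic
    scale: float = 1.0

    def boundary_radius(self, theta: np.ndarray) -> np.ndarray:
        a = self.radius * math.sqrt(self.eccentricity)
        b = self.radius / math.sqrt(self.eccentricity)
        tr = theta - self.angle
        r = a * b / np.sqrt((b * np.cos(tr)) ** 2 + (a * np.sin(tr)) ** 2)
        mod = np.ones_like(theta)
        for k, amp, phase in self.border_harmonics:
            mod += amp * np.cos(k * theta + phase)
        amp1, phase1 = self.asymmetry
        mod += amp1 * np.cos(theta + phase1)
        return self.scale * r * np.clip(mod, 0.2, None)


@dataclass(frozen=True)
class LesionAppearance:
    base_color: tuple[float, float, float]
    site_offsets: tuple[tuple[float, float], ...]  # relative to center, units of R
    site_colors: tuple[tuple[float, float, float], ...]
    structures: bool
    structure_sites: tuple[tuple[float, float], ...]
    texture_seed: int
    intensity_scale: float = 1.0


@dataclass
class LesionImage:
    """One 224x224 RGB lesion image with label, mask and provenance."""

    pixels: np.ndarray  # (H, W, 3) float64 in [0, 1]
    label: int
    lesion_mask: np.ndarray  # (H, W) bool
    seed: int
    features: dict | None = None
    geometry: LesionGeometry | None = None
    appearance: LesionAppearance | None = None
    sequence_id: int | None = None
    timestep: int | None = None


@dataclass
class LesionSequence:
    """Three-frame pseudo-longitudinal series (t-2, t-1, t)."""

    frames: list[LesionImage]
    area_growth_per_step: float
    darkening_per_step: float

    @property
    def label(self) -> int:
        return self.frames[0].label


# ---------------------------------------------------------------------------
# rasterization / rendering
# ---------------------------------------------------------------------------

def _polar_grid(center: tuple[float, float], size: int):
    rows = np.arange(size)[:, None] - center[0]
    cols = np.arange(size)[None, :] - center[1]
    rho = np.hypot(rows, cols)
    theta = np.arctan2(rows, cols)
    return rho, theta


def rasterize_mask(geometry: LesionGeometry, size: int = IMAGE_SIZE) -> np.ndarray:
    rho, theta = _polar_grid(geometry.center, size)
    return rho <= geometry.boundary_radius(theta)


def render(
    geometry: LesionGeometry,
    appearance: LesionAppearance,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Render (pixels, mask) deterministically from a parametric lesion."""
    size = config.image_size
    noise_rng = np.random.default_rng(appearance.texture_seed)
    bg = np.empty((size, size, 3))
    bg[:] = config.background_color
    bg += ndimage.gaussian_filter(
        noise_rng.normal(0.0, config.background_noise * 3, size=(size, size, 3)),
        sigma=(2.0, 2.0, 0.0),
    )

    mask = rasterize_mask(geometry, size)
    rho, theta = _polar_grid(geometry.center, size)
    boundary = geometry.boundary_radius(theta)

    pixels = bg
    if mask.any():
        colors = np.array(appearance.base_color)
        lesion_rgb = np.empty((mask.sum(), 3))
        lesion_rgb[:] = colors
        if appearance.site_offsets:
            rr, cc = np.nonzero(mask)
            sites = np.array(
                [
                    (
                        geometry.center[0] + dy * geometry.radius * geometry.scale,
                        geometry.center[1] + dx * geometry.radius * geometry.scale,
                    )
                    for dy, dx in appearance.site_offsets
                ]
            )
            d2 = (rr[:, None] - sites[None, :, 0]) ** 2 + (
                cc[:, None] - sites[None, :, 1]
            ) ** 2
            nearest = np.argmin(d2, axis=1)
            lesion_rgb = np.array(appearance.site_colors)[nearest]
        # slight radial lightening toward the rim, as in real lesions
        rel = np.clip(rho[mask] / np.maximum(boundary[mask], 1e-9), 0.0, 1.0)
        lesion_rgb = lesion_rgb * (0.88 + 0.18 * rel)[:, None]
        lesion_rgb += noise_rng.normal(0.0, config.texture_noise, size=lesion_rgb.shape)
        if appearance.structures:
            rr, cc = np.nonzero(mask)
            for dy, dx in appearance.structure_sites:
                sy = geometry.center[0] + dy * geometry.radius * geometry.scale
                sx = geometry.center[1] + dx * geometry.radius * geometry.scale
                close = (rr - sy) ** 2 + (cc - sx) ** 2 < 2.5**2
                lesion_rgb[close] *= 0.45
        lesion_rgb *= appearance.intensity_scale
        pixels = bg.copy()
        pixels[mask] = lesion_rgb
    return np.clip(pixels, 0.0, 1.0), mask


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_lesion(
    class_id: int,
    seed: int,
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> LesionImage:
    """Generate one seeded lesion image for the given class.

    Deterministic for fixed ``(class_id, seed, config)``.
    """
    if not 0 <= class_id < config.n_classes:
        raise DomainError(
            f"class_id must be in [0, {config.n_classes - 1}], got {class_id}"
        )
    rng = np.random.default_rng((seed, class_id, 0xD3A))
    p = config.class_params[class_id]
    size = config.image_size

    center = (
        size / 2 + rng.uniform(-10, 10),
        size / 2 + rng.uniform(-10, 10),
    )
    border_amp = rng.uniform(*p.border_amp)
    harmonics = tuple(
        (k, border_amp * rng.uniform(0.5, 1.0) / math.sqrt(k - 1), rng.uniform(0, 2 * math.pi))
        for k in range(2, 7)
    )
    asym_amp = rng.uniform(*p.asymmetry)
    geometry = LesionGeometry(
        center=center,
        radius=rng.uniform(*p.radius),
        eccentricity=rng.uniform(*p.eccentricity),
        angle=rng.uniform(0, math.pi),
        border_harmonics=harmonics,
        asymmetry=(asym_amp, rng.uniform(0, 2 * math.pi)),
    )

    n_colors = int(rng.integers(p.n_colors[0], p.n_colors[1] + 1))
    base = tuple(rng.uniform(lo, hi) for lo, hi in p.base_color)
    site_offsets: tuple = ()
    site_colors: tuple = (base,)
    if n_colors > 1:
        site_offsets = tuple(
            (rng.uniform(-0.6, 0.6), rng.uniform(-0.6, 0.6)) for _ in range(n_colors)
        )
        site_colors = tuple(
            tuple(np.clip(np.array(base) * rng.uniform(0.55, 1.45), 0.02, 0.78))
            for _ in range(n_colors)
        )
    structures = bool(rng.random() < p.structures_prob)
    appearance = LesionAppearance(
        base_color=base,
        site_offsets=site_offsets,
        site_colors=site_colors,
        structures=structures,
        structure_sites=tuple(
            (rng.uniform(-0.55, 0.55), rng.uniform(-0.55, 0.55)) for _ in range(24)
        ),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )

    pixels, mask = render(geometry, appearance, config)
    features = {
        "asymmetry": asym_amp,
        "border_irregularity": border_amp,
        "n_colors": n_colors,
        "structures": structures,
    }
    return LesionImage(
        pixels=pixels,
        label=class_id,
        lesion_mask=mask,
        seed=seed,
        features=features,
        geometry=geometry,
        appearance=appearance,
    )


# ---------------------------------------------------------------------------
# measured morphology (used for real images and for validating the generator)
# ---------------------------------------------------------------------------

def mask_asymmetry(mask: np.ndarray) -> float:
    """1 - overlap of the mask with its 180-degree rotation about the centroid."""
    if not mask.any():
        raise DomainError("empty mask")
    rr, cc = np.nonzero(mask)
    cy, cx = rr.mean(), cc.mean()
    h, w = mask.shape
    shifted = ndimage.shift(
        mask.astype(float), (h / 2 - cy, w / 2 - cx), order=0, mode="constant"
    )
    rotated = shifted[::-1, ::-1]
    inter = np.logical_and(shifted > 0.5, rotated > 0.5).sum()
    return 1.0 - inter / max((shifted > 0.5).sum(), 1)


def border_irregularity(mask: np.ndarray) -> float:
    """Isoperimetric deficit P^2 / (4 pi A) - 1 of the mask boundary."""
    if not mask.any():
        raise DomainError("empty mask")
    eroded = ndimage.binary_erosion(mask)
    perimeter = float((mask & ~eroded).sum())
    area = float(mask.sum())
    return perimeter**2 / (4.0 * math.pi * area) - 1.0


def mask_eccentricity(mask: np.ndarray) -> float:
    """sqrt of the ratio of principal second moments of the mask."""
    rr, cc = np.nonzero(mask)
    y = rr - rr.mean()
    x = cc - cc.mean()
    cov = np.cov(np.stack([y, x]))
    eig = np.sort(np.linalg.eigvalsh(cov))
    return float(np.sqrt(eig[1] / max(eig[0], 1e-9)))


def mean_interior_intensity(image: LesionImage) -> float:
    return float(image.pixels[image.lesion_mask].mean())


# ---------------------------------------------------------------------------
# pseudo-sequences
# ---------------------------------------------------------------------------

def _calibrated_scale(
    geometry: LesionGeometry,
    prev_area: int,
    growth: float,
    size: int,
) -> LesionGeometry:
    """Find the radial scale whose rasterized area best matches prev_area*(1+growth).

    The measured pixel-count ratio is kept inside [1.05, 1.15] whenever the
    drawn growth rate lies in that band (rasterization granularity would
    otherwise let a boundary draw fall just outside).
    """
    target = int(round(prev_area * (1.0 + growth)))
    lo_band = math.ceil(prev_area * 1.05)
    hi_band = math.floor(prev_area * 1.15)
    if lo_band <= hi_band and 0.05 <= growth <= 0.15:
        target = min(max(target, lo_band), hi_band)

    # the boundary radius is linear in the scale, so the area at scale s is
    # #{pixels : rho/f(theta) <= s}; the exact scale for `target` pixels sits
    # between the target-th and next order statistics of rho/f(theta)
    rho, theta = _polar_grid(geometry.center, size)
    f = replace(geometry, scale=1.0).boundary_radius(theta)
    ratios = np.sort((rho / np.maximum(f, 1e-12)).ravel())
    target = min(target, ratios.size - 1)
    scale = 0.5 * (ratios[target - 1] + ratios[target])
    return replace(geometry, scale=scale)


def make_pseudo_sequence(
    base: LesionImage,
    seed: int,
    growth_range: tuple[float, float] = (0.05, 0.15),
    darkening_range: tuple[float, float] = (0.03, 0.10),
    config: GeneratorConfig = DEFAULT_CONFIG,
) -> LesionSequence:
    """Build a 3-frame pseudo-sequence from a generated lesion.

    One growth rate and one darkening rate are drawn per sequence (a
    gradual, consistent trend); each later frame's mask area is larger by
    the growth factor and its interior mean intensity smaller by the
    darkening factor, both measured on the rendered frame.
    """
    if not base.lesion_mask.any():
        raise DomainError("base lesion has an empty mask")
    if base.geometry is None or base.appearance is None:
        raise DomainError("base image does not carry generator parameters")

    rng = np.random.default_rng((seed, 0x5EC))
    growth = float(rng.uniform(*growth_range))
    darkening = float(rng.uniform(*darkening_range))

    frames = [
        LesionImage(
            pixels=base.pixels.copy(),
            label=base.label,
            lesion_mask=base.lesion_mask.copy(),
            seed=base.seed,
            features=dict(base.features) if base.features else None,
            geometry=base.geometry,
            appearance=base.appearance,
            timestep=0,
        )
    ]
    geometry = base.geometry
    for step in (1, 2):
        prev = frames[-1]
        if growth == 0.0 and darkening == 0.0:
            frame_pixels, frame_mask = prev.pixels.copy(), prev.lesion_mask.copy()
            frames.append(
                replace_frame(prev, frame_pixels, frame_mask, geometry, step)
            )
            continue
        prev_area = int(prev.lesion_mask.sum())
        geometry = _calibrated_scale(geometry, prev_area, growth, config.image_size)
        pixels, mask = render(geometry, base.appearance, config)
        # exact darkening: rescale interior so the measured mean-intensity
        # ratio equals (1 - darkening) per step
        target_mean = mean_interior_intensity(prev) * (1.0 - darkening)
        current_mean = float(pixels[mask].mean())
        pixels[mask] *= target_mean / current_mean
        frames.append(replace_frame(prev, pixels, mask, geometry, step))

    return LesionSequence(
        frames=frames,
        area_growth_per_step=growth,
        darkening_per_step=darkening,
    )


def replace_frame(
    prev: LesionImage,
    pixels: np.ndarray,
    mask: np.ndarray,
    geometry: LesionGeometry,
    timestep: int,
) -> LesionImage:
    return LesionImage(
        pixels=pixels,
        label=prev.label,
        lesion_mask=mask,
        seed=prev.seed,
        features=dict(prev.features) if prev.features else None,
        geometry=geometry,
        appearance=prev.appearance,
        timestep=timestep,
    )


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    p_hflip: float = 0.5
    p_vflip: float = 0.5
    max_rotation_deg: float = 20.0
    brightness: tuple[float, float] = (0.9, 1.1)
    contrast: tuple[float, float] = (0.9, 1.1)
    hue: tuple[float, float] = (0.9, 1.1)


DEFAULT_AUGMENT = AugmentConfig()


def hflip(image: LesionImage) -> LesionImage:
    return LesionImage(
        pixels=image.pixels[:, ::-1].copy(),
        label=image.label,
        lesion_mask=image.lesion_mask[:, ::-1].copy(),
        seed=image.seed,
        features=dict(image.features) if image.features else None,
    )


def vflip(image: LesionImage) -> LesionImage:
    return LesionImage(
        pixels=image.pixels[::-1].copy(),
        label=image.label,
        lesion_mask=image.lesion_mask[::-1].copy(),
        seed=image.seed,
        features=dict(image.features) if image.features else None,
    )


def augment(
    image: LesionImage,
    seed: int,
    config: AugmentConfig = DEFAULT_AUGMENT,
) -> LesionImage:
    """Random flips, rotation within +/-20 degrees and +/-10% color jitter.

    The lesion mask is transformed consistently with the pixels and the
    label is never altered.
    """
    rng = np.random.default_rng((seed, 0xAA6))
    out = image
    if rng.random() < config.p_hflip:
        out = hflip(out)
    if rng.random() < config.p_vflip:
        out = vflip(out)
    angle = float(rng.uniform(-config.max_rotation_deg, config.max_rotation_deg))
    pixels = out.pixels
    mask = out.lesion_mask
    if angle != 0.0:
        pixels = ndimage.rotate(pixels, angle, axes=(1, 0), reshape=False, order=1, mode="nearest")
        mask = (
            ndimage.rotate(mask.astype(float), angle, axes=(1, 0), reshape=False, order=0, mode="constant")
            > 0.5
        )
    b = float(rng.uniform(*config.brightness))
    c = float(rng.uniform(*config.contrast))
    hfac = float(rng.uniform(*config.hue))
    pixels = pixels * b
    gray = pixels.mean()
    pixels = (pixels - gray) * c + gray
    if hfac != 1.0:
        from matplotlib.colors import hsv_to_rgb, rgb_to_hsv

        hsv = rgb_to_hsv(np.clip(pixels, 0.0, 1.0))
        hsv[..., 0] = np.mod(hsv[..., 0] * hfac, 1.0)
        pixels = hsv_to_rgb(hsv)
    return LesionImage(
        pixels=np.clip(pixels, 0.0, 1.0),
        label=image.label,
        lesion_mask=mask,
        seed=image.seed,
        features=dict(image.features) if image.features else None,
    )
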