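"""BraTS-like 2-D phantom generation.

Each phantom is a single-channel intensity image plus a 4-class label mask
(0 background, 1 necrotic/non-enhancing core, 2 edema, 3 enhancing rim). With
probability ``tumor_probability`` a slice contains a nested lesion: an edema
region enclosing a tumor core whose interior is necrotic and whose rim
enhances. Region outlines are ellipses deformed by a low-order radial Fourier
perturbation shared across the three nested boundaries, so nesting holds by
construction. Intensities are drawn per class from Gaussian distributions,
modulated by a smooth multiplicative bias field (mimicking MRI coil
inhomogeneity), perturbed with additive Gaussian noise, and clipped to [0, 1].

The defaults aim at a FLAIR-like contrast: edema bright, enhancing rim
brightest, necrosis dark, on a mid-gray background. A 4-channel
pseudo-modality mode provides FLAIR/T1/T1ce/T2-like contrasts of the same
anatomy for experimentation.

Determinism: phantom ``index`` under ``spec.seed`` is bitwise reproducible —
the RNG is keyed on ``(seed, index)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["PhantomSpec", "PhantomPair", "generate_phantom", "generate_arrays",
           "generate_dataset", "split_counts", "MODALITY_CONTRASTS"]

# per-modality class intensity means (background, necrosis, edema, enhancing)
MODALITY_CONTRASTS = {
    "flair": (0.35, 0.15, 0.70, 0.80),
    "t1": (0.55, 0.25, 0.40, 0.50),
    "t1ce": (0.45, 0.15, 0.50, 0.90),
    "t2": (0.40, 0.60, 0.75, 0.55),
}


@dataclass
class PhantomSpec:
    """Generator configuration; defaults emulate FLAIR-like tumor slices."""

    image_size: tuple[int, int] = (128, 128)
    tumor_probability: float = 0.8
    whole_radius: tuple[float, float] = (0.18, 0.32)   # fractions of min(H, W)
    core_radius: tuple[float, float] = (0.40, 0.65)    # fractions of whole radius
    enhancing_radius: tuple[float, float] = (0.35, 0.60)  # fractions of core radius
    class_means: tuple[float, ...] = (0.35, 0.15, 0.70, 0.80)
    class_stds: tuple[float, ...] = (0.02, 0.02, 0.02, 0.02)
    bias_field_amplitude: float = 0.08
    noise_sigma: float = 0.02
    seed: int = 0
    channels: int = 1  # 1 or 4 (pseudo-modalities)

    def __post_init__(self):
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ConfigurationError("image_size must be at least 16x16")
        if not 0.0 <= self.tumor_probability <= 1.0:
            raise ConfigurationError("tumor_probability must be in [0, 1]")
        for name, (lo, hi) in (("whole_radius", self.whole_radius),
                               ("core_radius", self.core_radius),
                               ("enhancing_radius", self.enhancing_radius)):
            if not (0.0 < lo <= hi):
                raise ConfigurationError(f"{name} range invalid: ({lo}, {hi})")
        if self.core_radius[1] >= 1.0 or self.enhancing_radius[1] >= 1.0:
            raise ConfigurationError(
                "core and enhancing radii are fractions of the enclosing "
                "region and must stay below 1 to preserve nesting")
        if len(self.class_means) != 4 or len(self.class_stds) != 4:
            raise ConfigurationError("class_means/class_stds must have 4 entries")
        if any(not 0.0 <= m <= 1.0 for m in self.class_means):
            raise ConfigurationError("class means must lie in [0, 1]")
        if self.noise_sigma < 0 or any(s < 0 for s in self.class_stds):
            raise ConfigurationError("noise levels must be non-negative")
        if self.channels not in (1, 4):
            raise ConfigurationError("channels must be 1 or 4")


@dataclass
class PhantomPair:
    image: np.ndarray  # (H, W, C) float32 in [0, 1]
    mask: np.ndarray   # (H, W) int labels 0..3


def _radial_deformation(rng: np.random.Generator, theta: np.ndarray) -> np.ndarray:
    """1 + small sum of random cos harmonics (orders 3-5), bounded below."""
    d = np.ones_like(theta)
    for h in (3, 4, 5):
        amp = rng.uniform(0.0, 0.12 / math.sqrt(h))
        phase = rng.uniform(0.0, 2 * math.pi)
        d += amp * np.cos(h * theta + phase)
    return np.maximum(d, 0.5)


def _bias_field(rng: np.random.Generator, h: int, w: int,
                amplitude: float) -> np.ndarray:
    """Smooth multiplicative field 1 + a * P(i, j), |P| <= 1, P quadratic."""
    if amplitude == 0.0:
        return np.ones((h, w), dtype=np.float32)
    yy, xx = np.meshgrid(np.linspace(-1, 1, h), np.linspace(-1, 1, w),
                         indexing="ij")
    coef = rng.uniform(-1, 1, size=6)
    poly = (coef[0] + coef[1] * yy + coef[2] * xx + coef[3] * yy * xx
            + coef[4] * yy ** 2 + coef[5] * xx ** 2)
    poly /= max(np.abs(poly).max(), 1e-9)
    return (1.0 + amplitude * poly).astype(np.float32)


def _tumor_mask(rng: np.random.Generator, spec: PhantomSpec) -> np.ndarray:
    h, w = spec.image_size
    mask = np.zeros((h, w), dtype=np.int64)
    r_wt = rng.uniform(*spec.whole_radius) * min(h, w)
    r_tc = rng.uniform(*spec.core_radius) * r_wt
    r_en = rng.uniform(*spec.enhancing_radius) * r_tc  # necrosis boundary
    margin = r_wt * 1.3
    cy = rng.uniform(margin, h - margin) if h > 2 * margin else h / 2
    cx = rng.uniform(margin, w - margin) if w > 2 * margin else w / 2
    # anisotropy + rotation shared by all nested boundaries
    sx = rng.uniform(0.7, 1.3)
    sy = rng.uniform(0.7, 1.3)
    rot = rng.uniform(0.0, math.pi)
    yy, xx = np.meshgrid(np.arange(h) - cy, np.arange(w) - cx, indexing="ij")
    u = (xx * math.cos(rot) + yy * math.sin(rot)) / sx
    v = (-xx * math.sin(rot) + yy * math.cos(rot)) / sy
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    deform = _radial_deformation(rng, theta)
    mask[rho <= r_wt * deform] = 2                    # edema (whole tumor)
    mask[rho <= r_tc * deform] = 3                    # core: enhancing rim...
    mask[rho <= r_en * deform] = 1                    # ...around necrosis
    return mask


def generate_phantom(spec: PhantomSpec, index: int) -> PhantomPair:
    """Deterministically generate phantom ``index`` under ``spec``."""
    rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, int(index)])
    h, w = spec.image_size
    has_tumor = rng.uniform() < spec.tumor_probability
    mask = _tumor_mask(rng, spec) if has_tumor \
        else np.zeros((h, w), dtype=np.int64)

    contrasts = [spec.class_means] if spec.channels == 1 else [
        MODALITY_CONTRASTS[m] for m in ("flair", "t1", "t1ce", "t2")]
    bias = _bias_field(rng, h, w, spec.bias_field_amplitude)
    channels = []
    for means in contrasts:
        mean_map = np.asarray(means, dtype=np.float32)[mask]
        std_map = np.asarray(spec.class_stds, dtype=np.float32)[mask]
        img = mean_map + std_map * rng.standard_normal((h, w)).astype(np.float32)
        img *= bias
        if spec.noise_sigma > 0:
            img += spec.noise_sigma * rng.standard_normal((h, w)).astype(np.float32)
        channels.append(img)
    image = np.clip(np.stack(channels, axis=-1), 0.0, 1.0).astype(np.float32)
    return PhantomPair(image=image, mask=mask)


def generate_arrays(spec: PhantomSpec, n: int,
                    start_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Stack ``n`` phantoms into ``(images (n,H,W,C), masks (n,H,W))``."""
    pairs = [generate_phantom(spec, start_index + i) for i in range(n)]
    return (np.stack([p.image for p in pairs]),
            np.stack([p.mask for p in pairs]))


def split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of ``n`` items into three splits."""
    if abs(sum(fractions) - 1.0) > 1e-6:
        raise ConfigurationError(f"split fractions must sum to 1: {fractions}")
    raw = [n * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for _ in range(n - sum(counts)):
        i = int(np.argmax(remainders))
        counts[i] += 1
        remainders[i] = -1.0
    return tuple(counts)


def generate_dataset(spec: PhantomSpec, n: int, out_dir,
                     split: tuple[float, float, float] = (0.68, 0.20, 0.12)):
    """Write ``n`` phantoms as 16-bit PNGs with a train/val/test manifest.

    The default split mirrors a 425:125:75 train/validation/test proportion.
    Each phantom belongs to exactly one split. Returns a
    :class:`~gnet.io_formats.DatasetManifest`.
    """
    from . import io_formats  # local import to keep module load light

    if n < 3:
        raise ConfigurationError("need at least one phantom per split")
    counts = split_counts(n, split)
    tags = (["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2])
    return io_formats.write_phantom_dataset(spec, n, tags, out_dir)
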