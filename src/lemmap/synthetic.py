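"""Seeded synthetic lesion images with labels and pixel ground-truth masks.

Each generated image contains exactly one small lesion on a textured
background, emulating the weakly supervised regime the method targets: the
lesion occupies only a tiny fraction of the image (at most ``max_fraction``,
default 5%), so dense pooling of the whole image dilutes the signal.

* class 0 (benign): radially smooth Gaussian bump, low contrast;
* class 1 (malignant): Gaussian core plus 5-9 radial spicule ridges,
  higher contrast — a shape/contrast signal loosely analogous to mass
  morphology, with no claim of radiological realism.

Background is a sum of three low-frequency cosine gratings with random
orientation/phase plus i.i.d. Gaussian noise, so images are not trivially
thresholdable.  The ground-truth mask is the set of pixels where the additive
lesion field exceeds 15% of the lesion's contrast; it is used only for
localization scoring, never for training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionSpec",
    "LabeledImage",
    "AugmentParams",
    "generate_dataset",
    "sample_augment_params",
    "augment",
]

#: lesion core radius as a fraction of image side, [low, high]
_RADIUS_FRAC = (0.047, 0.070)
_MIN_RADIUS = 2.0
#: additive contrast ranges per class — separated enough that contrast (with
#: spicule shape) is learnable by a small from-scratch network
_CONTRAST_BENIGN = (0.10, 0.18)
_CONTRAST_MALIGNANT = (0.38, 0.60)
#: mask = lesion field > this fraction of contrast
_MASK_LEVEL = 0.15
#: spicules extend at most this many core radii from the centre
_SPICULE_REACH = 1.8


@dataclass(frozen=True)
class LesionSpec:
    center: tuple[float, float]  # (row, col), pixels
    radius: float  # core radius, pixels
    kind: str  # "benign" | "malignant"
    contrast: float  # additive amplitude in [0, 1]
    n_spicules: int = 0  # malignant only

    def __post_init__(self):
        if self.kind not in ("benign", "malignant"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        if self.radius < _MIN_RADIUS:
            raise ValueError(f"lesion radius must be >= {_MIN_RADIUS} px")
        if not (0.0 <= self.contrast <= 1.0):
            raise ValueError("contrast must lie in [0, 1]")
        if self.n_spicules < 0:
            raise ValueError("n_spicules must be >= 0")


@dataclass
class LabeledImage:
    pixels: np.ndarray  # (H, W) float in [0, 1]
    label: int  # 0 benign, 1 malignant
    mask: np.ndarray | None  # (H, W) bool ground truth, synthetic only
    id: str


def _lesion_field(spec: LesionSpec, size: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Additive intensity field of one lesion, zero away from it."""
    rr, cc = np.mgrid[0:size, 0:size].astype(float)
    dr = rr - spec.center[0]
    dc = cc - spec.center[1]
    dist = np.hypot(dr, dc)
    sig = spec.radius / 2.0
    field = spec.contrast * np.exp(-(dist ** 2) / (2.0 * sig ** 2))
    if spec.kind == "malignant" and spec.n_spicules > 0:
        theta = np.arctan2(dr, dc)
        reach = _SPICULE_REACH * spec.radius
        width = 0.18 * spec.radius
        base = rng.uniform(0.0, 2.0 * np.pi)
        angles = base + 2.0 * np.pi * np.arange(spec.n_spicules) / spec.n_spicules
        for ang in angles:
            # perpendicular distance from the ray at angle `ang`
            dperp = dist * np.abs(np.sin(theta - ang))
            along = dist * np.cos(theta - ang)
            ray = (along > 0) & (along <= reach)
            ridge = 0.7 * spec.contrast * np.exp(
                -(dperp ** 2) / (2.0 * width ** 2)) * np.exp(-along / (1.2 * spec.radius))
            field = np.maximum(field, np.where(ray, ridge, 0.0))
    return field


def _background(size: int, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    rr, cc = np.mgrid[0:size, 0:size].astype(float) / size
    bg = np.full((size, size), 0.35)
    for _ in range(3):
        theta = rng.uniform(0.0, np.pi)
        freq = rng.uniform(1.0, 3.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        amp = rng.uniform(0.02, 0.045)
        bg += amp * np.cos(2.0 * np.pi * freq * (rr * np.sin(theta) + cc * np.cos(theta)) + phase)
    bg += rng.normal(0.0, noise_sd, (size, size))
    return bg


def _sample_lesion(label: int, size: int, max_fraction: float,
                   rng: np.random.Generator) -> LesionSpec:
    lo = max(_MIN_RADIUS, _RADIUS_FRAC[0] * size)
    hi = max(lo, _RADIUS_FRAC[1] * size)
    radius = rng.uniform(lo, hi)
    support = np.ceil(max(2.2 * radius, _SPICULE_REACH * radius)) + 1.0
    if 2 * support >= size:
        raise ValueError(
            f"image size {size} too small to contain a lesion of radius {radius:.1f}"
        )
    center = tuple(rng.uniform(support, size - support, 2))
    if label == 1:
        return LesionSpec(center=center, radius=radius, kind="malignant",
                          contrast=rng.uniform(*_CONTRAST_MALIGNANT),
                          n_spicules=int(rng.integers(5, 10)))
    return LesionSpec(center=center, radius=radius, kind="benign",
                      contrast=rng.uniform(*_CONTRAST_BENIGN))


def generate_dataset(n: int, image_size: int = 64, class_balance: float = 0.5,
                     noise_sd: float = 0.02, seed: int = 0,
                     max_fraction: float = 0.05) -> list[LabeledImage]:
    """Generate ``n`` single-lesion images with exactly round(n * class_balance)
    malignant samples.  Identical arguments produce bit-identical output."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if image_size < 32:
        raise ValueError("image_size must be >= 32 to contain the minimum lesion")
    if not (0.0 <= class_balance <= 1.0):
        raise ValueError("class_balance must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_mal = round(n * class_balance)
    labels = np.array([1] * n_mal + [0] * (n - n_mal))
    rng.shuffle(labels)
    out: list[LabeledImage] = []
    for i, label in enumerate(labels):
        spec = _sample_lesion(int(label), image_size, max_fraction, rng)
        field = _lesion_field(spec, image_size, rng)
        pixels = np.clip(_background(image_size, noise_sd, rng) + field, 0.0, 1.0)
        mask = field > _MASK_LEVEL * spec.contrast
        frac = mask.mean()
        if not mask.any() or frac > max_fraction:
            raise RuntimeError(
                f"lesion mask fraction {frac:.3f} violates (0, {max_fraction}]"
            )
        out.append(LabeledImage(pixels=pixels, label=int(label), mask=mask,
                                id=f"syn-{i:05d}"))
    return out


# ---------------------------------------------------------------------------
# augmentation


@dataclass(frozen=True)
class AugmentParams:
    """One sampled augmentation: flip, rotation (degrees), contrast factor,
    gamma exponent (single-channel analogue of a saturation jitter) and
    additive noise level."""

    flip: bool = False
    angle: float = 0.0
    contrast: float = 1.0
    gamma: float = 1.0
    noise_sd: float = 0.0
    noise_seed: int = 0


def sample_augment_params(rng: np.random.Generator, *, flip: bool = True,
                          rotate: bool = True, contrast: bool = True,
                          gamma: bool = True, noise: bool = True) -> AugmentParams:
    """Draw one augmentation; rotation is uniform in [-30, +30] degrees."""
    return AugmentParams(
        flip=bool(rng.random() < 0.5) if flip else False,
        angle=float(rng.uniform(-30.0, 30.0)) if rotate else 0.0,
        contrast=float(rng.uniform(0.9, 1.1)) if contrast else 1.0,
        gamma=float(rng.uniform(0.9, 1.1)) if gamma else 1.0,
        noise_sd=0.01 if noise else 0.0,
        noise_seed=int(rng.integers(0, 2 ** 31)),
    )


def augment(image: LabeledImage, seed: int | None = None,
            params: AugmentParams | None = None) -> LabeledImage:
    """Label-preserving augmentation; the mask undergoes the same geometric
    transform as the pixels.  Pass explicit ``params`` (e.g. the defaults of
    :class:`AugmentParams`) for a deterministic — possibly identity —
    transform."""
    if params is None:
        params = sample_augment_params(np.random.default_rng(seed))
    px = image.pixels
    mask = image.mask
    if params.flip:
        px = px[:, ::-1]
        mask = mask[:, ::-1] if mask is not None else None
    if params.angle != 0.0:
        px = ndimage.rotate(px, params.angle, reshape=False, order=1, mode="nearest")
        if mask is not None:
            mask = ndimage.rotate(mask.astype(float), params.angle, reshape=False,
                                  order=0, mode="constant", cval=0.0) > 0.5
    if params.contrast != 1.0:
        m = px.mean()
        px = (px - m) * params.contrast + m
    px = np.clip(px, 0.0, 1.0)
    if params.gamma != 1.0:
        px = px ** params.gamma
    if params.noise_sd > 0.0:
        nrng = np.random.default_rng(params.noise_seed)
        px = px + nrng.normal(0.0, params.noise_sd, px.shape)
    px = np.clip(np.ascontiguousarray(px), 0.0, 1.0)
    mask = np.ascontiguousarray(mask) if mask is not None else None
    return replace(image, pixels=px, mask=mask)
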