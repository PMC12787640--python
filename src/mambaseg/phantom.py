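"""Synthetic breast-ultrasound phantoms with paired lesion masks.

The generator emulates the qualitative structure of clinical B-mode
images so the network and metrics can be exercised without any data
download: a smooth tissue-intensity field carrying multiplicative
gamma-distributed speckle, one or more hypoechoic (darkened) elliptical
lesions with Gaussian-blurred boundaries, and an optional acoustic-shadow
band below a lesion.  The binary mask records the pre-blur lesion support.

It makes no attempt at physical wave simulation; see docs/methods.md for
what this does and does not validate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.transform import resize

__all__ = ["PhantomSpec", "MaskPair", "generate_phantom", "augment",
           "make_dataset", "write_dataset", "load_dataset"]


@dataclass
class PhantomSpec:
    """Sampling ranges for one phantom; `seed` fixes the sample exactly."""

    image_size: int = 64
    lesion_count: tuple[int, int] = (1, 2)          # inclusive range
    lesion_radius: tuple[float, float] = (0.08, 0.22)  # fraction of image side
    intensity_drop: tuple[float, float] = (0.35, 0.65)  # hypoechoic contrast
    boundary_blur_sigma: float = 1.5                # px
    speckle_shape: float = 4.0                      # gamma shape (mean-1 noise)
    shadow_prob: float = 0.3
    shadow_strength: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 8:
            raise ValueError("image_size too small")
        if not (0 <= self.lesion_count[0] <= self.lesion_count[1]):
            raise ValueError("invalid lesion_count range")
        if not (0 < self.lesion_radius[0] <= self.lesion_radius[1] < 0.5):
            raise ValueError("lesion radius must lie in (0, 0.5) of the image")
        if self.speckle_shape <= 0:
            raise ValueError("speckle_shape must be positive")


@dataclass
class MaskPair:
    """A grayscale image in [0,1] with its binary lesion mask."""

    image: np.ndarray
    mask: np.ndarray

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask must share spatial dims")


def _ellipse_support(size: int, rng: np.random.Generator,
                     radius_range) -> np.ndarray:
    r_px = rng.uniform(*radius_range) * size
    aspect = rng.uniform(0.6, 1.0)
    theta = rng.uniform(0, np.pi)
    margin = int(np.ceil(r_px)) + 2
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    u = x * np.cos(theta) + y * np.sin(theta)
    v = -x * np.sin(theta) + y * np.cos(theta)
    return (u / r_px) ** 2 + (v / (r_px * aspect)) ** 2 <= 1.0


def generate_phantom(spec: PhantomSpec, seed: int | None = None) -> MaskPair:
    """Draw one phantom/mask pair; `seed` overrides spec.seed if given."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.image_size
    # smooth tissue field around 0.55 with gentle large-scale variation
    f = gaussian_filter(rng.standard_normal((n, n)), n / 8.0)
    base = 0.55 + 0.08 * f / (f.std() + 1e-8)
    base = np.clip(base, 0.2, 0.85)

    k = int(rng.integers(spec.lesion_count[0], spec.lesion_count[1] + 1))
    mask = np.zeros((n, n), dtype=bool)
    attenuation = np.ones((n, n))
    for _ in range(k):
        support = _ellipse_support(n, rng, spec.lesion_radius)
        mask |= support
        drop = rng.uniform(*spec.intensity_drop)
        soft = gaussian_filter(support.astype(float), spec.boundary_blur_sigma)
        attenuation *= 1.0 - drop * soft
        if rng.uniform() < spec.shadow_prob:
            cols = support.any(axis=0)
            bottom = np.where(support.any(axis=1))[0].max()
            falloff = np.zeros((n, 1))
            rows = np.arange(n)
            below = rows > bottom
            falloff[below, 0] = np.exp(-(rows[below] - bottom) / (0.5 * n))
            attenuation *= 1.0 - spec.shadow_strength * falloff * cols[None, :]

    img = base * attenuation
    speckle = rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, size=(n, n))
    img = np.clip(img * speckle, 0.0, 1.0).astype(np.float32)
    return MaskPair(image=img, mask=mask.astype(np.uint8))


def augment(pair: MaskPair, seed: int, out_size: int | None = None,
            crop_frac: tuple[float, float] = (0.8, 1.0)) -> MaskPair:
    """Random horizontal/vertical flip plus random crop (re-resized).

    The identical geometric transform is applied to image and mask; the
    mask is resampled with nearest-neighbour so it stays binary.
    """
    if not (0 < crop_frac[0] <= crop_frac[1] <= 1.0):
        raise ValueError("crop fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    img, msk = pair.image, pair.mask
    H, W = img.shape
    if rng.uniform() < 0.5:
        img, msk = img[:, ::-1], msk[:, ::-1]
    if rng.uniform() < 0.5:
        img, msk = img[::-1, :], msk[::-1, :]
    frac = rng.uniform(*crop_frac)
    ch, cw = max(1, int(round(frac * H))), max(1, int(round(frac * W)))
    if ch > H or cw > W:
        raise ValueError("crop larger than image")
    oy = int(rng.integers(0, H - ch + 1))
    ox = int(rng.integers(0, W - cw + 1))
    img = img[oy:oy + ch, ox:ox + cw]
    msk = msk[oy:oy + ch, ox:ox + cw]
    size = out_size or H
    if (ch, cw) != (size, size):
        img = resize(img, (size, size), order=1, anti_aliasing=False,
                     preserve_range=True)
        msk = resize(msk.astype(float), (size, size), order=0,
                     anti_aliasing=False, preserve_range=True)
    return MaskPair(image=np.ascontiguousarray(img, dtype=np.float32),
                    mask=np.ascontiguousarray(msk > 0.5).astype(np.uint8))


def make_dataset(n: int, spec: PhantomSpec, split_ratio: float = 0.8,
                 ) -> tuple[list[MaskPair], list[MaskPair]]:
    """n seeded phantoms split deterministically train:test (default 8:2)."""
    if n < 5:
        raise ValueError("need at least 5 samples to split")
    if not 0 < split_ratio < 1:
        raise ValueError("split_ratio must lie in (0, 1)")
    pairs = [generate_phantom(spec, seed=spec.seed + i) for i in range(n)]
    order = np.random.default_rng(spec.seed).permutation(n)
    n_train = int(round(n * split_ratio))
    train = [pairs[i] for i in order[:n_train]]
    test = [pairs[i] for i in order[n_train:]]
    return train, test


def write_dataset(root, train: list[MaskPair], test: list[MaskPair],
                  spec: PhantomSpec | None = None) -> dict:
    """Write images/*.png + masks/*.png per split and a JSON manifest."""
    root = Path(root)
    manifest = {"n_train": len(train), "n_test": len(test),
                "spec": asdict(spec) if spec else None, "splits": {}}
    for split, pairs in (("train", train), ("test", test)):
        stems = []
        for i, pair in enumerate(pairs):
            stem = f"{split}_{i:04d}"
            img_dir = root / split / "images"
            msk_dir = root / split / "masks"
            img_dir.mkdir(parents=True, exist_ok=True)
            msk_dir.mkdir(parents=True, exist_ok=True)
            Image.fromarray((pair.image * 255).round().astype(np.uint8)).save(
                img_dir / f"{stem}.png")
            Image.fromarray(pair.mask * 255).save(msk_dir / f"{stem}.png")
            stems.append(stem)
        manifest["splits"][split] = stems
    (root / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


def load_dataset(root, split: str) -> list[MaskPair]:
    """Read a split back; accepts `<stem>.png` or the BUSI-style
    `<stem>_mask.png` naming inside masks/."""
    root = Path(root) / split
    img_dir, msk_dir = root / "images", root / "masks"
    pairs = []
    for img_path in sorted(img_dir.glob("*.png")):
        stem = img_path.stem
        for cand in (msk_dir / f"{stem}.png", msk_dir / f"{stem}_mask.png"):
            if cand.exists():
                break
        else:
            raise FileNotFoundError(f"no mask for {img_path}")
        img = np.asarray(Image.open(img_path).convert("L"), dtype=np.float32) / 255.0
        msk = (np.asarray(Image.open(cand).convert("L")) > 127).astype(np.uint8)
        pairs.append(MaskPair(image=img, mask=msk))
    return pairs
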