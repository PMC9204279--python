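"""CT preprocessing and label-consistent augmentation.

Pipeline for one slice: stored pixels -> HU (affine rescale) -> window/level
clipping to [0, 1] -> contrast-limited adaptive histogram equalization
(CLAHE).  The default window (level 60 HU, width 400 HU) is a soft-tissue
neck window that keeps thyroid tissue (~60-100 HU) well inside its linear
range.

Augmentation applies one geometric transform (rotation, horizontal flip,
zoom, shear) identically to the image (bilinear) and its mask (nearest
neighbor, re-binarized at 0.5), preserving the output shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

__all__ = [
    "WindowSpec",
    "AugmentSpec",
    "pixels_to_hu",
    "apply_window",
    "adaptive_hist_equalize",
    "augment_pair",
    "sample_augment_spec",
    "preprocess_slice",
]


@dataclass(frozen=True)
class WindowSpec:
    level: float = 60.0
    width: float = 400.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError(f"window width must be > 0, got {self.width}")


@dataclass(frozen=True)
class AugmentSpec:
    rotation_deg: float = 0.0
    flip_horizontal: bool = False
    zoom_factor: float = 1.0
    shear_deg: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.zoom_factor <= 0:
            raise ValueError(f"zoom_factor must be > 0, got {self.zoom_factor}")


def pixels_to_hu(raw, slope: float, intercept: float) -> np.ndarray:
    """HU = raw * slope + intercept, elementwise."""
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("slope and intercept must be finite")
    return np.asarray(raw, dtype=np.float64) * slope + intercept


def apply_window(hu, window: WindowSpec) -> np.ndarray:
    """Clip to [level - width/2, level + width/2] and map linearly to [0, 1]."""
    lo = window.level - window.width / 2.0
    return np.clip((np.asarray(hu, dtype=np.float64) - lo) / window.width, 0.0, 1.0)


def adaptive_hist_equalize(img, clip_limit: float = 0.01,
                           tiles: tuple[int, int] = (8, 8)) -> np.ndarray:
    """CLAHE on a [0, 1] image; output stays in [0, 1].

    A constant image passes through (nearly) unchanged: there is no contrast
    to redistribute.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("input image must lie in [0, 1]")
    if tiles[0] > img.shape[0] or tiles[1] > img.shape[1]:
        raise ValueError(f"tile grid {tiles} larger than image {img.shape}")
    if np.ptp(img) == 0:
        return img.copy()
    kernel = (max(img.shape[0] // tiles[0], 1), max(img.shape[1] // tiles[1], 1))
    return exposure.equalize_adapthist(img, kernel_size=kernel,
                                       clip_limit=clip_limit)


def _affine_matrix(spec: AugmentSpec, shape) -> np.ndarray:
    """Inverse (output -> input) affine map about the image center."""
    theta = np.deg2rad(spec.rotation_deg)
    shear = np.deg2rad(spec.shear_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)],
                    [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, np.tan(shear)], [0.0, 1.0]])
    flp = np.array([[1.0, 0.0], [0.0, -1.0]]) if spec.flip_horizontal else np.eye(2)
    fwd = (rot @ shr @ flp) * spec.zoom_factor
    inv = np.linalg.inv(fwd)
    center = (np.asarray(shape, dtype=float) - 1) / 2.0
    offset = center - inv @ center
    return inv, offset


def augment_pair(img, mask, spec: AugmentSpec):
    """Apply the identical geometric transform to image and mask.

    Image is interpolated bilinearly, mask nearest-neighbor and re-binarized
    (>= 0.5 -> 1); shapes are preserved (out-of-frame regions are filled with
    the image edge minimum / mask background).
    """
    img = np.asarray(img, dtype=np.float64)
    mask = np.asarray(mask)
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {mask.shape}")
    ident = (spec.rotation_deg == 0 and not spec.flip_horizontal
             and spec.zoom_factor == 1 and spec.shear_deg == 0)
    if ident:
        return img.copy(), np.asarray(mask, dtype=np.uint8).copy()
    if spec.flip_horizontal and spec.rotation_deg == 0 \
            and spec.zoom_factor == 1 and spec.shear_deg == 0:
        # pure flip: exact, no interpolation
        return img[:, ::-1].copy(), np.asarray(mask, np.uint8)[:, ::-1].copy()
    inv, offset = _affine_matrix(spec, img.shape)
    img2 = ndimage.affine_transform(img, inv, offset=offset, order=1,
                                    mode="constant", cval=float(img.min()))
    m2 = ndimage.affine_transform(mask.astype(np.float64), inv, offset=offset,
                                  order=0, mode="constant", cval=0.0)
    return img2, (m2 >= 0.5).astype(np.uint8)


def sample_augment_spec(rng: np.random.Generator,
                        rotation_range: float = 15.0,
                        zoom_range: tuple[float, float] = (0.9, 1.1),
                        shear_range: float = 8.0,
                        flip_prob: float = 0.5) -> AugmentSpec:
    """Draw one random augmentation within the configured ranges."""
    return AugmentSpec(
        rotation_deg=float(rng.uniform(-rotation_range, rotation_range)),
        flip_horizontal=bool(rng.random() < flip_prob),
        zoom_factor=float(rng.uniform(*zoom_range)),
        shear_deg=float(rng.uniform(-shear_range, shear_range)),
    )


def preprocess_slice(hu_image, window: WindowSpec | None = None,
                     clahe: bool = True) -> np.ndarray:
    """window/level + optional CLAHE: the model-ready [0, 1] image."""
    window = window or WindowSpec()
    out = apply_window(hu_image, window)
    if clahe:
        out = adaptive_hist_equalize(out)
    return out
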