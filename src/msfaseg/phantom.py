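"""Synthetic CT-like phantom slices with ground-truth thyroid-like masks.

Each phantom is a 2-D HU-valued slice of uniform neck soft tissue containing
a bilobed gland — two ellipses joined by a thin isthmus band, mimicking
thyroid topology — drawn in a soft-tissue HU range, surrounded by circular
vessel-like confounders whose HU range overlaps the gland's (so telling them
apart is a shape problem, not an intensity threshold), plus additive Gaussian
noise.  The mask marks exactly the gland pixels before noise.

Generation is a pure function of (config, index): per-phantom randomness is
drawn from ``default_rng(seed + index)``, so any phantom of a dataset can be
regenerated independently and bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import io_formats

__all__ = ["PhantomConfig", "PhantomPair", "generate_phantom", "generate_dataset"]


@dataclass(frozen=True)
class PhantomConfig:
    image_size: int = 512
    gland_hu_range: tuple[float, float] = (60.0, 100.0)
    background_hu: float = 40.0
    vessel_count: int = 8
    vessel_hu_range: tuple[float, float] = (60.0, 100.0)
    noise_sd: float = 10.0
    lobe_size_range: tuple[float, float] = (0.06, 0.10)
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError(f"image_size must be >= 32, got {self.image_size}")
        for name in ("gland_hu_range", "vessel_hu_range", "lobe_size_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} is not a valid interval: ({lo}, {hi})")
        if self.vessel_count < 0:
            raise ValueError("vessel_count must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.lobe_size_range[1] * 4 * self.image_size < 4:
            raise ValueError("image_size too small to place two lobes")


@dataclass(frozen=True)
class PhantomPair:
    image: np.ndarray  # HU-valued float32, (H, W)
    mask: np.ndarray   # uint8 {0,1}, same shape
    config: PhantomConfig
    index: int


def _ellipse(yy, xx, cy, cx, ay, ax_):
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax_) ** 2 <= 1.0


def _gland_mask(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    s = cfg.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    # gland centered near the slice middle with mild jitter
    cy = s * (0.5 + rng.uniform(-0.06, 0.06))
    cx = s * (0.5 + rng.uniform(-0.06, 0.06))
    half_w = s * rng.uniform(*cfg.lobe_size_range)      # lobe semi-axis (x)
    half_h = half_w * rng.uniform(1.5, 2.0)             # lobes are taller than wide
    gap = half_w * rng.uniform(1.6, 2.2)                # lobe center offset from midline
    mask = _ellipse(yy, xx, cy, cx - gap, half_h, half_w)
    mask |= _ellipse(yy, xx, cy, cx + gap, half_h, half_w)
    # isthmus: thin band joining the lobes across the midline
    ih = max(half_h * 0.25, 1.5)
    iy = cy + half_h * rng.uniform(0.2, 0.5)
    mask |= (np.abs(yy - iy) <= ih) & (np.abs(xx - cx) <= gap)
    return mask


def generate_phantom(config: PhantomConfig, index: int) -> PhantomPair:
    """Deterministically generate phantom `index` under `config`."""
    config.validate()
    rng = np.random.default_rng(config.seed + index)
    s = config.image_size
    mask = _gland_mask(config, rng)
    if not mask.any():
        raise ValueError("degenerate geometry: empty gland mask")

    image = np.full((s, s), config.background_hu, dtype=np.float64)
    # smooth intra-gland texture within the configured HU interval
    lo, hi = config.gland_hu_range
    mid, amp = 0.5 * (lo + hi), 0.5 * (hi - lo)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    phase = rng.uniform(0, 2 * np.pi, size=4)
    texture = 0.5 * np.sin(2 * np.pi * yy / s * rng.uniform(2, 5) + phase[0]) \
        + 0.5 * np.sin(2 * np.pi * xx / s * rng.uniform(2, 5) + phase[1])
    image[mask] = np.clip(mid + amp * texture[mask], lo, hi)

    # vessels: circles rejection-sampled to avoid the gland (with a margin)
    vr_lo, vr_hi = config.vessel_hu_range
    placed = 0
    attempts = 0
    while placed < config.vessel_count and attempts < config.vessel_count * 200:
        attempts += 1
        r = rng.uniform(0.01, 0.035) * s
        cy = rng.uniform(r, s - r)
        cx = rng.uniform(r, s - r)
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= (r + 1.0) ** 2
        if (disc & mask).any():
            continue
        hu = rng.uniform(vr_lo, vr_hi)
        image[(yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2] = hu
        placed += 1

    if config.noise_sd > 0:
        image = image + rng.normal(0.0, config.noise_sd, size=image.shape)

    pair = PhantomPair(image.astype(np.float32), mask.astype(np.uint8),
                       config, index)
    frac = pair.mask.mean()
    if not 0.0 < frac < 0.25:
        raise ValueError(f"mask foreground fraction {frac:.3f} outside (0, 0.25)")
    return pair


def generate_dataset(config: PhantomConfig, n: int, out_dir) -> dict:
    """Write n phantom image/mask pairs plus a JSON manifest to `out_dir`.

    Images are stored as single-frame DICOM (RescaleSlope 1, RescaleIntercept
    -1024 encoded in the stored pixels), masks as 8-bit PNG (0/255).
    Re-running with the same config reproduces identical files.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = []
    for i in range(n):
        pair = generate_phantom(config, i)
        case_id = f"phantom_{i:04d}"
        img_path = out_dir / f"{case_id}.dcm"
        mask_path = out_dir / f"{case_id}_mask.png"
        io_formats.write_dicom_slice(pair.image, img_path, case_id=case_id)
        io_formats.write_mask_png(pair.mask, mask_path)
        cases.append({"case_id": case_id, "image_path": img_path.name,
                      "mask_path": mask_path.name})
    manifest = {"config": asdict(config), "n": n, "cases": cases}
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
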