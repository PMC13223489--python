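"""Seeded generator of class-separable, fundus-like test images.

Real optic-disc-centered fundus photographs are not required anywhere in
this package: this module emits small RGB images that carry the one signal
the downstream models need — a bright optic disc containing a brighter
central cup whose cup-to-disc ratio (CDR) is drawn from a class-dependent
distribution (an enlarged cup relative to the disc is the glaucoma
hallmark).  A reddish textured background, slight disc-center jitter and a
few dark curved vessel proxies provide nuisance variation.

The same :class:`SynthConfig` always yields byte-identical PNG files and an
identical manifest, so fixtures never need to be stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._rng import rng_for
from .data import ImageManifest, ManifestRecord, write_manifest

__all__ = ["SynthConfig", "generate_dataset"]


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator.

    ``cdr_normal`` / ``cdr_glaucoma`` are the mean cup-to-disc ratios of the
    two classes (0.3 vs 0.7: a healthy cup is small, a glaucomatous cup
    approaches the disc rim); per-image ratios are truncated-normal draws
    with sd ``cdr_sd``.  ``noise_sd`` is additive pixel noise on the [0, 1]
    intensity scale.
    """

    n_images: int = 100
    class_balance: float = 0.5
    image_size: int = 128
    cdr_normal: float = 0.3
    cdr_glaucoma: float = 0.7
    cdr_sd: float = 0.1
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not (isinstance(self.n_images, int) and self.n_images >= 2):
            raise ValueError(f"n_images must be an integer >= 2, got {self.n_images!r}")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError(f"class_balance must be in [0, 1], got {self.class_balance!r}")
        if not (isinstance(self.image_size, int) and self.image_size >= 16):
            raise ValueError(f"image_size must be an integer >= 16, got {self.image_size!r}")
        if not 0.0 < self.cdr_normal < self.cdr_glaucoma < 1.0:
            raise ValueError(
                "cup-to-disc means must satisfy 0 < cdr_normal < cdr_glaucoma < 1, "
                f"got cdr_normal={self.cdr_normal!r}, cdr_glaucoma={self.cdr_glaucoma!r}"
            )
        if self.cdr_sd < 0:
            raise ValueError(f"cdr_sd must be nonnegative, got {self.cdr_sd!r}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be nonnegative, got {self.noise_sd!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) restricted to (0, 1) by rejection."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if 0.0 < x < 1.0:
            return float(x)
    return float(min(max(mean, 1e-3), 1 - 1e-3))  # pragma: no cover - sd huge


def _render(rng: np.random.Generator, size: int, cdr: float, noise_sd: float) -> np.ndarray:
    """One fundus-like image in [0, 1], shape (size, size, 3)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    # reddish retinal background with mild radial shading
    img = np.empty((size, size, 3))
    img[..., 0] = 0.55
    img[..., 1] = 0.22
    img[..., 2] = 0.10
    cy0, cx0 = (size - 1) / 2, (size - 1) / 2
    shade = 1.0 - 0.3 * (((yy - cy0) ** 2 + (xx - cx0) ** 2) / (2 * cx0**2))
    img *= shade[..., None]

    # optic disc: bright yellowish circle, center jittered <= 10% of side
    jitter = 0.10 * size
    cy = cy0 + rng.uniform(-jitter, jitter)
    cx = cx0 + rng.uniform(-jitter, jitter)
    disc_r = size * rng.uniform(0.26, 0.32)
    cup_r = cdr * disc_r
    dist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    disc = np.clip((disc_r - dist) / 2.0, 0.0, 1.0)  # soft edge
    cup = np.clip((cup_r - dist) / 1.5, 0.0, 1.0)
    disc_color = np.array([0.95, 0.80, 0.45])
    cup_color = np.array([1.00, 0.97, 0.80])
    img = img * (1 - disc[..., None]) + disc[..., None] * disc_color
    img = img * (1 - cup[..., None]) + cup[..., None] * cup_color

    # 2-4 dark vessel-like quadratic curves emanating at the disc rim;
    # the cup region stays vessel-free, as in disc-centered crops, so the
    # cup-to-disc signal is not occluded
    for _ in range(rng.integers(2, 5)):
        t = np.linspace(0.0, 1.0, 4 * size)
        ang = rng.uniform(0, 2 * math.pi)
        direction = np.array([math.sin(ang), math.cos(ang)])
        p0 = np.array([cy, cx]) + disc_r * direction
        p2 = np.array([cy, cx]) + 0.8 * size * direction
        p1 = (p0 + p2) / 2 + rng.uniform(-0.15, 0.15, size=2) * size
        pts = (
            (1 - t)[:, None] ** 2 * p0
            + 2 * (1 - t)[:, None] * t[:, None] * p1
            + t[:, None] ** 2 * p2
        )
        width = rng.uniform(0.8, 1.6)
        for py, px in pts:
            if (py - cy) ** 2 + (px - cx) ** 2 < disc_r**2:
                continue
            y0, y1 = int(max(0, py - width)), int(min(size - 1, py + width))
            x0, x1 = int(max(0, px - width)), int(min(size - 1, px + width))
            if y0 <= y1 and x0 <= x1:
                img[y0 : y1 + 1, x0 : x1 + 1] *= 0.55

    img += rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_dataset(config: SynthConfig, out_dir) -> ImageManifest:
    """Write ``n_images`` PNGs plus a CSV manifest; return the manifest.

    Exactly ``round(n_images * class_balance)`` images are glaucoma, the
    rest normal.  Per-image randomness is keyed to (seed, image index), so
    the output is byte-identical across runs of the same config.  A sidecar
    ``synth_meta.csv`` records each image's drawn cup-to-disc ratio.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_glaucoma = round(config.n_images * config.class_balance)
    labels = ["glaucoma"] * n_glaucoma + ["normal"] * (config.n_images - n_glaucoma)
    order = rng_for(config.seed, "synth-order").permutation(config.n_images)
    labels = [labels[i] for i in order]

    records, meta = [], []
    for i, label in enumerate(labels):
        rng = rng_for(config.seed, "synth-image", i)
        mean = config.cdr_glaucoma if label == "glaucoma" else config.cdr_normal
        cdr = _truncnorm01(rng, mean, config.cdr_sd)
        img = _render(rng, config.image_size, cdr, config.noise_sd)
        arr = np.round(img * 255.0).astype(np.uint8)
        path = out / f"img_{i:05d}_{label}.png"
        Image.fromarray(arr, mode="RGB").save(path, format="PNG")
        records.append(ManifestRecord(path=str(path), label=label, source="synthetic"))
        meta.append({"path": str(path), "label": label, "cdr": cdr})

    manifest = ImageManifest(records)
    write_manifest(manifest, out / "manifest.csv")
    pd.DataFrame(meta).to_csv(out / "synth_meta.csv", index=False)
    return manifest
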