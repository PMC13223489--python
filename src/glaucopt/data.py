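"""Dataset assembly, image normalization, cropping, and splitting.

Collections of labeled optic-disc images are tracked by a CSV-backed
manifest (path, label in {glaucoma, normal}, source).  Source datasets are
merged by :func:`assemble`; images are loaded as float tensors in [0, 1] at
a fixed square size; a center-crop utility stands in for the manual
optic-disc cropping applied to full-fundus images; and
:func:`split` partitions a manifest 70/15/15 (by default) into train,
validation and test sets.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from ._rng import rng_for

__all__ = [
    "LABELS",
    "ManifestRecord",
    "ImageManifest",
    "SplitSpec",
    "read_manifest",
    "write_manifest",
    "assemble",
    "load_and_normalize",
    "center_crop",
    "split",
]

logger = logging.getLogger(__name__)

LABELS = ("glaucoma", "normal")


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: str
    source: str = ""

    def __post_init__(self):
        if self.label not in LABELS:
            raise ValueError(f"unknown label {self.label!r} (expected one of {LABELS})")


@dataclass
class ImageManifest:
    """Ordered labeled image records; paths are unique."""

    records: list = field(default_factory=list)

    def __post_init__(self):
        paths = [r.path for r in self.records]
        dupes = [p for p, c in Counter(paths).items() if c > 1]
        if dupes:
            raise ValueError(f"duplicate paths in manifest: {sorted(dupes)[:5]}")

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def class_counts(self) -> dict:
        c = Counter(r.label for r in self.records)
        return {label: c.get(label, 0) for label in LABELS}

    def labels(self) -> np.ndarray:
        """Binary labels, glaucoma = 1."""
        return np.array([1 if r.label == "glaucoma" else 0 for r in self.records])


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions (default 0.70/0.15/0.15)."""

    train_frac: float = 0.70
    val_frac: float = 0.15
    test_frac: float = 0.15
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        for name in ("train_frac", "val_frac", "test_frac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)!r}")
        total = self.train_frac + self.val_frac + self.test_frac
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {total!r}")


def read_manifest(path) -> ImageManifest:
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {"path", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns path,label[,source]")
    return ImageManifest(
        [
            ManifestRecord(path=row["path"], label=row["label"], source=row.get("source", ""))
            for _, row in df.iterrows()
        ]
    )


def write_manifest(manifest: ImageManifest, path) -> None:
    pd.DataFrame(
        [{"path": r.path, "label": r.label, "source": r.source} for r in manifest]
    ).to_csv(path, index=False)


def assemble(manifests) -> ImageManifest:
    """Concatenate several manifests into one merged dataset.

    Raises if any path appears in more than one input.  Per-class counts of
    the merged collection are logged.
    """
    manifests = list(manifests)
    if not manifests:
        raise ValueError("assemble needs at least one manifest")
    records = [r for m in manifests for r in m]
    merged = ImageManifest(records)  # duplicate check happens here
    counts = merged.class_counts()
    logger.info(
        "assembled %d records: %d glaucoma, %d normal",
        len(merged),
        counts["glaucoma"],
        counts["normal"],
    )
    return merged


def _resize_bilinear(arr: np.ndarray, size: int) -> np.ndarray:
    """Per-channel bilinear resize of a float image to size x size."""
    if arr.shape[0] == size and arr.shape[1] == size:
        return arr
    channels = [
        np.asarray(
            Image.fromarray(arr[..., c].astype(np.float32), mode="F").resize(
                (size, size), resample=Image.BILINEAR
            )
        )
        for c in range(arr.shape[-1])
    ]
    return np.stack(channels, axis=-1)


def load_and_normalize(path, target_size: int = 128) -> np.ndarray:
    """Decode an image to a (size, size, 3) float tensor in [0, 1].

    8-bit intensities are divided by 255; grayscale inputs are replicated
    across the three channels (logged).  Resizing is bilinear.
    """
    try:
        with Image.open(path) as im:
            if im.mode in ("L", "I;16", "I"):
                logger.info("grayscale image %s replicated to 3 channels", path)
            rgb = im.convert("RGB")
            arr = np.asarray(rgb, dtype=np.float32) / 255.0
    except (OSError, ValueError) as e:
        raise OSError(f"cannot read image {path}: {e}") from e
    return np.clip(_resize_bilinear(arr, target_size), 0.0, 1.0)


def center_crop(image: np.ndarray, crop_fraction: float) -> np.ndarray:
    """Central square window of side round(fraction * side), resized back.

    An automated stand-in for manual optic-disc cropping of full-fundus
    views: the disc region of interest sits near the image center once
    acquisition is disc-centered.
    """
    if not 0.0 < crop_fraction <= 1.0:
        raise ValueError(f"crop_fraction must be in (0, 1], got {crop_fraction!r}")
    h, w = image.shape[:2]
    side = min(h, w)
    crop = max(1, round(crop_fraction * side))
    y0 = (h - crop) // 2
    x0 = (w - crop) // 2
    window = image[y0 : y0 + crop, x0 : x0 + crop]
    return np.clip(_resize_bilinear(np.asarray(window, dtype=np.float32), side), 0.0, 1.0)


def _allocate(counts: dict, n_train: int, n_val: int):
    """Largest-remainder allocation of global subset sizes across classes.

    Returns {label: (train, val, test)} with per-class totals preserved and
    the per-class remainder going to test.
    """
    labels = sorted(counts)
    total = sum(counts.values())
    alloc = {}
    for target, key in ((n_train, 0), (n_val, 1)):
        ideal = {lab: target * counts[lab] / total for lab in labels}
        base = {lab: int(ideal[lab]) for lab in labels}
        short = target - sum(base.values())
        order = sorted(labels, key=lambda lab: (-(ideal[lab] - base[lab]), lab))
        for lab in order[:short]:
            base[lab] += 1
        for lab in labels:
            alloc.setdefault(lab, []).append(base[lab])
    for lab in labels:
        tr, va = alloc[lab]
        alloc[lab] = (tr, va, counts[lab] - tr - va)
    return alloc


def split(manifest: ImageManifest, spec: SplitSpec = SplitSpec()):
    """Partition a manifest into (train, val, test) manifests.

    Global sizes are floor(train_frac*N), floor(val_frac*N) and the
    remainder — the convention that maps 1355 records at 70/15/15 to
    948/203/204.  With ``stratified`` on, those totals are divided across
    classes by largest remainder, keeping per-class proportions within one
    record of the global ones while preserving the global sizes exactly.
    Membership is a seeded shuffle; the three subsets are disjoint and
    cover the input.
    """
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    n_train = int(spec.train_frac * n + 1e-9)
    n_val = int(spec.val_frac * n + 1e-9)
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) == 0:
        raise ValueError(
            f"split of {n} records gives an empty subset "
            f"({n_train}/{n_val}/{n_test}); use more data or larger fractions"
        )

    rng = rng_for(spec.seed, "split")
    if spec.stratified:
        by_label: dict[str, list] = {}
        for r in manifest:
            by_label.setdefault(r.label, []).append(r)
        alloc = _allocate({k: len(v) for k, v in by_label.items()}, n_train, n_val)
        parts: dict[int, list] = {0: [], 1: [], 2: []}
        for lab in sorted(by_label):
            recs = by_label[lab]
            order = rng.permutation(len(recs))
            tr, va, te = alloc[lab]
            idx = 0
            for part, size in ((0, tr), (1, va), (2, te)):
                parts[part].extend(recs[order[i]] for i in range(idx, idx + size))
                idx += size
        train, val, test = parts[0], parts[1], parts[2]
    else:
        order = rng.permutation(n)
        recs = [manifest.records[i] for i in order]
        train = recs[:n_train]
        val = recs[n_train : n_train + n_val]
        test = recs[n_train + n_val :]
    return ImageManifest(train), ImageManifest(val), ImageManifest(test)
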