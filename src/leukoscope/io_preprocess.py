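"""Image-folder loading, stratified splitting and preprocessing.

The on-disk dialect is a directory tree of JPEG/PNG single-cell crops grouped
by class folder, optionally accompanied by a ``filename,label`` CSV manifest.
Preprocessing follows the pipeline's convention: resize to a square target
side (default 244), then channel-wise normalization that by default is applied
to training images only (``normalize_train_only``). Normalization statistics
default to the identity (means 0, stds 1); ``compute_channel_stats`` derives
per-dataset statistics for callers who want them, in which case applying them
to training images only introduces a train/validation distribution shift —
see the methods note before enabling that combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from .cells import CLASS_NAMES, CellClass

logger = logging.getLogger(__name__)

_IMAGE_SUFFIXES = {".png", ".jpg", ".jpeg"}


@dataclass(frozen=True)
class LabeledItem:
    path: Path
    label: CellClass


@dataclass(frozen=True)
class SplitManifest:
    """A disjoint train/validation partition of labeled items."""

    train: tuple[LabeledItem, ...]
    validation: tuple[LabeledItem, ...]
    seed: int
    fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [(str(it.path), it.label.name, subset)
                for subset, items in (("train", self.train), ("validation", self.validation))
                for it in items]
        return pd.DataFrame(rows, columns=["filename", "label", "subset"])

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class PreprocessConfig:
    """Resize + normalization settings.

    ``target_side`` defaults to 244 (the pipeline's stated input size; note
    the canonical dense-connectivity input is 224 — the 244 default is kept
    deliberately and is configurable). ``normalize_train_only`` applies the
    channel normalization to training images only.
    """

    target_side: int = 244
    normalize_train_only: bool = True
    channel_means: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel_stds: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.target_side < 32:
            raise ValueError(f"target_side must be >= 32, got {self.target_side}")
        if any(s <= 0 for s in self.channel_stds):
            raise ValueError(f"channel_stds must be > 0, got {self.channel_stds}")


def load_image(path: str | Path) -> np.ndarray:
    """Decode a JPEG/PNG to an (H, W, 3) float array in [0, 1]."""
    from PIL import Image

    with Image.open(path) as im:
        arr = np.asarray(im.convert("RGB"), dtype=np.float64) / 255.0
    return arr


def load_labeled_images(root: str | Path, manifest: str | Path | None = None) -> list[LabeledItem]:
    """Collect labeled image paths from a class-folder tree or a CSV manifest.

    With a manifest, labels come from its ``label`` column and filenames are
    interpreted relative to ``root``; without one, the parent folder name is
    the label. Unreadable images are skipped with a logged warning; unknown
    class labels (including ``basophil``, which is excluded from the class
    set) raise a ValueError.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"image root {root} does not exist")

    pairs: list[tuple[Path, str]] = []
    if manifest is not None:
        df = pd.read_csv(manifest)
        if list(df.columns[:2]) != ["filename", "label"]:
            raise ValueError(
                f"manifest header must be 'filename,label', got {list(df.columns)}"
            )
        pairs = [(root / fn, str(lab)) for fn, lab in zip(df["filename"], df["label"])]
    else:
        for sub in sorted(p for p in root.iterdir() if p.is_dir()):
            if sub.name == "masks":
                continue
            for img in sorted(sub.iterdir()):
                if img.suffix.lower() in _IMAGE_SUFFIXES:
                    pairs.append((img, sub.name))

    items: list[LabeledItem] = []
    skipped = 0
    for path, label in pairs:
        cls = CellClass.from_name(label)  # raises for basophil/unknown labels
        try:
            with open(path, "rb") as fh:
                head = fh.read(16)
            from PIL import Image

            with Image.open(path) as im:
                im.verify()
            del head
        except Exception:
            skipped += 1
            logger.warning("skipping unreadable image %s", path)
            continue
        items.append(LabeledItem(path=path, label=cls))
    if skipped:
        logger.warning("skipped %d unreadable image(s) under %s", skipped, root)
    return items


def stratified_split(items: list[LabeledItem], fraction: float, seed: int) -> SplitManifest:
    """Seed-deterministic per-class split; ``fraction`` is the train share.

    The validation count per class is round((1 - fraction) * n) with banker's
    rounding, which always lands on floor or ceil of the exact share.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    by_class: dict[CellClass, list[LabeledItem]] = {c: [] for c in CellClass.all()}
    for it in items:
        by_class[it.label].append(it)
    for cls, members in by_class.items():
        if not members:
            raise ValueError(f"class {cls.name!r} has 0 items; every class needs at least 1")

    rng = np.random.default_rng(seed)
    train: list[LabeledItem] = []
    val: list[LabeledItem] = []
    for cls in CellClass.all():
        members = by_class[cls]
        order = rng.permutation(len(members))
        n_val = int(round((1.0 - fraction) * len(members)))
        n_val = min(max(n_val, 0), len(members) - 1)  # keep >=1 training item
        shuffled = [members[i] for i in order]
        val.extend(shuffled[:n_val])
        train.extend(shuffled[n_val:])
    return SplitManifest(train=tuple(train), validation=tuple(val),
                         seed=seed, fraction=fraction)


@dataclass(frozen=True)
class ManifestSummary:
    per_class_train: tuple[int, int, int, int]
    per_class_val: tuple[int, int, int, int]
    per_class_total: tuple[int, int, int, int] = field(init=False)
    train_total: int = field(init=False)
    validation_total: int = field(init=False)
    grand_total: int = field(init=False)

    def __post_init__(self) -> None:
        for counts in (self.per_class_train, self.per_class_val):
            if len(counts) != len(CLASS_NAMES):
                raise ValueError(f"expected {len(CLASS_NAMES)} per-class counts")
            if any(c < 0 for c in counts):
                raise ValueError(f"counts must be non-negative, got {counts}")
        object.__setattr__(self, "per_class_total",
                           tuple(t + v for t, v in zip(self.per_class_train, self.per_class_val)))
        object.__setattr__(self, "train_total", sum(self.per_class_train))
        object.__setattr__(self, "validation_total", sum(self.per_class_val))
        object.__setattr__(self, "grand_total", self.train_total + self.validation_total)


def manifest_summary(per_class_train, per_class_val) -> ManifestSummary:
    """Exact integer bookkeeping of per-class train/validation counts."""
    return ManifestSummary(tuple(int(c) for c in per_class_train),
                           tuple(int(c) for c in per_class_val))


def resize_image(image: np.ndarray, side: int) -> np.ndarray:
    """Bilinear resize to side x side x 3, values clipped back into [0, 1]."""
    if side < 1:
        raise ValueError(f"side must be >= 1, got {side}")
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {image.shape}")
    if image.shape[0] == side and image.shape[1] == side:
        return image.copy()
    out = _sk_resize(image, (side, side), order=1, anti_aliasing=False,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def normalize_image(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Channel-wise (x - mean) / std; output is unbounded."""
    means = np.asarray(config.channel_means, dtype=float)
    stds = np.asarray(config.channel_stds, dtype=float)
    if np.any(stds <= 0):
        raise ValueError(f"channel stds must be > 0, got {config.channel_stds}")
    return (np.asarray(image, dtype=float) - means) / stds


def denormalize_image(image: np.ndarray, config: PreprocessConfig) -> np.ndarray:
    """Inverse of :func:`normalize_image`."""
    means = np.asarray(config.channel_means, dtype=float)
    stds = np.asarray(config.channel_stds, dtype=float)
    return np.asarray(image, dtype=float) * stds + means


def compute_channel_stats(images) -> tuple[tuple[float, float, float], tuple[float, float, float]]:
    """Per-channel mean/std across a collection of (H, W, 3) images."""
    stacked = np.concatenate([np.asarray(im, dtype=float).reshape(-1, 3) for im in images])
    means = tuple(float(m) for m in stacked.mean(axis=0))
    stds = tuple(float(s) for s in stacked.std(axis=0))
    if any(s <= 0 for s in stds):
        raise ValueError("constant channel encountered; stds must be > 0")
    return means, stds


def augment_image(image: np.ndarray, rng: np.random.Generator,
                  max_rotation_deg: float = 15.0,
                  zoom_range: tuple[float, float] = (0.9, 1.1)) -> np.ndarray:
    """Random flip / rotate / zoom, for synthetic data that is not pre-augmented."""
    from skimage.transform import rotate, rescale

    out = np.asarray(image, dtype=float)
    if rng.random() < 0.5:
        out = out[:, ::-1]
    if rng.random() < 0.5:
        out = out[::-1, :]
    angle = rng.uniform(-max_rotation_deg, max_rotation_deg)
    out = rotate(out, angle, mode="edge", preserve_range=True)
    z = rng.uniform(*zoom_range)
    side = out.shape[0]
    zoomed = rescale(out, z, channel_axis=2, mode="edge", preserve_range=True,
                     anti_aliasing=False)
    if zoomed.shape[0] >= side:
        o = (zoomed.shape[0] - side) // 2
        out = zoomed[o:o + side, o:o + side]
    else:
        pad = side - zoomed.shape[0]
        out = np.pad(zoomed, ((pad // 2, pad - pad // 2),
                              (pad // 2, pad - pad // 2), (0, 0)), mode="edge")
    return np.clip(out[:side, :side], 0.0, 1.0)
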