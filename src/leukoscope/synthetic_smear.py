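"""Synthetic stained-smear generator with ground-truth masks.

Public single-cell blood-smear collections (Romanowsky-stained crops with one
leukocyte roughly centered per frame) are emulated here by an analytic
renderer: a filled, rotated cytoplasm ellipse over a pale low-saturation
background, with the nucleus drawn as one to three overlapping darker, more
saturated ellipse lobes. Morphology follows the textbook descriptions the
classifier relies on:

* eosinophil — bilobed nucleus, pink-stained cytoplasm;
* lymphocyte — single large dark purple nucleus, thin cytoplasm rim;
* monocyte  — largest cell, kidney-shaped (bitten) nucleus, light blue cytoplasm;
* neutrophil — multilobed (three-lobe) nucleus.

Every sample carries the exact foreground mask of the rendered cell, so the
HSV threshold segmenter and the classifier can both be validated without any
external download. Rendering is purely deterministic in (appearance,
image_side, seed).
"""

from __future__ import annotations

import colorsys
import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .cells import CLASS_NAMES, CellClass

#: Reference frame side used to express cell radii in pixels; rendering at a
#: different ``image_side`` scales every radius by image_side / REFERENCE_SIDE
#: so class-relative cell sizes are preserved at any resolution.
REFERENCE_SIDE = 240

#: Additive uniform RGB noise amplitude. Kept well below the margin between
#: background saturation (~0.08) and the 0.45 saturation threshold.
NOISE_AMPLITUDE = 0.02

# Pale, low-saturation background (HSV): faint yellowish glass/plasma tone.
_BACKGROUND_HSV = (0.12, 0.08, 0.96)


@dataclass(frozen=True)
class CellAppearance:
    """Renderable description of one leukocyte class.

    Hues and saturations live on the [0, 1] HSV scale. ``nucleus_fraction`` is
    the nucleus-to-cell area ratio (the inverse of the cytoplasm-to-nucleus
    ratio hematologists quote). ``cell_radius_px`` is the major semi-axis in
    pixels at the 240 px reference frame.
    """

    nucleus_lobes: int
    nucleus_fraction: float
    nucleus_hue: float
    cytoplasm_hue: float
    nucleus_saturation: float
    cytoplasm_saturation: float
    nucleus_value: float
    cytoplasm_value: float
    cell_radius_px: int
    hue_jitter: float = 0.015
    radius_jitter: float = 0.08
    position_jitter: float = 0.05
    kidney_notch: bool = False
    cell_class: str | None = None

    def __post_init__(self) -> None:
        if self.nucleus_lobes < 1:
            raise ValueError("nucleus_lobes must be >= 1")
        if not 0.0 < self.nucleus_fraction <= 1.0:
            raise ValueError("nucleus_fraction must be in (0, 1]")
        for field in ("nucleus_hue", "cytoplasm_hue", "nucleus_saturation",
                      "cytoplasm_saturation", "nucleus_value", "cytoplasm_value"):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{field} must be in [0, 1], got {v}")
        if self.nucleus_saturation <= _BACKGROUND_HSV[1]:
            raise ValueError("nucleus_saturation must exceed background saturation")


# Class-default appearances. Hues sit in the blue-to-magenta band typical of
# Romanowsky stains and are kept away from the 0/1 hue seam (the segmenter's
# hue bounds are plain intervals without wraparound). Classes are separable by
# hue, nucleus morphology and cell size.
_DEFAULTS: dict[str, CellAppearance] = {
    "eosinophil": CellAppearance(
        nucleus_lobes=2, nucleus_fraction=0.35,
        nucleus_hue=0.78, cytoplasm_hue=0.92,
        nucleus_saturation=0.80, cytoplasm_saturation=0.55,
        nucleus_value=0.55, cytoplasm_value=0.88,
        cell_radius_px=70, cell_class="eosinophil",
    ),
    "lymphocyte": CellAppearance(
        nucleus_lobes=1, nucleus_fraction=0.85,
        nucleus_hue=0.76, cytoplasm_hue=0.72,
        nucleus_saturation=0.82, cytoplasm_saturation=0.50,
        nucleus_value=0.45, cytoplasm_value=0.85,
        cell_radius_px=55, cell_class="lymphocyte",
    ),
    "monocyte": CellAppearance(
        nucleus_lobes=1, nucleus_fraction=0.45,
        nucleus_hue=0.62, cytoplasm_hue=0.55,
        nucleus_saturation=0.75, cytoplasm_saturation=0.50,
        nucleus_value=0.60, cytoplasm_value=0.88,
        cell_radius_px=90, kidney_notch=True, cell_class="monocyte",
    ),
    "neutrophil": CellAppearance(
        nucleus_lobes=3, nucleus_fraction=0.40,
        nucleus_hue=0.70, cytoplasm_hue=0.63,
        nucleus_saturation=0.78, cytoplasm_saturation=0.50,
        nucleus_value=0.55, cytoplasm_value=0.88,
        cell_radius_px=65, cell_class="neutrophil",
    ),
}


@dataclass(frozen=True)
class SyntheticSample:
    """A rendered smear crop, its exact foreground mask and its label."""

    image: np.ndarray  # (H, W, 3) float64 RGB in [0, 1]
    mask: np.ndarray   # (H, W) uint8 in {0, 1}; 1 = cell pixel
    label: CellClass | None
    seed: int


def default_appearance(cell_class: CellClass | str) -> CellAppearance:
    """Return the documented default appearance for a leukocyte class."""
    name = cell_class.name if isinstance(cell_class, CellClass) else str(cell_class).lower()
    if name not in _DEFAULTS:
        raise ValueError(
            f"unknown cell class {cell_class!r}; valid classes are {list(CLASS_NAMES)}"
        )
    return _DEFAULTS[name]


def _hsv_rgb(h: float, s: float, v: float) -> np.ndarray:
    return np.array(colorsys.hsv_to_rgb(h % 1.0, s, v))


def _ellipse(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
             a: float, b: float, theta: float) -> np.ndarray:
    """Boolean mask of a rotated filled ellipse (no anti-aliasing)."""
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def render_cell(appearance: CellAppearance, image_side: int, seed: int) -> SyntheticSample:
    """Render one cell on a pale background; deterministic in all arguments.

    The returned mask is exactly the set of rendered cell (cytoplasm or
    nucleus) pixels, and background saturation stays far below the 0.45
    segmentation threshold, so the HSV segmenter can recover the mask.
    """
    if image_side < 32:
        raise ValueError(f"image_side must be >= 32, got {image_side}")
    rng = np.random.default_rng(seed)
    side = int(image_side)
    scale = side / REFERENCE_SIDE

    r = appearance.cell_radius_px * scale
    r *= 1.0 + rng.uniform(-appearance.radius_jitter, appearance.radius_jitter)
    jit = appearance.position_jitter * side
    cy = side / 2.0 + rng.uniform(-jit, jit)
    cx = side / 2.0 + rng.uniform(-jit, jit)
    theta = rng.uniform(0.0, np.pi)
    hue_d = rng.uniform(-appearance.hue_jitter, appearance.hue_jitter)

    yy, xx = np.mgrid[0:side, 0:side].astype(float)
    cell = _ellipse(yy, xx, cy, cx, r, 0.85 * r, theta)

    # Nucleus lobes placed around the cell center along the cell axis; each
    # lobe area is sized so the union approximates nucleus_fraction of the cell.
    lobes = appearance.nucleus_lobes
    rn = r * np.sqrt(appearance.nucleus_fraction / lobes) * (1.1 if lobes > 1 else 1.0)
    nucleus = np.zeros_like(cell)
    if lobes == 1:
        offsets = [0.0]
    else:
        offsets = np.linspace(-0.45 * r, 0.45 * r, lobes)
    for k, off in enumerate(offsets):
        ang = theta + (0.5 * (k - (lobes - 1) / 2)) * 0.3
        ly = cy + off * np.sin(theta)
        lx = cx + off * np.cos(theta)
        nucleus |= _ellipse(yy, xx, ly, lx, rn, 0.85 * rn, ang)
    if appearance.kidney_notch:
        # carve a concave bite out of the nucleus to mimic a kidney shape
        ny = cy + 0.55 * rn * np.sin(theta + np.pi / 2)
        nx = cx + 0.55 * rn * np.cos(theta + np.pi / 2)
        nucleus &= ~_ellipse(yy, xx, ny, nx, 0.6 * rn, 0.6 * rn, 0.0)
    nucleus &= cell

    img = np.empty((side, side, 3), dtype=float)
    img[:] = _hsv_rgb(*_BACKGROUND_HSV)
    img[cell] = _hsv_rgb(appearance.cytoplasm_hue + hue_d,
                         appearance.cytoplasm_saturation,
                         appearance.cytoplasm_value)
    img[nucleus] = _hsv_rgb(appearance.nucleus_hue + hue_d,
                            appearance.nucleus_saturation,
                            appearance.nucleus_value)
    img += rng.uniform(-NOISE_AMPLITUDE, NOISE_AMPLITUDE, img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    mask = cell.astype(np.uint8)
    if mask.sum() == 0:
        raise RuntimeError("rendered cell has no foreground pixels")
    label = CellClass.from_name(appearance.cell_class) if appearance.cell_class else None
    return SyntheticSample(image=img, mask=mask, label=label, seed=seed)


def generate_dataset(n_per_class: int, image_side: int = REFERENCE_SIDE,
                     seed: int = 0) -> list[SyntheticSample]:
    """Generate a balanced labeled dataset, 4*n_per_class samples.

    Per-sample seeds are ``seed + sample_index`` with samples ordered
    class-major (all eosinophils first), so the sequence is reproducible and
    individual samples can be re-rendered in isolation.
    """
    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    samples: list[SyntheticSample] = []
    for c, name in enumerate(CLASS_NAMES):
        app = default_appearance(name)
        for j in range(n_per_class):
            sample_seed = seed + c * n_per_class + j
            samples.append(render_cell(app, image_side, sample_seed))
    return samples


def write_dataset(samples: list[SyntheticSample], root: str | Path) -> Path:
    """Write samples as ``<root>/<class>/<i>.png`` plus masks and a manifest.

    Masks go to ``<root>/masks/<class>/<i>.png`` as 8-bit 0/255 PNGs; the
    manifest CSV has header ``filename,label`` with class-relative paths.
    """
    from PIL import Image

    root = Path(root)
    rows: list[tuple[str, str]] = []
    counters: dict[str, int] = {}
    for s in samples:
        if s.label is None:
            raise ValueError("cannot write an unlabeled sample")
        name = s.label.name
        i = counters.get(name, 0)
        counters[name] = i + 1
        rel = f"{name}/{i}.png"
        img_path = root / rel
        mask_path = root / "masks" / rel
        img_path.parent.mkdir(parents=True, exist_ok=True)
        mask_path.parent.mkdir(parents=True, exist_ok=True)
        Image.fromarray((s.image * 255).round().astype(np.uint8)).save(img_path)
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(mask_path)
        rows.append((rel, name))
    manifest = root / "labels.csv"
    with open(manifest, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "label"])
        w.writerows(rows)
    return manifest


def scaled_appearance(appearance: CellAppearance, **overrides) -> CellAppearance:
    """Return a copy of an appearance with selected fields overridden."""
    return replace(appearance, **overrides)
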