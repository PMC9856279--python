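"""Synthetic microscopy-like image generator for the four iPSC-derived classes.

The real image collections this pipeline was designed for are not publicly
deposited, so this module renders labelled stand-ins that carry the same
class-distinguishing morphology at a controllable, testable level:

* **IPSC** — bright compact colonies with a sharp (high-gradient) border.
* **MSC**  — thin elongated fibroblast-like streaks.
* **RGC**  — branching neurite-like polylines.
* **RPE**  — dark-brown pigment patches whose areal fraction is set by a
  differentiation-degree parameter in ``[0, 1]``.

Every image is a pure function of its :class:`PhenotypeSpec` (including the
seed), which is what makes the downstream CNN/PCA/SVM stages testable:
ground-truth pigment masks and degrees are recorded in image metadata, never
in anything the models can see.

These are phenotype sketches, not photorealistic micrographs: there is no
optics model, no illumination gradient and no stain variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage import draw as skdraw

from .types import CLASS_ORDER, CellClass, LabeledImage

__all__ = [
    "PIGMENT_LUMINANCE_THRESHOLD",
    "PhenotypeSpec",
    "generate_image",
    "stamp_scale_bar",
    "generate_dataset",
    "write_dataset",
    "luminance",
    "pigment_fraction",
]

#: Luminance (Rec. 601, 0-255 scale) below which a pixel counts as pigment.
#: Non-RPE phenotypes are drawn strictly above this, RPE pigment strictly
#: below, so thresholding is an exact ground-truth probe on synthetic images.
PIGMENT_LUMINANCE_THRESHOLD = 90.0

_BG_LEVEL = 200.0          # light-gray background mean
_BAR_COLOR = 245           # near-white scale bar
_DEFAULT_BAR = (80, 12)    # width x height in px at 512 canvas


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an RGB array, on the input's intensity scale."""
    px = np.asarray(pixels, dtype=np.float64)
    return 0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2]


def pigment_fraction(pixels: np.ndarray,
                     threshold: float = PIGMENT_LUMINANCE_THRESHOLD) -> float:
    """Fraction of pixels darker than the pigment luminance threshold."""
    return float(np.mean(luminance(pixels) < threshold))


@dataclass(frozen=True)
class PhenotypeSpec:
    """Recipe for one synthetic image.

    ``rpe_degree`` is the target areal fraction of pigment and is only
    consulted for ``cell_class = RPE``; other classes render zero pigment.
    ``n_structures`` overrides the per-class default count of colonies /
    streaks / neurite trees / pigment patch clusters.
    """

    cell_class: CellClass
    canvas_side: int = 512
    rpe_degree: float = 0.5
    texture_noise_sd: float = 8.0
    n_structures: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not isinstance(self.cell_class, CellClass):
            object.__setattr__(self, "cell_class", CellClass.parse(self.cell_class))
        if self.canvas_side < 64:
            raise ValueError(f"canvas_side must be >= 64, got {self.canvas_side}")
        if not (0.0 <= self.rpe_degree <= 1.0):
            raise ValueError(f"rpe_degree must lie in [0, 1], got {self.rpe_degree}")
        if self.texture_noise_sd < 0:
            raise ValueError("texture_noise_sd must be non-negative")


def _background(rng: np.random.Generator, side: int, noise_sd: float) -> np.ndarray:
    noise = rng.normal(0.0, noise_sd, size=(side, side))
    # keep background luminance safely above the pigment threshold
    np.clip(noise, -3.5 * noise_sd - 1e-9, 3.5 * noise_sd + 1e-9, out=noise)
    canvas = _BG_LEVEL + noise
    return np.repeat(canvas[:, :, None], 3, axis=2)


def _fill_ellipse(canvas: np.ndarray, rng: np.random.Generator,
                  center: tuple[float, float], radii: tuple[float, float],
                  angle: float, color: np.ndarray, jitter: float) -> np.ndarray:
    side = canvas.shape[0]
    rr, cc = skdraw.ellipse(center[0], center[1], radii[0], radii[1],
                            shape=(side, side), rotation=angle)
    col = color + rng.normal(0.0, jitter, size=3)
    canvas[rr, cc] = col
    mask = np.zeros((side, side), dtype=bool)
    mask[rr, cc] = True
    return mask


def _draw_ipsc(canvas: np.ndarray, rng: np.random.Generator, n: int) -> None:
    """Bright compact colonies with a darker rim: sharp, high-gradient border."""
    side = canvas.shape[0]
    for _ in range(n):
        cy, cx = rng.uniform(0.15 * side, 0.85 * side, size=2)
        ry = rng.uniform(0.10 * side, 0.22 * side)
        rx = ry * rng.uniform(0.75, 1.3)
        ang = rng.uniform(0, math.pi)
        rim_w = max(2.0, 0.012 * side)
        _fill_ellipse(canvas, rng, (cy, cx), (ry + rim_w, rx + rim_w), ang,
                      np.array([122.0, 120.0, 118.0]), 4.0)
        _fill_ellipse(canvas, rng, (cy, cx), (ry, rx), ang,
                      np.array([236.0, 233.0, 228.0]), 4.0)


def _thick_line(canvas: np.ndarray, r0: int, c0: int, r1: int, c1: int,
                color: np.ndarray, width: int) -> None:
    side = canvas.shape[0]
    for off in range(width):
        dr = off - width // 2
        rr, cc = skdraw.line(r0 + dr, c0, r1 + dr, c1)
        ok = (rr >= 0) & (rr < side) & (cc >= 0) & (cc < side)
        canvas[rr[ok], cc[ok]] = color


def _draw_msc(canvas: np.ndarray, rng: np.random.Generator, n: int) -> None:
    """Thin elongated fibroblast streaks, mid-gray, roughly aligned bundles."""
    side = canvas.shape[0]
    base_angle = rng.uniform(0, math.pi)
    for _ in range(n):
        ang = base_angle + rng.normal(0.0, 0.45)
        length = rng.uniform(0.35, 0.75) * side
        cy, cx = rng.uniform(0.05 * side, 0.95 * side, size=2)
        dy, dx = math.sin(ang) * length / 2, math.cos(ang) * length / 2
        col = np.array([148.0, 146.0, 144.0]) + rng.normal(0, 4.0)
        width = 1 if side < 128 else 2
        _thick_line(canvas, int(cy - dy), int(cx - dx),
                    int(cy + dy), int(cx + dx), col, width)


def _draw_rgc(canvas: np.ndarray, rng: np.random.Generator, n: int) -> None:
    """Branching neurite trees: recursive forking polylines from dark somas."""
    side = canvas.shape[0]

    def grow(r: float, c: float, ang: float, depth: int, length: float) -> None:
        if depth == 0 or length < 2:
            return
        r1 = r + math.sin(ang) * length
        c1 = c + math.cos(ang) * length
        col = np.array([112.0, 108.0, 104.0]) + rng.normal(0, 3.0)
        _thick_line(canvas, int(r), int(c), int(r1), int(c1), col, 1)
        n_children = 2 if rng.random() < 0.7 else 1
        for _ in range(n_children):
            grow(r1, c1, ang + rng.normal(0.0, 0.55), depth - 1,
                 length * rng.uniform(0.6, 0.9))

    for _ in range(n):
        cy, cx = rng.uniform(0.2 * side, 0.8 * side, size=2)
        rr, cc = skdraw.disk((cy, cx), max(2.0, 0.015 * side), shape=(side, side))
        canvas[rr, cc] = np.array([104.0, 100.0, 97.0])
        n_neurites = rng.integers(3, 6)
        for _ in range(n_neurites):
            grow(cy, cx, rng.uniform(0, 2 * math.pi), depth=4,
                 length=rng.uniform(0.12, 0.2) * side)


def _draw_rpe(canvas: np.ndarray, rng: np.random.Generator,
              degree: float) -> np.ndarray:
    """Dark-brown pigment ellipses until ~``degree`` of the canvas is covered.

    Returns the ground-truth pigment mask. Patch placement is rejection-free:
    ellipses are added until the covered fraction reaches the target, so the
    achieved fraction overshoots by at most one ellipse (< ~3% of the canvas).
    """
    side = canvas.shape[0]
    mask = np.zeros((side, side), dtype=bool)
    if degree <= 0:
        return mask
    brown = np.array([74.0, 52.0, 38.0])   # luminance ~ 57, well below 90
    max_iter = 20000
    it = 0
    while mask.mean() < degree and it < max_iter:
        it += 1
        cy, cx = rng.uniform(0, side, size=2)
        ry = rng.uniform(0.035, 0.08) * side
        rx = ry * rng.uniform(0.6, 1.4)
        ang = rng.uniform(0, math.pi)
        m = _fill_ellipse(canvas, rng, (cy, cx), (ry, rx), ang, brown, 5.0)
        mask |= m
    return mask


_DEFAULT_N = {CellClass.IPSC: 3, CellClass.MSC: 25,
              CellClass.RGC: 4, CellClass.RPE: 0}


def generate_image(spec: PhenotypeSpec) -> LabeledImage:
    """Render one labelled synthetic image from its spec.

    Identical ``(spec, seed)`` pairs yield byte-identical images. For RPE the
    ground-truth pigment mask is stored under ``meta["pigment_mask"]`` and the
    target degree under ``rpe_degree``; other classes contain zero pigment
    (no pixel below the pigment luminance threshold).
    """
    rng = np.random.default_rng(spec.seed)
    canvas = _background(rng, spec.canvas_side, spec.texture_noise_sd)
    n = spec.n_structures if spec.n_structures is not None \
        else _DEFAULT_N[spec.cell_class]

    meta: dict = {}
    degree: float | None = None
    if spec.cell_class is CellClass.IPSC:
        _draw_ipsc(canvas, rng, n)
    elif spec.cell_class is CellClass.MSC:
        _draw_msc(canvas, rng, n)
    elif spec.cell_class is CellClass.RGC:
        _draw_rgc(canvas, rng, n)
    elif spec.cell_class is CellClass.RPE:
        degree = spec.rpe_degree
        meta["pigment_mask"] = _draw_rpe(canvas, rng, degree)
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown cell class {spec.cell_class}")

    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    return LabeledImage(
        pixels=pixels,
        label=spec.cell_class,
        source_id=f"{spec.cell_class.value.lower()}-{spec.seed}",
        rpe_degree=degree,
        meta=meta,
    )


def stamp_scale_bar(img: LabeledImage,
                    corner: str = "bottom_right",
                    bar_px: tuple[int, int] = _DEFAULT_BAR,
                    margin: int = 4) -> LabeledImage:
    """Burn a near-white scale bar with tick marks into one corner.

    All modified pixels lie inside the ``width x height`` bar rectangle;
    everything else is untouched. Returns a copy with ``has_scale_bar=True``.
    """
    h_img, w_img = img.pixels.shape[:2]
    w, h = bar_px
    if w <= 0 or h <= 0:
        raise ValueError("bar dimensions must be positive")
    if w + margin > w_img or h + margin > h_img:
        raise ValueError(
            f"scale bar {bar_px} does not fit a {h_img}x{w_img} image")

    corners = {
        "top_left": (margin, margin),
        "top_right": (margin, w_img - margin - w),
        "bottom_left": (h_img - margin - h, margin),
        "bottom_right": (h_img - margin - h, w_img - margin - w),
    }
    if corner not in corners:
        raise ValueError(f"corner must be one of {sorted(corners)}, got {corner!r}")
    r0, c0 = corners[corner]

    out = img.pixels.copy()
    out[r0:r0 + h, c0:c0 + w] = _BAR_COLOR
    # text-like tick marks inside the bar rectangle
    tick_h = max(1, h // 3)
    for fx in (0.2, 0.5, 0.8):
        c = c0 + int(fx * (w - 1))
        out[r0:r0 + tick_h, c] = 40
    stamped = img.with_pixels(out)
    stamped.has_scale_bar = True
    stamped.meta = dict(img.meta)
    stamped.meta.setdefault("scale_bar_rects", [])
    stamped.meta["scale_bar_rects"] = list(stamped.meta["scale_bar_rects"]) + \
        [(r0, c0, h, w)]
    return stamped


def _degree_sampler(sampler, rng: np.random.Generator) -> float:
    if callable(sampler):
        return float(sampler(rng))
    if isinstance(sampler, (int, float)):
        return float(sampler)
    kind = sampler[0]
    if kind == "uniform":
        return float(rng.uniform(sampler[1], sampler[2]))
    if kind == "choice":
        return float(rng.choice(np.asarray(sampler[1], dtype=float)))
    raise ValueError(f"unknown rpe_degree sampler: {sampler!r}")


def generate_dataset(per_class_counts: dict,
                     rpe_degree_sampler=("uniform", 0.0, 1.0),
                     seed: int = 0,
                     canvas_side: int = 512,
                     texture_noise_sd: float = 8.0,
                     scale_bar_frac: float = 0.0,
                     scale_bar_classes: tuple[CellClass, ...] | None = None,
                     scale_bar_px: tuple[int, int] | None = None) -> list[LabeledImage]:
    """Generate a shuffled labelled dataset with the requested class counts.

    RPE degrees are drawn from ``rpe_degree_sampler`` (a constant, a
    ``("uniform", lo, hi)`` / ``("choice", values)`` tuple, or a callable of
    the rng) and recorded on each image as ground truth. With
    ``scale_bar_frac > 0``, that fraction of images (optionally restricted to
    ``scale_bar_classes``) gets a corner scale bar stamped. The whole dataset
    is a pure function of its arguments.
    """
    counts = {CellClass.parse(k) if not isinstance(k, CellClass) else k: int(v)
              for k, v in per_class_counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("per-class counts must be >= 0")
    if not (0.0 <= scale_bar_frac <= 1.0):
        raise ValueError("scale_bar_frac must lie in [0, 1]")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5eed]))
    if scale_bar_px is None:
        scale_bar_px = (max(8, canvas_side * _DEFAULT_BAR[0] // 512),
                        max(3, canvas_side * _DEFAULT_BAR[1] // 512))

    images: list[LabeledImage] = []
    idx = 0
    for cls in CLASS_ORDER:
        for _ in range(counts.get(cls, 0)):
            child_seed = int(rng.integers(0, 2**31 - 1))
            degree = _degree_sampler(rpe_degree_sampler, rng) \
                if cls is CellClass.RPE else 0.5
            spec = PhenotypeSpec(cell_class=cls, canvas_side=canvas_side,
                                 rpe_degree=degree,
                                 texture_noise_sd=texture_noise_sd,
                                 seed=child_seed)
            img = generate_image(spec)
            img.source_id = f"{cls.value.lower()}-{idx:05d}"
            img.meta["seed"] = child_seed
            stamp = rng.random() < scale_bar_frac and (
                scale_bar_classes is None or cls in scale_bar_classes)
            if stamp:
                img = stamp_scale_bar(img, "bottom_right", scale_bar_px)
            images.append(img)
            idx += 1

    order = rng.permutation(len(images))
    return [images[i] for i in order]


def write_dataset(images: list[LabeledImage], out_dir) -> "pandas.DataFrame":
    """Write images as PNGs plus a CSV manifest; returns the manifest."""
    import pandas as pd
    from PIL import Image
    from pathlib import Path

    out = Path(out_dir)
    rows = []
    for img in images:
        cls_dir = out / img.label.value
        cls_dir.mkdir(parents=True, exist_ok=True)
        path = cls_dir / f"{img.source_id}.png"
        Image.fromarray(img.pixels).save(path)
        rows.append({
            "path": str(path.relative_to(out)),
            "label": img.label.value,
            "rpe_degree": img.rpe_degree if img.rpe_degree is not None else "",
            "has_scale_bar": img.has_scale_bar,
            "seed": img.meta.get("seed", ""),
        })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
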