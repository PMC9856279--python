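"""Image loading and preprocessing for the multi-slice tensor pipeline.

The preprocessing chain mirrors how the models consume microscopy images:
an optional centered crop that discards burned-in scale bars at the margins,
a bilinear resize to the canonical 512 x 512 canvas, pixel scaling to either
``[0, 1]`` or ``[-1, 1]``, and slicing into the five-tensor bundle (one
macroscopic whole-image tensor plus four quadrant tensors) the multi-branch
CNN expects. Training-set expansion by the four flip variants and by
quadrant "cut images" lives here too, as does the train/val/test split.

Conventions frozen across the package: row-major arrays with origin at the
top-left, 0-based indices, half-open slices; quadrant order TL, TR, BL, BR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import CLASS_ORDER, CellClass, LabeledImage

__all__ = [
    "SliceBundle", "DatasetSplit",
    "load_image", "save_image", "read_manifest",
    "crop_scale_bar", "canonicalize", "scale_pixels", "make_slices",
    "prepare_bundle", "augment_flips", "divide_expand", "split_dataset",
]

CANVAS_SIDE = 512
SCALE_MODES = ("zero_one", "sym_one")


@dataclass
class SliceBundle:
    """The five-tensor CNN input: a macro tensor plus its four quadrants.

    ``macro`` is ``S x S x 3`` float; ``quadrants`` are the TL, TR, BL, BR
    ``S/2 x S/2 x 3`` blocks of ``macro`` in that fixed order, so stitching
    the quadrants back together reproduces ``macro`` exactly.
    """

    macro: np.ndarray
    quadrants: list[np.ndarray]
    scale_mode: str

    def __post_init__(self) -> None:
        s = self.macro.shape[0]
        if self.macro.shape != (s, s, 3) or s % 2:
            raise ValueError(f"macro must be SxSx3 with even S, got {self.macro.shape}")
        if len(self.quadrants) != 4 or any(
                q.shape != (s // 2, s // 2, 3) for q in self.quadrants):
            raise ValueError("need exactly four S/2 x S/2 x 3 quadrants")
        if self.scale_mode not in SCALE_MODES:
            raise ValueError(f"scale_mode must be one of {SCALE_MODES}")
        lo, hi = (0.0, 1.0) if self.scale_mode == "zero_one" else (-1.0, 1.0)
        if self.macro.min() < lo - 1e-9 or self.macro.max() > hi + 1e-9:
            raise ValueError(f"macro values outside [{lo}, {hi}] for {self.scale_mode}")

    @property
    def side(self) -> int:
        return self.macro.shape[0]

    def reassembled(self) -> np.ndarray:
        """Stitch the four quadrants back into a full-size tensor."""
        tl, tr, bl, br = self.quadrants
        top = np.concatenate([tl, tr], axis=1)
        bottom = np.concatenate([bl, br], axis=1)
        return np.concatenate([top, bottom], axis=0)


@dataclass
class DatasetSplit:
    """Train/val/test membership with the fractions and seed that made it."""

    train: list[LabeledImage]
    val: list[LabeledImage]
    test: list[LabeledImage]
    train_frac: float = 0.0
    val_frac_of_augmented_train: float = 0.20
    seed: int = 0

    def counts(self) -> dict[str, int]:
        return {"train": len(self.train), "val": len(self.val),
                "test": len(self.test)}

    def membership_frame(self) -> "pandas.DataFrame":
        import pandas as pd
        rows = []
        for name, imgs in (("train", self.train), ("val", self.val),
                           ("test", self.test)):
            for im in imgs:
                base, _, variant = im.source_id.partition(":")
                rows.append({"source_id": base, "split": name,
                             "variant": variant or "orig",
                             "label": im.label.value})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO

def load_image(path, label: CellClass | str | None = None) -> LabeledImage:
    """Load a JPEG/PNG/TIFF image as a 3-channel uint8 :class:`LabeledImage`.

    Grayscale inputs are replicated across channels; an alpha channel is
    dropped; 16-bit TIFFs are linearly rescaled to 8-bit. When ``label`` is
    not given it is parsed from the parent directory name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            import tifffile
            arr = np.asarray(tifffile.imread(str(path)))
        else:
            from PIL import Image
            with Image.open(path) as im:
                im.load()
                arr = np.asarray(im)
    except Exception as exc:
        raise OSError(f"could not read image {path}: {exc}") from exc

    if arr.dtype == np.uint16:
        arr = np.rint(arr.astype(np.float64) / 65535.0 * 255.0).astype(np.uint8)
    elif arr.dtype != np.uint8:
        if np.issubdtype(arr.dtype, np.integer):
            arr = np.clip(arr, 0, 255).astype(np.uint8)
        else:
            raise OSError(f"unsupported bit depth {arr.dtype} in {path}")

    if arr.ndim == 2:
        arr = np.repeat(arr[:, :, None], 3, axis=2)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    elif arr.ndim != 3 or arr.shape[2] != 3:
        raise OSError(f"unsupported image layout {arr.shape} in {path}")

    if label is None:
        try:
            label = CellClass.parse(path.parent.name)
        except ValueError:
            raise ValueError(
                f"no label given and directory {path.parent.name!r} is not a "
                f"cell class") from None
    elif not isinstance(label, CellClass):
        label = CellClass.parse(label)
    return LabeledImage(pixels=arr, label=label, source_id=path.stem)


def save_image(img: LabeledImage, path) -> None:
    """Write pixels losslessly (PNG/TIFF) or as JPEG by extension."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(str(path), img.pixels)
    else:
        from PIL import Image
        Image.fromarray(img.pixels).save(path)


def read_manifest(data_dir) -> list[LabeledImage]:
    """Load a dataset written by :func:`mstcell.synthetic.write_dataset`."""
    import pandas as pd
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    images = []
    for row in manifest.itertuples():
        img = load_image(data_dir / row.path, label=row.label)
        img.has_scale_bar = bool(row.has_scale_bar)
        if row.rpe_degree == row.rpe_degree and row.rpe_degree != "":  # not NaN
            img.rpe_degree = float(row.rpe_degree)
        images.append(img)
    return images


# ---------------------------------------------------------------------------
# Per-image transforms

def crop_scale_bar(img: LabeledImage, margin_frac: float = 0.05) -> LabeledImage:
    """Centered crop removing ``margin_frac`` of each edge (scale-bar removal).

    Burned-in scale bars sit at the image margins, so a fixed-margin centered
    crop discards them without any detection step. ``margin_frac = 0`` is the
    identity.
    """
    if not (0.0 <= margin_frac < 0.25):
        raise ValueError(f"margin_frac must lie in [0, 0.25), got {margin_frac}")
    h, w = img.pixels.shape[:2]
    mh, mw = math.floor(h * margin_frac), math.floor(w * margin_frac)
    out = img.with_pixels(img.pixels[mh:h - mh, mw:w - mw].copy())
    out.has_scale_bar = False
    return out


def canonicalize(img: LabeledImage | np.ndarray,
                 side: int = CANVAS_SIDE) -> np.ndarray:
    """Bilinear-resize to the canonical ``side x side x 3`` float tensor.

    Values stay on the 0-255 scale as float64. A same-size input is returned
    numerically unchanged (no-op resize).
    """
    px = img.pixels if isinstance(img, LabeledImage) else np.asarray(img)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected HxWx3 input, got {px.shape}")
    px = px.astype(np.float64)
    if px.shape[:2] == (side, side):
        return px.copy()
    return _sk_resize(px, (side, side), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def scale_pixels(t: np.ndarray, mode: str) -> np.ndarray:
    """Map 0-255 floats to [0,1] (``zero_one``) or [-1,1] (``sym_one``)."""
    if mode not in SCALE_MODES:
        raise ValueError(f"mode must be one of {SCALE_MODES}, got {mode!r}")
    t = np.asarray(t, dtype=np.float64)
    if t.min() < 0 or t.max() > 255:
        raise ValueError("pixel values must lie in [0, 255] before scaling")
    return t / 255.0 if mode == "zero_one" else t / 127.5 - 1.0


def make_slices(t: np.ndarray, mode: str) -> SliceBundle:
    """Slice a scaled ``S x S x 3`` tensor into the five-tensor bundle.

    Quadrants are the TL, TR, BL, BR blocks, in that frozen order.
    """
    t = np.asarray(t, dtype=np.float64)
    s = t.shape[0]
    if t.shape != (s, s, 3) or s % 2:
        raise ValueError(f"expected SxSx3 with even S, got {t.shape}")
    h = s // 2
    quadrants = [t[:h, :h].copy(), t[:h, h:].copy(),
                 t[h:, :h].copy(), t[h:, h:].copy()]
    return SliceBundle(macro=t.copy(), quadrants=quadrants, scale_mode=mode)


def prepare_bundle(img: LabeledImage, mode: str = "sym_one",
                   side: int = CANVAS_SIDE,
                   crop_margin: float = 0.0) -> SliceBundle:
    """Full chain crop → canonicalize → scale → slice for one image."""
    if crop_margin > 0:
        img = crop_scale_bar(img, crop_margin)
    return make_slices(scale_pixels(canonicalize(img, side), mode), mode)


# ---------------------------------------------------------------------------
# Dataset-level transforms

_FLIPS = (("orig", (False, False)), ("h", (False, True)),
          ("v", (True, False)), ("hv", (True, True)))


def augment_flips(imgs: list[LabeledImage]) -> list[LabeledImage]:
    """Expand each image into {original, h-flip, v-flip, hv-flip} (4x).

    Labels are preserved and provenance ids get a variant suffix, so flip
    variants of one source remain traceable to it.
    """
    if not imgs:
        raise ValueError("augment_flips needs a nonempty list")
    out = []
    for img in imgs:
        for name, (fv, fh) in _FLIPS:
            px = img.pixels
            if fv:
                px = np.flip(px, axis=0)
            if fh:
                px = np.flip(px, axis=1)
            out.append(img.with_pixels(np.ascontiguousarray(px), suffix=name))
    return out


def divide_expand(imgs: list[LabeledImage],
                  side: int | None = None) -> list[LabeledImage]:
    """Add each image's four quadrants, upscaled to full size, as samples (5x).

    The quadrant "cut images" inherit the parent's label and teach the model
    to cope with different magnifications.
    """
    if not imgs:
        raise ValueError("divide_expand needs a nonempty list")
    out = []
    for img in imgs:
        out.append(img)
        h, w = img.pixels.shape[:2]
        target = side or max(h, w)
        blocks = (("q0", img.pixels[:h // 2, :w // 2]),
                  ("q1", img.pixels[:h // 2, w // 2:]),
                  ("q2", img.pixels[h // 2:, :w // 2]),
                  ("q3", img.pixels[h // 2:, w // 2:]))
        for name, block in blocks:
            up = _sk_resize(block.astype(np.float64), (target, target), order=1,
                            mode="edge", anti_aliasing=False, preserve_range=True)
            up8 = np.clip(np.rint(up), 0, 255).astype(np.uint8)
            out.append(img.with_pixels(up8, suffix=name))
    return out


def split_dataset(imgs: list[LabeledImage], train_frac: float,
                  val_frac_of_augmented: float = 0.20,
                  seed: int = 0, augment: bool = True) -> DatasetSplit:
    """Split sources into train/val/test, augmenting only the training pool.

    Test images are drawn first, before augmentation, and never augmented.
    The remaining sources are expanded 4x by flips, then
    ``floor(val_frac_of_augmented * len(augmented))`` samples are held out as
    the validation subset by a seeded uniform draw. With the published counts
    (1291 training sources) this yields 5164 augmented training samples of
    which 1032 form the validation subset.

    Note: flip variants of one source may land in both train and validation;
    the sampling is over augmented samples, not over sources.
    """
    if not (0.0 < train_frac < 1.0):
        raise ValueError(f"train_frac must lie in (0, 1), got {train_frac}")
    if not (0.0 <= val_frac_of_augmented < 1.0):
        raise ValueError("val_frac_of_augmented must lie in [0, 1)")
    if not imgs:
        raise ValueError("cannot split an empty dataset")

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(imgs))
    n_train = int(round(train_frac * len(imgs)))
    train_sources = [imgs[i] for i in order[:n_train]]
    test = [imgs[i] for i in order[n_train:]]

    pool = augment_flips(train_sources) if augment else list(train_sources)
    n_val = math.floor(val_frac_of_augmented * len(pool))
    val_idx = set(rng.choice(len(pool), size=n_val, replace=False).tolist())
    val = [pool[i] for i in sorted(val_idx)]
    train = [pool[i] for i in range(len(pool)) if i not in val_idx]
    return DatasetSplit(train=train, val=val, test=test, train_frac=train_frac,
                        val_frac_of_augmented_train=val_frac_of_augmented,
                        seed=seed)
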