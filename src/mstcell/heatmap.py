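"""Class-activation heatmaps at the merge convolution layer.

Gradient-weighted class-activation mapping, computed at the merge conv's
input — the concatenation of the five branch outputs, the last point where
channels are still attributable to individual branches. Two choices depart
from the classic global-average-pooled formulation, both because of this
architecture:

* activations are weighted by their gradients *element-wise* (as in
  HiResCAM) rather than by spatially pooled channel weights — with a
  flatten head instead of global average pooling, the element-wise product
  is the faithful first-order attribution, and the 16x16-or-smaller maps
  leave no spatial resolution to spare;
* each branch's rectified map is painted into the image region that branch
  actually sees — the macro map covers the whole canvas, each quadrant map
  only its quadrant — then the summed canvas map is normalised to
  ``[0, 1]``. Upsampling the merged map directly would smear quadrant
  evidence across the full image.

Corner artifacts such as burned-in scale bars therefore light up in the
correct corner whether the macro or a quadrant branch picked them up.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .model import MultiSliceModel
from .preprocess import SliceBundle
from .types import CLASS_ORDER, CellClass

__all__ = ["Heatmap", "compute_heatmap"]


@dataclass
class Heatmap:
    """Normalised attention weights plus an RGB overlay on the input."""

    weights: np.ndarray
    overlay: np.ndarray
    target_class: CellClass

    def heat_mass_fraction(self, rect: tuple[int, int, int, int]) -> float:
        """Fraction of total heat inside ``(row, col, height, width)``."""
        total = float(self.weights.sum())
        if total == 0:
            return 0.0
        r, c, h, w = rect
        return float(self.weights[r:r + h, c:c + w].sum()) / total

    def save_triptych(self, path, input_rgb: np.ndarray | None = None) -> None:
        """PNG with input | heat | overlay panels side by side."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, axes = plt.subplots(1, 3, figsize=(10.5, 3.6))
        if input_rgb is not None:
            axes[0].imshow(np.clip(input_rgb, 0, 255).astype(np.uint8))
        axes[0].set_title("input")
        axes[1].imshow(self.weights, cmap="jet", vmin=0, vmax=1)
        axes[1].set_title(f"heatmap ({self.target_class.value})")
        axes[2].imshow(np.clip(self.overlay, 0, 255).astype(np.uint8))
        axes[2].set_title("overlay")
        for ax in axes:
            ax.axis("off")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def _bundle_rgb(bundle: SliceBundle) -> np.ndarray:
    """Undo pixel scaling to recover a 0-255 RGB rendering of the macro."""
    if bundle.scale_mode == "zero_one":
        return bundle.macro * 255.0
    return (bundle.macro + 1.0) * 127.5


def compute_heatmap(model: MultiSliceModel, bundle: SliceBundle,
                    target_class: CellClass | str | None = None,
                    alpha: float = 0.4,
                    weighting: str = "elementwise") -> Heatmap:
    """Gradient-weighted class-activation map, upsampled to the canvas.

    ``target_class`` defaults to the model's predicted class. ``weighting``
    selects how gradients weight activations: ``"elementwise"`` (default,
    faithful to the flatten head and spatially sharp) or ``"pooled"`` (the
    classic formulation with spatially averaged channel weights, which is
    constant on constant inputs but blind to position-specific evidence).
    A map with no positive evidence (all-zero after rectification) is
    returned as zeros rather than being renormalised into spurious
    structure.
    """
    if weighting not in ("elementwise", "pooled"):
        raise ValueError("weighting must be 'elementwise' or 'pooled'")
    if bundle.scale_mode != model.cfg.scale_mode:
        raise ValueError("bundle scale_mode does not match the model's")
    if target_class is None:
        probs = model.predict_proba(bundle)
        cls = CLASS_ORDER[int(np.argmax(probs[0]))]
    elif isinstance(target_class, CellClass):
        cls = target_class
    else:
        cls = CellClass.parse(target_class)

    pairs = model.branch_activation_grads(bundle, CLASS_ORDER.index(cls))
    side = model.cfg.canvas_side
    half = side // 2
    regions = [(0, 0, side)]                       # macro covers the canvas
    if model.n_branches == 5:                      # quadrants: TL, TR, BL, BR
        regions += [(0, 0, half), (0, half, half),
                    (half, 0, half), (half, half, half)]
    full = np.zeros((side, side))
    for (a, g), (r0, c0, extent) in zip(pairs, regions):
        gw = g[0] if weighting == "elementwise" else g[0].mean(axis=(0, 1))
        cam = np.maximum((a[0] * gw).sum(axis=2), 0.0)
        full[r0:r0 + extent, c0:c0 + extent] += _sk_resize(
            cam, (extent, extent), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True)
    if full.max() > 0:
        full = full / full.max()
    up = np.clip(full, 0.0, 1.0)

    import matplotlib
    matplotlib.use("Agg")
    colored = matplotlib.colormaps["jet"](up)[..., :3] * 255.0
    rgb = _bundle_rgb(bundle)
    overlay = (1.0 - alpha) * rgb + alpha * colored
    return Heatmap(weights=up, overlay=overlay, target_class=cls)
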