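"""Shared domain types for the iPSC image-recognition pipeline.

The pipeline recognises four cell classes derived from induced pluripotent
stem cells (iPSCs): undifferentiated iPSC colonies, mesenchymal stem cells
(MSC, fibroblast-like streaks), retinal ganglion cells (RGC, branching
neurites) and retinal pigment epithelium (RPE, dark-brown pigment patches).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["CellClass", "CLASS_ORDER", "LabeledImage"]


class CellClass(enum.Enum):
    """The four recognised cell classes, in the fixed reporting order."""

    IPSC = "IPSC"
    MSC = "MSC"
    RGC = "RGC"
    RPE = "RPE"

    @classmethod
    def parse(cls, name: str) -> "CellClass":
        key = str(name).strip().upper()
        # tolerate directory names like "iPSC-RPE"
        for prefix in ("IPSC-", "IPSC_"):
            if key.startswith(prefix) and key != "IPSC":
                key = key[len(prefix):]
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown cell class: {name!r}") from None


#: Fixed class order used for labels, softmax outputs and confusion matrices.
CLASS_ORDER: tuple[CellClass, ...] = (
    CellClass.IPSC,
    CellClass.MSC,
    CellClass.RGC,
    CellClass.RPE,
)


@dataclass
class LabeledImage:
    """One microscopy image plus its label and provenance.

    Parameters
    ----------
    pixels
        ``H x W x 3`` uint8 array (RGB).
    label
        The cell class this image depicts.
    source_id
        Stable identifier for the source sample; augmentation variants
        append a ``:variant`` suffix so split bookkeeping can trace them.
    has_scale_bar
        Whether a burned-in scale bar is present.
    magnification_tag
        Free-text magnification annotation (e.g. ``"10x"``); not used by
        the models.
    rpe_degree
        Ground-truth differentiation degree in ``[0, 1]`` for synthetic RPE
        images; ``None`` otherwise.
    """

    pixels: np.ndarray
    label: CellClass
    source_id: str = ""
    has_scale_bar: bool = False
    magnification_tag: str = ""
    rpe_degree: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 64 or px.shape[1] < 64:
            raise ValueError(f"image too small: {px.shape[:2]} (need >= 64)")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray, suffix: str = "") -> "LabeledImage":
        """Copy with new pixels; optionally suffix the provenance id."""
        out = replace(self, pixels=pixels)
        if suffix:
            out.source_id = f"{self.source_id}:{suffix}" if self.source_id else suffix
        out.meta = dict(self.meta)
        return out
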