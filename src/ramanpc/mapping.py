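"""Prediction maps: per-pixel final classes rendered as tissue images."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from sklearn.metrics import confusion_matrix

from .core import DEFAULT_SCHEME, ClassScheme, HyperspectralMap, UNANNOTATED, mask_stats

__all__ = [
    "PredictionMap",
    "DEFAULT_PALETTE",
    "predict_map",
    "render_map",
    "confusion_vs_mask",
]

#: Colorblind-safe 7-class palette (Okabe-Ito derived); class 0 is neutral.
DEFAULT_PALETTE = (
    "#BBBBBB",  # stroma/empty
    "#E69F00",  # AVAC nucleus
    "#F0E442",  # AVAC cytoplasm
    "#0072B2",  # cPDAC nucleus
    "#56B4E9",  # cPDAC cytoplasm
    "#D55E00",  # IPMC nucleus
    "#CC79A7",  # IPMC cytoplasm
)


@dataclass
class PredictionMap:
    """A height x width grid of final classes 0..6 with provenance tags."""

    classes: np.ndarray
    provenance: dict = field(default_factory=dict)
    scheme: ClassScheme = DEFAULT_SCHEME

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype=np.int64)
        if self.classes.ndim != 2:
            raise ValueError("classes must be 2-D")
        if self.classes.size and (
            self.classes.min() < 0 or self.classes.max() >= self.scheme.n_classes
        ):
            raise ValueError("predicted classes must lie in 0..6")

    @property
    def height(self) -> int:
        return int(self.classes.shape[0])

    @property
    def width(self) -> int:
        return int(self.classes.shape[1])

    def class_counts(self):
        """Per-class pixel counts of the prediction grid."""
        return mask_stats(self.classes, self.scheme.n_classes).counts


def predict_map(
    hmap: HyperspectralMap,
    cnn_model,
    dense_model=None,
    preprocessor=None,
) -> PredictionMap:
    """Classify every pixel of a map, preserving pixel order.

    ``cnn_model`` may be a fitted :class:`~ramanpc.dense.TwoStageClassifier`
    (then ``dense_model`` is omitted) or a fitted CNN paired with a fitted
    dense model.  Pass a fitted :class:`~ramanpc.preprocess.RamanPreprocessor`
    when the map is still on the acquisition axis.
    """
    from .dense import predict_combined

    if preprocessor is not None:
        hmap = preprocessor.transform_map(hmap)
    X = hmap.spectra()
    if dense_model is None:
        flat = cnn_model.predict(X)
        provenance = {"model": type(cnn_model).__name__}
    else:
        flat = predict_combined(cnn_model, dense_model, X, hmap.axis)
        provenance = {
            "cnn_model": type(cnn_model).__name__,
            "dense_model": type(dense_model).__name__,
        }
    provenance["map_shape"] = (hmap.height, hmap.width)
    return PredictionMap(
        classes=flat.reshape(hmap.height, hmap.width), provenance=provenance
    )


def _hex_to_rgb(color: str) -> tuple[int, int, int]:
    color = color.lstrip("#")
    return tuple(int(color[i : i + 2], 16) for i in (0, 2, 4))


def render_map(
    pm: PredictionMap,
    path: str | Path,
    palette=DEFAULT_PALETTE,
    scale: int = 4,
    legend: bool = True,
) -> Path:
    """Write a deterministic PNG raster of the prediction map.

    Each pixel becomes a ``scale`` x ``scale`` block of its class color;
    with ``legend=True`` a swatch column with the class names in scheme
    order is attached on the right.  Rendering is a pure function of
    (prediction map, palette, scale): two renders are byte-identical.
    """
    if len(palette) != pm.scheme.n_classes:
        raise ValueError("palette must assign one color per class")
    rgb = [_hex_to_rgb(c) for c in palette]
    if len(set(rgb)) != len(rgb):
        raise ValueError("palette colors must be distinct")
    lut = np.asarray(rgb, dtype=np.uint8)
    raster = lut[pm.classes]  # (h, w, 3)
    raster = np.repeat(np.repeat(raster, scale, axis=0), scale, axis=1)
    h, w = raster.shape[:2]
    if legend:
        entry_h, legend_w = 18, 130
        legend_h = entry_h * pm.scheme.n_classes + 8
        canvas_h = max(h, legend_h)
        canvas = np.full((canvas_h, w + legend_w, 3), 255, dtype=np.uint8)
        canvas[:h, :w] = raster
        img = Image.fromarray(canvas)
        draw = ImageDraw.Draw(img)
        for i, name in enumerate(pm.scheme.labels):
            y0 = 4 + i * entry_h
            draw.rectangle([w + 6, y0, w + 18, y0 + 12], fill=tuple(lut[i]), outline=(0, 0, 0))
            draw.text((w + 24, y0), f"{i} {name}", fill=(0, 0, 0))
    else:
        img = Image.fromarray(raster)
    path = Path(path)
    img.save(path, format="PNG")
    return path


def confusion_vs_mask(pm: PredictionMap, mask: np.ndarray):
    """7x7 confusion matrix (rows = truth, cols = prediction) and accuracy.

    Unannotated pixels (mask value -1) are excluded.
    """
    mask = np.asarray(mask)
    if mask.shape != pm.classes.shape:
        raise ValueError(
            f"mask shape {mask.shape} != prediction shape {pm.classes.shape}"
        )
    annotated = mask != UNANNOTATED
    truth = mask[annotated].ravel()
    pred = pm.classes[annotated].ravel()
    n = pm.scheme.n_classes
    cm = confusion_matrix(truth, pred, labels=np.arange(n))
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else float("nan")
    return cm, accuracy
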