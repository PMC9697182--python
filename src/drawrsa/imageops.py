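"""Rasterization and the exact image preprocessing the feature analysis assumes.

Drawings are rendered onto a white canvas with the presented strokes in black
and the produced strokes in blue.  Before feature extraction the blue ink is
recolored to black (the presented/produced distinction is irrelevant to the
network), the image is resized to the backbone's input size with bilinear
interpolation, and per-channel means are subtracted.  For within-child
comparisons the presented layer is dropped at the stroke level (the produced
layer is re-rendered alone), which avoids halo artifacts where strokes cross.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image, ImageDraw

from .stimuli import CANVAS_SIZE

WHITE = (255, 255, 255)
BLACK = (0, 0, 0)
BLUE = (0, 0, 255)
DEFAULT_STROKE_WIDTH = 3

__all__ = [
    "RasterImage",
    "BackboneInput",
    "rasterize",
    "recolor_blue_to_black",
    "produced_only_image",
    "full_drawing_image",
    "preprocess_for_backbone",
    "save_png",
]


@dataclass(frozen=True)
class RasterImage:
    pixels: np.ndarray  # H x W x 3 uint8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("RasterImage needs an HxWx3 array")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def canvas_size(self) -> tuple:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class BackboneInput:
    array: np.ndarray   # H x W x 3 float32, mean-subtracted
    backbone_id: str

    def __post_init__(self) -> None:
        arr = np.asarray(self.array, dtype=np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("backbone input contains non-finite values")
        object.__setattr__(self, "array", arr)


def _draw_strokeset(draw: ImageDraw.ImageDraw, strokes, color, width: int) -> None:
    for stroke in strokes:
        pts = [tuple(p) for p in stroke.points]
        draw.line(pts, fill=color, width=width, joint="curve")


def rasterize(
    drawing,
    canvas_size: int = CANVAS_SIZE,
    include_presented: bool = True,
    include_produced: bool = True,
    stroke_width: int = DEFAULT_STROKE_WIDTH,
) -> RasterImage:
    """Render a drawing: white background, presented strokes black, produced
    strokes blue.  Deterministic; an empty selection yields an all-white image."""
    if not (include_presented or include_produced):
        raise ValueError("at least one of include_presented/include_produced must be set")
    img = Image.new("RGB", (canvas_size, canvas_size), WHITE)
    draw = ImageDraw.Draw(img)
    if include_presented:
        _draw_strokeset(draw, drawing.presented_strokes, BLACK, stroke_width)
    if include_produced:
        _draw_strokeset(draw, drawing.produced_strokes, BLUE, stroke_width)
    return RasterImage(np.asarray(img))


def recolor_blue_to_black(
    image: RasterImage, dominance_margin: int | None = None
) -> RasterImage:
    """Turn blue ink black, leaving everything else untouched.  Idempotent.

    By default blue is detected by exact match to the renderer's blue
    constant (clean synthetic data).  For externally supplied scans a
    channel-dominance rule can be enabled: a pixel is blue when
    B > R + margin and B > G + margin.
    """
    px = image.pixels
    if dominance_margin is None:
        mask = (px[:, :, 0] == 0) & (px[:, :, 1] == 0) & (px[:, :, 2] == 255)
    else:
        b = px[:, :, 2].astype(np.int16)
        mask = (b > px[:, :, 0].astype(np.int16) + dominance_margin) & (
            b > px[:, :, 1].astype(np.int16) + dominance_margin
        )
    out = px.copy()
    out[mask] = BLACK
    return RasterImage(out)


def produced_only_image(
    drawing, canvas_size: int = CANVAS_SIZE, stroke_width: int = DEFAULT_STROKE_WIDTH
) -> RasterImage:
    """The drawing with the presented part removed: the produced layer is
    re-rendered alone and recolored black.  Empty drawings give a white image."""
    raster = rasterize(
        drawing,
        canvas_size=canvas_size,
        include_presented=False,
        include_produced=True,
        stroke_width=stroke_width,
    )
    return recolor_blue_to_black(raster)


def full_drawing_image(
    drawing, canvas_size: int = CANVAS_SIZE, stroke_width: int = DEFAULT_STROKE_WIDTH
) -> RasterImage:
    """Presented + produced layers merged and recolored black: the variant used
    when two drawings on the same stimulus are compared."""
    raster = rasterize(drawing, canvas_size=canvas_size, stroke_width=stroke_width)
    return recolor_blue_to_black(raster)


def preprocess_for_backbone(image: RasterImage, backbone_spec) -> BackboneInput:
    """Bilinear resize to the backbone's input size and per-channel mean
    subtraction (channel order per the backbone spec)."""
    h, w = image.canvas_size
    if h == 0 or w == 0:
        raise ValueError("degenerate image")
    th, tw = backbone_spec.input_size[:2]
    pil = Image.fromarray(image.pixels)
    if (h, w) != (th, tw):
        pil = pil.resize((tw, th), Image.BILINEAR)
    arr = np.asarray(pil, dtype=np.float32)
    if getattr(backbone_spec, "channel_order", "rgb") == "bgr":
        arr = arr[:, :, ::-1]
    arr = arr - np.asarray(backbone_spec.channel_means, dtype=np.float32)
    return BackboneInput(arr, backbone_spec.backbone_id)


def save_png(image: RasterImage, path) -> None:
    Image.fromarray(image.pixels).save(path, format="PNG")


def load_png(path) -> RasterImage:
    return RasterImage(np.asarray(Image.open(path).convert("RGB")))
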