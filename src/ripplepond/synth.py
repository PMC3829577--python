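"""Procedural test imagery.

The experiments need a mixed set of centered grayscale images — letters,
digits, short words, geometric shapes, and organic blob/silhouette
stand-ins for photographic categories (smooth radial-harmonic "faces" with
interior features, and fish-like silhouettes) — generated deterministically
from a seed so every experiment is reproducible without external data.

All images are ``size x size`` (default 200), values in [0, 1], and the
foreground centroid is shifted onto the image center after rendering; the
foreground is kept between 10% and 80% of the inscribed disc's area by a
deterministic corrective loop on stroke width / object scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
from PIL import Image as PILImage
from PIL import ImageDraw
from scipy import ndimage

from ._stroke_font import GLYPH_HEIGHT, GLYPH_STROKES, GLYPH_WIDTH
from .errors import (
    DegenerateImageWarning,
    InvalidParameterError,
    UnknownGlyphError,
)

__all__ = [
    "ImageRecipe",
    "KINDS",
    "render",
    "transform_image",
    "make_test_set",
]

KINDS = ("letter", "digit", "word", "shape", "blob", "silhouette")


@dataclass(frozen=True)
class ImageRecipe:
    """Deterministic description of one test image."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)
    size: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise InvalidParameterError(f"unknown kind {self.kind!r}")
        if self.size < 16:
            raise InvalidParameterError("size must be >= 16")


def _draw_glyph(
    draw: ImageDraw.ImageDraw,
    glyph: str,
    origin: tuple[float, float],
    height: float,
    width_px: float,
    img_h: int,
) -> float:
    """Draw one glyph with its bottom-left at ``origin`` (y up); returns
    the advance width in pixels."""
    if glyph not in GLYPH_STROKES:
        raise UnknownGlyphError(glyph)
    s = height / GLYPH_HEIGHT
    ox, oy = origin
    for poly in GLYPH_STROKES[glyph]:
        pts = [(ox + x * s, img_h - 1 - (oy + y * s)) for x, y in poly]
        draw.line(pts, fill=255, width=max(1, int(round(width_px))),
                  joint="curve")
        for px, py in pts:  # round caps
            rr = width_px / 2.0
            draw.ellipse([px - rr, py - rr, px + rr, py + rr], fill=255)
    return GLYPH_WIDTH * s


def _render_text(text: str, size: int, height: float, stroke: float,
                 gap: float) -> np.ndarray:
    # Draw on a double-size canvas so wide strokes and round caps never
    # clip at the border, center the ink there, then crop the middle.
    big = 2 * size
    img = PILImage.new("L", (big, big), 0)
    draw = ImageDraw.Draw(img)
    n = len(text)
    adv = GLYPH_WIDTH * height / GLYPH_HEIGHT
    total_w = n * adv + (n - 1) * gap
    x = (big - total_w) / 2.0
    y = (big - height) / 2.0
    for ch in text:
        _draw_glyph(draw, ch, (x, y), height, stroke, big)
        x += adv + gap
    arr = _center_foreground(np.asarray(img, dtype=float) / 255.0)
    half = size // 2
    return arr[half : half + size, half : half + size]


def _render_shape(rng: np.random.Generator, size: int,
                  params: dict[str, Any]) -> np.ndarray:
    img = PILImage.new("L", (size, size), 0)
    draw = ImageDraw.Draw(img)
    c = (size - 1) / 2.0
    shape = params.get("shape", rng.choice(
        ["circle", "polygon", "star", "rectangle"]))
    radius = params.get("radius", rng.uniform(0.35, 0.7) * size / 2.0)
    filled = params.get("filled", bool(rng.random() < 0.7))
    outline_w = max(3, int(radius * 0.18))
    if shape == "circle":
        box = [c - radius, c - radius, c + radius, c + radius]
        if filled:
            draw.ellipse(box, fill=255)
        else:
            draw.ellipse(box, outline=255, width=outline_w)
    elif shape == "rectangle":
        a = radius * rng.uniform(0.6, 1.0)
        b = radius
        box = [c - b, c - a, c + b, c + a]
        if filled:
            draw.rectangle(box, fill=255)
        else:
            draw.rectangle(box, outline=255, width=outline_w)
    else:
        k = int(params.get("vertices", rng.integers(3, 9)))
        rot = rng.uniform(0, 2 * np.pi)
        if shape == "star":
            angles = rot + np.arange(2 * k) * np.pi / k
            radii = np.where(np.arange(2 * k) % 2 == 0, radius, radius * 0.45)
        else:
            angles = rot + np.arange(k) * 2 * np.pi / k
            radii = np.full(k, radius)
        pts = [(c + r_ * np.cos(a), c - r_ * np.sin(a))
               for r_, a in zip(radii, angles)]
        if filled:
            draw.polygon(pts, fill=255)
        else:
            draw.polygon(pts, outline=255, width=outline_w)
    return np.asarray(img, dtype=float) / 255.0


def _render_blob(rng: np.random.Generator, size: int,
                 params: dict[str, Any]) -> np.ndarray:
    """Smooth radial-harmonic closed contour with interior features — a
    parametric stand-in for a face-like image."""
    img = PILImage.new("L", (size, size), 0)
    draw = ImageDraw.Draw(img)
    c = (size - 1) / 2.0
    r0 = params.get("r0", rng.uniform(0.45, 0.7) * size / 2.0)
    n_harm = int(params.get("harmonics", 4))
    amps = params.get("amps", rng.uniform(0.0, 0.12, size=n_harm))
    phases = params.get("phases", rng.uniform(0, 2 * np.pi, size=n_harm))
    th = np.linspace(0, 2 * np.pi, 120, endpoint=False)
    r = r0 * (1.0 + sum(a * np.cos((k + 2) * th + p)
                        for k, (a, p) in enumerate(zip(amps, phases))))
    pts = [(c + ri * np.cos(t), c - ri * np.sin(t)) for ri, t in zip(r, th)]
    draw.polygon(pts, fill=255)
    # interior features: two "eyes" and a "mouth" carved out
    er = r0 * 0.12
    for sx in (-1, 1):
        ex, ey = c + sx * r0 * 0.33, c - r0 * 0.25
        draw.ellipse([ex - er, ey - er, ex + er, ey + er], fill=0)
    mw, mh = r0 * 0.5, r0 * 0.22
    my = c + r0 * 0.3
    draw.arc([c - mw, my - mh, c + mw, my + mh], start=20, end=160,
             fill=0, width=max(2, int(r0 * 0.08)))
    return np.asarray(img, dtype=float) / 255.0


def _render_silhouette(rng: np.random.Generator, size: int,
                       params: dict[str, Any]) -> np.ndarray:
    """Fish-like silhouette: ellipse body, triangle tail, eye hole."""
    img = PILImage.new("L", (size, size), 0)
    draw = ImageDraw.Draw(img)
    c = (size - 1) / 2.0
    L = params.get("length", rng.uniform(0.55, 0.85) * size / 2.0)
    body_h = L * params.get("aspect", rng.uniform(0.4, 0.6))
    draw.ellipse([c - L * 0.7, c - body_h, c + L * 0.7, c + body_h], fill=255)
    tail = [(c - L * 0.6, c), (c - L * 1.1, c - body_h * 0.9),
            (c - L * 1.1, c + body_h * 0.9)]
    draw.polygon(tail, fill=255)
    er = body_h * 0.18
    ex, ey = c + L * 0.4, c - body_h * 0.3
    draw.ellipse([ex - er, ey - er, ex + er, ey + er], fill=0)
    # dorsal fin
    draw.polygon([(c - L * 0.1, c - body_h * 0.9),
                  (c + L * 0.15, c - body_h * 1.35),
                  (c + L * 0.3, c - body_h * 0.85)], fill=255)
    return np.asarray(img, dtype=float) / 255.0


def _center_foreground(img: np.ndarray) -> np.ndarray:
    """Shift (zero-fill) so the intensity centroid lands on the center."""
    total = img.sum()
    if total <= 0:
        return img
    cy, cx = ndimage.center_of_mass(img)
    size = img.shape[0]
    tgt = (size - 1) / 2.0
    dy, dx = int(round(tgt - cy)), int(round(tgt - cx))
    out = np.zeros_like(img)
    src = img[
        max(0, -dy): img.shape[0] - max(0, dy),
        max(0, -dx): img.shape[1] - max(0, dx),
    ]
    out[max(0, dy): max(0, dy) + src.shape[0],
        max(0, dx): max(0, dx) + src.shape[1]] = src
    return out


def _disc_coverage(img: np.ndarray) -> float:
    size = img.shape[0]
    disc_area = np.pi * (size / 2.0) ** 2
    return float((img > 0.5).sum()) / disc_area


_LETTERS = sorted(k for k in GLYPH_STROKES if k.isalpha())
_DIGITS = sorted(k for k in GLYPH_STROKES if k.isdigit())


def render(recipe: ImageRecipe) -> np.ndarray:
    """Render a recipe to a centered [0, 1] grayscale array.

    Deterministic given the recipe's seed.  The result is re-centered on
    its foreground centroid and its foreground area is nudged into the
    10–80% band of the inscribed disc by adjusting stroke width (glyphs)
    or scale (solids) before the final centering.
    """
    rng = np.random.default_rng(recipe.seed)
    size = recipe.size
    kind = recipe.kind
    p = dict(recipe.params)

    if kind in ("letter", "digit", "word"):
        if kind == "letter":
            text = p.get("text", rng.choice(_LETTERS))
        elif kind == "digit":
            text = p.get("text", rng.choice(_DIGITS))
        else:
            n = int(p.get("n_glyphs", rng.integers(2, 5)))
            text = p.get("text", "".join(rng.choice(_LETTERS, size=n)))
        for ch in text:
            if ch not in GLYPH_STROKES:
                raise UnknownGlyphError(ch)
        height = p.get("height", rng.uniform(0.45, 0.8) * size)
        stroke_frac = rng.uniform(0.10, 0.18)
        # total width = n*adv + (n-1)*gap with gap = adv/4, plus stroke slack
        n_g = len(text)
        width_factor = (GLYPH_WIDTH / GLYPH_HEIGHT) * (1.25 * n_g - 0.25)
        need = height * (width_factor + stroke_frac)
        max_w = 0.88 * size
        if need > max_w:
            height *= max_w / need
        stroke = p.get("stroke", max(3.0, height * stroke_frac))

        def _layout(h: float, w: float) -> np.ndarray:
            adv = GLYPH_WIDTH * h / GLYPH_HEIGHT
            return _render_text(text, size, h, w, adv * 0.25)

        img = _layout(height, stroke)
        # widen strokes until coverage clears the floor (deterministic)
        for _ in range(12):
            if _disc_coverage(img) >= 0.10:
                break
            stroke *= 1.4
            img = _layout(height, stroke)
    elif kind == "shape":
        img = _render_shape(rng, size, p)
        for _ in range(12):
            if _disc_coverage(img) >= 0.10:
                break
            p["radius"] = p.get("radius", 0.5 * size / 2.0) * 1.3
            img = _render_shape(np.random.default_rng(recipe.seed), size, p)
    elif kind == "blob":
        img = _render_blob(rng, size, p)
    else:
        img = _render_silhouette(rng, size, p)

    # shrink anything overgrown back under the ceiling
    for _ in range(8):
        if _disc_coverage(img) <= 0.80:
            break
        img = transform_image(img, scale=0.85, method="nearest")

    return _center_foreground(img)


def transform_image(
    image: np.ndarray,
    rotation: float = 0.0,
    scale: float = 1.0,
    shift: tuple[int, int] = (0, 0),
    method: str = "nearest",
) -> np.ndarray:
    """Rotate, then scale, then shift an image about its center.

    ``rotation`` is counterclockwise in radians (+y up); ``shift`` is
    (dx, dy) in pixels with +x right, +y up; output is cropped/zero-padded
    back to the input size.  ``method`` is ``nearest`` (default, matching
    the resizing family used in the characterization experiments) or
    ``bilinear``.  A transform that erases the whole foreground raises a
    ``DegenerateImageWarning`` (not an exception).
    """
    if scale <= 0:
        raise InvalidParameterError("scale must be positive")
    if method not in ("nearest", "bilinear"):
        raise InvalidParameterError(f"unknown method {method!r}")
    img = np.asarray(image, dtype=float)
    if rotation == 0.0 and scale == 1.0 and shift == (0, 0):
        return img.copy()

    h, w = img.shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    # forward map: p' = S R (p - c) + c + t  (array coords, row = -y)
    ct, st = np.cos(rotation), np.sin(rotation)
    # CCW rotation (+y up) expressed on (row, col) deltas, where row ~ -y
    fwd = scale * np.array([[ct, -st], [st, ct]])
    inv = np.linalg.inv(fwd)
    t = np.array([-shift[1], shift[0]], dtype=float)  # (drow, dcol)
    center = np.array([cy, cx])
    offset = center - inv @ (center + t)
    order = 0 if method == "nearest" else 1
    out = ndimage.affine_transform(
        img, inv, offset=offset, order=order, mode="constant", cval=0.0
    )
    had_fg = (img > 0.5).any()
    if had_fg and not (out > 0.5).any():
        warnings.warn(
            "transform erased the foreground", DegenerateImageWarning,
            stacklevel=2,
        )
    return out


def make_test_set(
    n: int,
    mix: dict[str, float] | None = None,
    seed: int = 0,
    size: int = 200,
) -> list[tuple[ImageRecipe, np.ndarray]]:
    """Generate ``n`` centered test images with kinds in given proportions.

    ``mix`` maps kind -> proportion (default: equal over all six kinds).
    Counts follow the largest-remainder rule so they sum to ``n`` exactly;
    everything is deterministic given ``seed``.
    """
    if mix is None:
        mix = {k: 1.0 / len(KINDS) for k in KINDS}
    props = np.array([mix.get(k, 0.0) for k in KINDS], dtype=float)
    if not np.isclose(props.sum(), 1.0):
        raise InvalidParameterError("mix proportions must sum to 1")
    raw = props * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:rem]] += 1

    rng = np.random.default_rng(seed)
    out: list[tuple[ImageRecipe, np.ndarray]] = []
    for kind, cnt in zip(KINDS, counts):
        for _ in range(cnt):
            recipe = ImageRecipe(
                kind=kind, size=size, seed=int(rng.integers(0, 2**31 - 1))
            )
            out.append((recipe, render(recipe)))
    return out
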