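"""Format plumbing: grayscale images and temporal-pattern CSV round trips."""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image as PILImage

from .core import TemporalPattern
from .errors import ParseError

__all__ = ["read_image", "write_image", "write_tp", "read_tp"]


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/PGM image as a [0, 1] grayscale float array.

    8-bit values are divided by 255, 16-bit by 65535; color images are
    converted to luminance first.
    """
    path = Path(path)
    try:
        img = PILImage.open(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if img.mode == "I;16" or img.mode == "I":
        arr = np.asarray(img, dtype=float)
        return arr / 65535.0
    if img.mode != "L":
        img = img.convert("L")
    return np.asarray(img, dtype=float) / 255.0


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float array as an 8-bit grayscale PNG/PGM."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    PILImage.fromarray((arr * 255).round().astype(np.uint8), "L").save(path)


def write_tp(tp: TemporalPattern, path: str | Path, **meta) -> None:
    """Write a pattern as CSV (step, value) with a JSON sidecar.

    The sidecar (same stem, ``.json``) carries m, dt, t0 and any extra
    metadata (e.g. arms, per_arm, shutter mode).
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["step", "value"])
        for t, v in enumerate(tp.values, start=1):
            w.writerow([t, int(v)])
    side = {"m": tp.m, "dt": tp.dt, "t0": tp.t0, **meta}
    path.with_suffix(".json").write_text(json.dumps(side, indent=1))


def read_tp(path: str | Path) -> TemporalPattern:
    """Read a pattern back from its CSV + JSON sidecar (lossless)."""
    path = Path(path)
    side_path = path.with_suffix(".json")
    if not side_path.exists():
        raise ParseError(f"missing JSON sidecar {side_path}")
    side = json.loads(side_path.read_text())
    values = []
    with open(path) as fh:
        reader = csv.reader(fh)
        head = next(reader, None)
        if head != ["step", "value"]:
            raise ParseError(f"{path}: expected header step,value, got {head}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 2:
                raise ParseError(f"{path}: line {lineno}: expected 2 fields")
            try:
                step, val = int(row[0]), int(row[1])
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            if step != len(values) + 1:
                raise ParseError(
                    f"{path}: line {lineno}: step {step} out of order"
                )
            values.append(val)
    if not values:
        raise ParseError(f"{path}: no pattern rows")
    tp = TemporalPattern(
        values=np.asarray(values, dtype=int),
        dt=float(side.get("dt", 1.0)),
        m=int(side["m"]),
        t0=int(side.get("t0", 0)),
    )
    if int(tp.values.sum()) != tp.m:
        raise ParseError(
            f"{path}: sum of values {int(tp.values.sum())} != sidecar m {tp.m}"
            " (truncated file?)"
        )
    return tp
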