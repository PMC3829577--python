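"""Temporal-pattern normalization and invariance characterization.

A downstream time-warp-invariant memory sees a rescaled object as the
same pattern played faster/slower and larger/smaller; here that is
emulated by resampling a pattern's support to a fixed length and dividing
by its size cue ``m``.  The module also provides the two similarity
metrics used to characterize the transform (cosine similarity and
Spearman rank correlation) and the sweep driver that measures mean
similarity between each image's pattern and the pattern of its rotated /
rescaled / translated version over a grid of transform magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .core import TemporalPattern, project_frame, ripple
from .disc import DiscLayout, rotate_layout
from .errors import (
    EmptyPatternError,
    InvalidParameterError,
    NoPeriodError,
    UndefinedSimilarityError,
)
from .features import dog_highpass
from .synth import transform_image

__all__ = [
    "NormalizedTP",
    "SimilarityTable",
    "normalize_tp",
    "cosine_similarity",
    "spearman_rho",
    "transform_to_tp",
    "invariance_sweep",
    "estimate_period",
    "SWEEP_THRESHOLD",
]

# Activation threshold applied to |DoG| maps in the sweep pipeline.  Zero
# would fire neurons on float roundoff (~1e-16) inside constant regions;
# 1e-3 sits far below any real edge response on [0,1] images.
SWEEP_THRESHOLD = 1e-3


@dataclass(frozen=True)
class NormalizedTP:
    """A pattern resampled to fixed length and scaled by its size cue."""

    values: np.ndarray  # float, (target_len,)
    m: int


@dataclass(frozen=True)
class SimilarityTable:
    """Per-grid-point mean similarity between original and transformed TPs."""

    transform: str  # rotation | scale | translation
    grid: np.ndarray
    mean_cos: np.ndarray
    mean_rho: np.ndarray
    n_used: np.ndarray = field(default=None)  # images contributing per point
    n_images: int = 0
    seed: int = 0


def normalize_tp(tp: TemporalPattern, target_len: int = 200) -> NormalizedTP:
    """Resample a pattern's support to ``target_len`` and divide by ``m``.

    The support (first through last nonzero step) is linearly resampled,
    which aligns patterns from differently sized objects; dividing by the
    size cue ``m`` normalizes magnitude the way the inhibitory neuron's
    initial level would let a time-warp memory do.
    """
    if target_len < 1:
        raise InvalidParameterError("target_len must be >= 1")
    vals = np.asarray(tp.values, dtype=float)
    nz = np.flatnonzero(vals)
    if nz.size == 0:
        raise EmptyPatternError("cannot normalize an all-zero pattern")
    lo, hi = nz[0], nz[-1]
    support = vals[lo : hi + 1]
    x_src = np.arange(support.size, dtype=float)
    x_tgt = np.linspace(0.0, support.size - 1.0, target_len)
    resampled = np.interp(x_tgt, x_src, support)
    return NormalizedTP(values=resampled / tp.m, m=tp.m)


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidParameterError("sequences must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedSimilarityError("cosine undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def spearman_rho(u: np.ndarray, v: np.ndarray) -> float:
    """Spearman rank correlation (mean ranks for ties)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.size < 2:
        raise InvalidParameterError("sequences must have equal length >= 2")
    if np.all(u == u[0]) or np.all(v == v[0]):
        raise UndefinedSimilarityError("Spearman undefined for constant input")
    rho = stats.spearmanr(u, v).statistic
    return float(rho)


def transform_to_tp(
    image: np.ndarray,
    layout: DiscLayout,
    threshold: float = SWEEP_THRESHOLD,
    dog_sigmas: tuple[float, float] = (1.0, 2.0),
) -> TemporalPattern:
    """The characterization pipeline for one image: |DoG| -> disc -> TP."""
    fmap = np.abs(dog_highpass(image, *dog_sigmas))
    return ripple(project_frame(fmap, layout, threshold))


def _apply(transform: str, image: np.ndarray, magnitude: float) -> np.ndarray:
    if transform == "rotation":
        return transform_image(image, rotation=magnitude)
    if transform == "scale":
        return transform_image(image, scale=magnitude)
    if transform == "translation":
        return transform_image(image, shift=(int(round(magnitude)), 0))
    raise InvalidParameterError(f"unknown transform {transform!r}")


def _rotated_tp(
    fmap: np.ndarray, layout: DiscLayout, angle: float, threshold: float
) -> TemporalPattern:
    """Pattern of the scene rotated by ``angle``: sample the fixed feature
    map with the disc rotated by ``-angle`` (one resampling, not two)."""
    lay = rotate_layout(layout, -angle) if angle != 0.0 else layout
    return ripple(project_frame(fmap, lay, threshold))


def invariance_sweep(
    images: list[np.ndarray],
    layout: DiscLayout,
    transform: str,
    grid: np.ndarray,
    target_len: int = 200,
    seed: int = 0,
    threshold: float = SWEEP_THRESHOLD,
    dog_sigmas: tuple[float, float] = (1.0, 2.0),
    rotation_mode: str = "sampling",
) -> SimilarityTable:
    """Mean similarity between each image's TP and its transformed TP.

    For every image and grid magnitude: transform, DoG-filter and rectify
    both versions, project onto ``layout``, ripple, normalize both
    patterns to ``target_len`` and record cosine similarity and Spearman
    rho; the table holds per-grid-point means over images.  Images whose
    transformed pattern is empty (or constant, leaving rank correlation
    undefined) at a grid point are excluded from that point's mean
    (``n_used`` reports the count).  The sweep is fully deterministic;
    ``seed`` is recorded for provenance.

    Rotation is applied, by default, at the sampling stage: the fixed
    feature map is sampled with the disc rotated by ``-angle``, modeling a
    scene that rotates continuously in front of the sensor.  (Rotating the
    raster first and sampling the rotated raster — ``rotation_mode=
    "raster"`` — stacks two nearest-neighbor resamplings, and the aliasing
    of the first buries the disc's arm periodicity.)  Translation and
    scaling always act on the raster: integer-pixel shifts are exact, and
    nearest-neighbor rescaling is itself the degradation being studied.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InvalidParameterError("grid must be nonempty")
    if rotation_mode not in ("sampling", "raster"):
        raise InvalidParameterError(f"unknown rotation_mode {rotation_mode!r}")

    fmaps = [np.abs(dog_highpass(img, *dog_sigmas)) for img in images]
    base: list[NormalizedTP | None] = []
    for fmap in fmaps:
        tp = ripple(project_frame(fmap, layout, threshold))
        base.append(normalize_tp(tp, target_len) if tp.m > 0 else None)

    sampling_rotation = transform == "rotation" and rotation_mode == "sampling"
    mean_cos = np.empty(grid.size)
    mean_rho = np.empty(grid.size)
    n_used = np.zeros(grid.size, dtype=int)
    for gi, mag in enumerate(grid):
        cos_acc: list[float] = []
        rho_acc: list[float] = []
        for img, fmap, b in zip(images, fmaps, base):
            if b is None:
                continue
            if sampling_rotation:
                tp = _rotated_tp(fmap, layout, mag, threshold)
            else:
                timg = _apply(transform, img, mag)
                tp = transform_to_tp(timg, layout, threshold, dog_sigmas)
            if tp.m == 0:
                continue
            nt = normalize_tp(tp, target_len)
            try:
                rho = spearman_rho(b.values, nt.values)
            except UndefinedSimilarityError:
                continue
            cos_acc.append(cosine_similarity(b.values, nt.values))
            rho_acc.append(rho)
        n_used[gi] = len(cos_acc)
        mean_cos[gi] = np.mean(cos_acc) if cos_acc else np.nan
        mean_rho[gi] = np.mean(rho_acc) if rho_acc else np.nan
    return SimilarityTable(
        transform=transform,
        grid=grid,
        mean_cos=mean_cos,
        mean_rho=mean_rho,
        n_used=n_used,
        n_images=len(images),
        seed=seed,
    )


def estimate_period(table: SimilarityTable) -> float:
    """Dominant period of the mean-cosine-vs-rotation curve (radians).

    The period is the lag of the strongest positive-lag peak of the
    centered curve's autocorrelation (uniform grid; must cover at least
    two periods).  The strongest peak — rather than, say, the mean peak
    spacing — is used because the within-period curve shape is often
    symmetric about the half-period, which plants genuine secondary
    autocorrelation peaks at half-period lags; the full-period lag always
    correlates best.  A peak-free (flat) curve raises ``NoPeriodError``.
    """
    if table.transform != "rotation":
        raise InvalidParameterError("period estimation requires a rotation sweep")
    steps = np.diff(table.grid)
    if table.grid.size < 4 or not np.allclose(steps, steps[0]):
        raise InvalidParameterError("grid must be uniform with >= 4 points")
    x = table.mean_cos - table.mean_cos.mean()
    ac = np.correlate(x, x, mode="full")[x.size - 1 :]
    peaks, _ = signal.find_peaks(ac, prominence=0.05 * ac[0])
    if peaks.size == 0:
        raise NoPeriodError("autocorrelation has no interior peaks")
    best = peaks[np.argmax(ac[peaks])]
    return float(best * steps[0])
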