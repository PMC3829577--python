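"""Ripple propagation: image frame -> temporal pattern.

Neurons are binary relays with unit delays, connected inward along their
arm.  Activation placed on ring ``n`` reaches the summing neuron at the
disc center after ``n + 1`` unit steps (the central neuron's own sample
exits at step 1), so a projected frame "ripples" inward and drains through
the center, emitting an integer-valued temporal pattern TP(t) of length
``per_arm``.  Because every arm is ``2*pi/arms`` from its neighbors, the
TP is exactly invariant to rotating the frame by whole arms.

The inhibitory neuron carries the total activity remaining on the disc;
its trace starts at the frame's initial count ``m`` and falls to zero as
the frame drains, which is what lets it act as an asynchronous shutter:
a new frame can be admitted the moment the trace hits zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .disc import DiscLayout
from .errors import InvalidInputError

__all__ = [
    "Frame",
    "TemporalPattern",
    "InhibitoryTrace",
    "project_frame",
    "ripple",
    "inhibitory_trace",
    "stream_run",
]


@dataclass(frozen=True)
class Frame:
    """Binary activation snapshot on the disc at projection time.

    ``ring_active[n - 1, phi]`` is the activation of ring ``n`` (1-based),
    arm ``phi``; ``center_active`` the shared central neuron.  ``m`` is the
    total count — the value the inhibitory neuron reads out at projection
    and the size cue attached to the emitted pattern.
    """

    ring_active: np.ndarray = field(repr=False)  # bool (per_arm-1, arms)
    center_active: bool
    t0: int = 0

    def __post_init__(self) -> None:
        if self.ring_active.ndim != 2:
            raise InvalidInputError("ring_active must be 2-D (rings x arms)")

    @property
    def m(self) -> int:
        return int(self.ring_active.sum()) + int(self.center_active)

    @property
    def per_arm(self) -> int:
        return self.ring_active.shape[0] + 1

    @property
    def arms(self) -> int:
        return self.ring_active.shape[1]


@dataclass(frozen=True)
class TemporalPattern:
    """Integer spike-count series emitted by the summing neuron.

    ``values[t - 1]`` is TP(t) for unit steps t = 1..per_arm; trailing
    zeros are kept so the length always equals the disc's per-arm count.
    ``m`` (= sum of values) is carried along as the normalization cue.
    """

    values: np.ndarray  # int, (per_arm,)
    dt: float = 1.0
    m: int = 0
    t0: int = 0

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class InhibitoryTrace:
    """Remaining disc activity Inh(t), t = 0..per_arm; Inh(0) = m."""

    values: np.ndarray  # int, (per_arm + 1,)

    @property
    def m(self) -> int:
        return int(self.values[0])


def project_frame(
    feature_map: np.ndarray,
    layout: DiscLayout,
    threshold: float = 0.0,
    *,
    bilinear: bool = False,
) -> Frame:
    """Project a square feature map onto the disc.

    The unit disc is inscribed in the map (radius = half the side, center
    = image center); each neuron samples the nearest pixel (or a bilinear
    interpolation with ``bilinear=True``) at its Cartesian position, with
    +y pointing up, and activates iff the sample exceeds ``threshold``.
    """
    fmap = np.asarray(feature_map, dtype=float)
    if fmap.ndim != 2 or fmap.shape[0] != fmap.shape[1]:
        raise InvalidInputError(f"feature map must be square, got {fmap.shape}")
    samples = _sample_disc(fmap, layout, bilinear=bilinear)
    active = samples > threshold
    arms, per_arm = layout.spec.arms, layout.spec.per_arm
    ring_active = active[1:].reshape(per_arm - 1, arms)
    return Frame(ring_active=ring_active, center_active=bool(active[0]))


def _sample_disc(
    fmap: np.ndarray, layout: DiscLayout, *, bilinear: bool = False
) -> np.ndarray:
    side = fmap.shape[0]
    c = (side - 1) / 2.0
    radius = side / 2.0
    cols = c + layout.positions[:, 0] * radius
    rows = c - layout.positions[:, 1] * radius  # +y up
    if bilinear:
        from scipy.ndimage import map_coordinates

        return map_coordinates(fmap, [rows, cols], order=1, mode="nearest")
    ri = np.clip(np.rint(rows).astype(int), 0, side - 1)
    ci = np.clip(np.rint(cols).astype(int), 0, side - 1)
    return fmap[ri, ci]


def ripple(frame: Frame) -> TemporalPattern:
    """Collapse a frame inward and return the summed temporal pattern.

    The unit-delay shift register means ring ``n``'s initial activation
    exits at step ``n + 1`` and the center's at step 1, so
    ``TP(1) = center`` and ``TP(t) = sum over arms of ring t-1`` for
    t >= 2.  Every initial activation exits exactly once: sum(TP) = m.
    """
    per_arm = frame.per_arm
    values = np.zeros(per_arm, dtype=int)
    values[0] = int(frame.center_active)
    values[1:] = frame.ring_active.sum(axis=1)
    return TemporalPattern(values=values, m=frame.m, t0=frame.t0)


def inhibitory_trace(frame: Frame) -> InhibitoryTrace:
    """Inh(t) = activity still on the disc after step t (Inh(0) = m)."""
    tp = ripple(frame)
    remaining = frame.m - np.cumsum(tp.values)
    return InhibitoryTrace(values=np.concatenate([[frame.m], remaining]))


def _clear_time(frame: Frame) -> int:
    """Steps until the disc is empty again after admitting ``frame``.

    Equals (outermost active ring) + 1; 1 for a center-only frame; an
    empty frame still occupies the disc for one step (the admission step).
    """
    active_rings = np.flatnonzero(frame.ring_active.any(axis=1))
    if active_rings.size:
        return int(active_rings[-1]) + 2  # row i is ring i+1; exits at n+1
    return 1


def stream_run(
    frames: list[tuple[np.ndarray, int]],
    layout: DiscLayout,
    threshold: float = 0.0,
    mode: str = "periodic",
) -> list[TemporalPattern]:
    """Run a stream of feature maps through the disc under a shutter mode.

    ``frames`` is a list of (feature map, arrival step) with non-decreasing
    arrival steps.  ``periodic`` admits a frame every ``per_arm`` steps
    (the worst-case drain time) regardless of content; ``gated`` admits the
    next frame the moment the inhibitory trace hits zero, so small objects
    are turned around faster.  While the disc is busy the latest pending
    frame wins and earlier unserved frames are dropped, modeling a sensor
    that keeps refreshing.  Each admitted frame yields one TemporalPattern
    tagged with its admission step.
    """
    if mode not in ("periodic", "gated"):
        raise InvalidInputError(f"mode must be 'periodic' or 'gated', got {mode!r}")
    if not frames:
        return []
    arrivals = [t for _, t in frames]
    if any(b < a for a, b in zip(arrivals, arrivals[1:])):
        raise InvalidInputError("arrival steps must be non-decreasing")

    per_arm = layout.spec.per_arm
    out: list[TemporalPattern] = []
    i = 0  # next unconsidered frame
    t = arrivals[0]
    while i < len(frames):
        # Latest frame that has arrived by t wins; earlier ones are dropped.
        j = i
        while j + 1 < len(frames) and arrivals[j + 1] <= t:
            j += 1
        fmap, _ = frames[j]
        frame = project_frame(fmap, layout, threshold)
        frame = Frame(
            ring_active=frame.ring_active,
            center_active=frame.center_active,
            t0=t,
        )
        tp = ripple(frame)
        out.append(tp)
        i = j + 1
        busy = per_arm if mode == "periodic" else _clear_time(frame)
        if i < len(frames):
            t = max(t + busy, arrivals[i])
    return out
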