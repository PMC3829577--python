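"""Multi-channel fan-out: feature channels x disc densities.

One image is split by a bank of radial Gabor orientations (or the DoG
channel), and each feature map is projected onto several discs of
decreasing per-arm neuron count.  Sparser discs drain sooner, so they
deliver an early, low-resolution version of the full pattern — useful for
normalization or coarse categorization before the dense channel finishes.
The result is an M-dimensional spatio-temporal pattern, one temporal
pattern per (feature, density) channel, with no cross-channel state.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import floor

import numpy as np

from .core import TemporalPattern, project_frame, ripple
from .disc import DiscLayout, DiscSpec, build_disc
from .errors import InvalidParameterError
from .features import GaborParams, dog_highpass, radial_gabor

__all__ = ["ChannelSpec", "SpatioTemporalPattern", "build_channels", "run_multidisc"]


@dataclass(frozen=True)
class ChannelSpec:
    """One (feature, disc density) processing channel.

    ``feature`` is either ``"dog"`` or ``"radial_gabor_<degrees>"``;
    ``density`` is the fraction of the full per-arm count this channel's
    disc was built at.
    """

    feature: str
    alpha: float | None  # radians; None for the DoG channel
    density: float
    disc: DiscLayout


@dataclass(frozen=True)
class SpatioTemporalPattern:
    """Ordered channel outputs of one multi-disc run."""

    channels: list[tuple[ChannelSpec, TemporalPattern]]

    def __len__(self) -> int:
        return len(self.channels)


def _round_half_up(x: float) -> int:
    return floor(x + 0.5)


def build_channels(
    full_spec: DiscSpec,
    alphas: list[float],
    densities: list[float],
) -> list[ChannelSpec]:
    """Build the |alphas| x |densities| channel grid.

    Each density disc is built by re-running the placement search at
    ``per_arm = round(density * N_full)`` (round half up) with a seed
    derived from the full spec's, so every disc independently satisfies
    the uniform-density guarantee.  Channels are ordered alpha-major.
    """
    if not alphas:
        raise InvalidParameterError("alphas must be nonempty")
    discs: dict[float, DiscLayout] = {}
    for di, d in enumerate(densities):
        d = float(Fraction(d).limit_denominator(10**6))
        if not (0 < d <= 1):
            raise InvalidParameterError(f"density must be in (0, 1], got {d}")
        per_arm = _round_half_up(d * full_spec.per_arm)
        if per_arm < 2:
            raise InvalidParameterError(
                f"density {d} yields per_arm {per_arm} < 2"
            )
        spec = DiscSpec(
            arms=full_spec.arms,
            per_arm=per_arm,
            trials=full_spec.trials,
            seed=full_spec.seed + di,
        )
        discs[d] = build_disc(spec)
    channels = []
    for a in alphas:
        for d, disc in discs.items():
            label = f"radial_gabor_{np.degrees(a):g}"
            channels.append(
                ChannelSpec(feature=label, alpha=a, density=d, disc=disc)
            )
    return channels


def run_multidisc(
    image: np.ndarray,
    channels: list[ChannelSpec],
    threshold: float = 0.0,
    gabor_params: GaborParams = GaborParams(),
    dog_sigmas: tuple[float, float] = (1.0, 2.0),
) -> SpatioTemporalPattern:
    """Run one image through every channel: feature map -> project -> ripple.

    Feature maps are rectified before projection (binary neurons respond
    to response magnitude); each channel's pattern length equals its own
    disc's per-arm count, and each obeys its own conservation law.
    """
    if not channels:
        raise InvalidParameterError("channels must be nonempty")
    fmap_cache: dict[str, np.ndarray] = {}
    out: list[tuple[ChannelSpec, TemporalPattern]] = []
    for ch in channels:
        if ch.feature not in fmap_cache:
            if ch.feature == "dog":
                fmap_cache[ch.feature] = np.abs(dog_highpass(image, *dog_sigmas))
            else:
                p = GaborParams(
                    alpha=ch.alpha,
                    wavelength=gabor_params.wavelength,
                    envelope_sigma=gabor_params.envelope_sigma,
                    aspect=gabor_params.aspect,
                    phase=gabor_params.phase,
                )
                fmap_cache[ch.feature] = np.abs(radial_gabor(image, p))
        frame = project_frame(fmap_cache[ch.feature], ch.disc, threshold)
        out.append((ch, ripple(frame)))
    return SpatioTemporalPattern(channels=out)
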