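"""Rotation-compatible feature maps.

Two front ends feed the disc.  A difference-of-Gaussians (DoG) high-pass
filter — isotropic, hence trivially rotation-compatible — strips the DC
component and emphasizes edges.  And *radial* Gabor filters: a Gabor
kernel whose orientation at each pixel is ``alpha + atan2(y, x)``, i.e.
fixed relative to the pixel's position angle about the image center rather
than to the Cartesian axes.  Rotating the input about the center then
rotates the response map with it (equivariance), which is what lets an
orientation-selective front end precede a rotation-invariant readout.
A conventional Cartesian Gabor (fixed orientation everywhere) breaks this
and is provided as the negative control.

Angles follow the mathematical convention: +y up, counterclockwise
positive.  Image arrays are row-major with row 0 at the top, so the pixel
at row r has y = center_row - r.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage

from .errors import InvalidParameterError

__all__ = [
    "GaborParams",
    "dog_highpass",
    "radial_gabor",
    "cartesian_gabor",
    "gabor_bank",
]


@dataclass(frozen=True)
class GaborParams:
    """Gabor kernel parameters (pixels / radians).

    ``alpha`` is the radial orientation offset: 0 selects features aligned
    with the local radius, pi/2 features tangent to it.
    """

    alpha: float = 0.0
    wavelength: float = 8.0
    envelope_sigma: float = 3.0
    aspect: float = 0.5
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise InvalidParameterError("wavelength must be positive")
        if self.envelope_sigma <= 0:
            raise InvalidParameterError("envelope_sigma must be positive")

    @property
    def kernel_radius(self) -> int:
        return int(np.ceil(3.0 * self.envelope_sigma))


def dog_highpass(
    image: np.ndarray, sigma_center: float = 1.0, sigma_surround: float = 2.0
) -> np.ndarray:
    """Difference-of-Gaussians high-pass filter (reflective boundaries).

    Returns ``G(sigma_center) * image - G(sigma_surround) * image``; both
    kernels are unit-mass so constant regions map to (numerically) zero.
    """
    if not (0 < sigma_center < sigma_surround):
        raise InvalidParameterError(
            "need 0 < sigma_center < sigma_surround, got "
            f"{sigma_center}, {sigma_surround}"
        )
    img = np.asarray(image, dtype=float)
    return ndimage.gaussian_filter(img, sigma_center, mode="reflect") - \
        ndimage.gaussian_filter(img, sigma_surround, mode="reflect")


def _gabor_kernel_values(
    xx: np.ndarray, yy: np.ndarray, theta: np.ndarray | float, p: GaborParams
) -> np.ndarray:
    """Evaluate the Gabor function at offsets (xx, yy), orientation theta."""
    ct, st = np.cos(theta), np.sin(theta)
    xr = xx * ct + yy * st
    yr = -xx * st + yy * ct
    env = np.exp(-(xr**2 + (p.aspect * yr) ** 2) / (2.0 * p.envelope_sigma**2))
    return env * np.cos(2.0 * np.pi * xr / p.wavelength + p.phase)


def _kernel_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax[::-1])  # +y up: first kernel row is top
    return xx, yy


def cartesian_gabor(image: np.ndarray, params: GaborParams) -> np.ndarray:
    """Conventional Gabor filtering with fixed orientation ``params.alpha``.

    Orientation is tied to the image axes, so the response map is *not*
    rotation-equivariant — the failure mode that motivates the radial form.
    """
    img = np.asarray(image, dtype=float)
    r = params.kernel_radius
    if 2 * r + 1 > min(img.shape):
        raise InvalidParameterError("Gabor kernel larger than image")
    xx, yy = _kernel_offsets(r)
    kern = _gabor_kernel_values(xx, yy, params.alpha, params)
    # correlate (not convolve): response = sum img(p+u) * K(u); 'mirror'
    # matches the edge-excluding reflect padding used by radial_gabor
    return ndimage.correlate(img, kern, mode="mirror")


def radial_gabor(
    image: np.ndarray,
    params: GaborParams,
    center: tuple[float, float] | None = None,
    *,
    chunk_rows: int = 16,
) -> np.ndarray:
    """Gabor filtering with orientation locked to the position angle.

    At pixel p (center-relative, +y up) the kernel orientation is
    ``theta(p) = alpha + atan2(y, x)``, so the whole response map rotates
    with the image about ``center`` (default: the grid center).  Computed
    exactly, pixel by pixel, with reflective boundary handling; rows are
    processed in chunks to bound memory.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    r = params.kernel_radius
    if 2 * r + 1 > min(h, w):
        raise InvalidParameterError("Gabor kernel larger than image")
    if center is None:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    else:
        cx, cy = center
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise InvalidParameterError("center outside image")

    padded = np.pad(img, r, mode="reflect")
    windows = sliding_window_view(padded, (2 * r + 1, 2 * r + 1))
    xx, yy = _kernel_offsets(r)

    cols = np.arange(w, dtype=float)
    out = np.empty_like(img)
    for row0 in range(0, h, chunk_rows):
        rows = np.arange(row0, min(row0 + chunk_rows, h))
        dy = cy - rows[:, None]  # +y up
        dx = cols[None, :] - cx
        theta = params.alpha + np.arctan2(dy, dx)
        kerns = _gabor_kernel_values(
            xx[None, None], yy[None, None], theta[:, :, None, None], params
        )
        out[rows[0] : rows[-1] + 1] = np.einsum(
            "rcij,rcij->rc", windows[rows[0] : rows[-1] + 1], kerns
        )
    return out


def gabor_bank(
    image: np.ndarray,
    alphas: list[float],
    params: GaborParams = GaborParams(),
) -> list[np.ndarray]:
    """Rectified radial-Gabor channels, one per orientation offset.

    Each channel is ``|radial_gabor(image, alpha)|`` — rectified because
    the disc's neurons are binary-activated and only response magnitude
    matters downstream.  Each channel is individually rotation-equivariant.
    """
    if not len(alphas):
        raise InvalidParameterError("alphas must be nonempty")
    maps = []
    for a in alphas:
        p = GaborParams(
            alpha=a,
            wavelength=params.wavelength,
            envelope_sigma=params.envelope_sigma,
            aspect=params.aspect,
            phase=params.phase,
        )
        maps.append(np.abs(radial_gabor(image, p)))
    return maps
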