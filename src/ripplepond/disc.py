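"""Spiral disc geometry.

The network's retina is a disc of binary relay neurons arranged on ``arms``
spiral arms with ``per_arm`` neurons per arm (the central neuron, ring
``n = 0``, is shared by all arms).  Ring ``n`` sits at radius ``sqrt(n)``
(normalized so the outermost ring has radius 1): on a disc this square-root
spacing is what keeps the areal neuron density approximately uniform, in
contrast to log-polar placements that concentrate neurons at the fovea.

The angular offset of each successive ring is chosen by a randomized
max-min-distance search: for every ring, candidate offsets are drawn
uniformly from one arm sector ``[0, 2*pi/arms)`` and the candidate whose
nearest already-placed neuron is farthest away wins.  Offsets accumulate
ring over ring, which is what bends the arms into spirals.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidParameterError, ParseError

__all__ = [
    "DiscSpec",
    "DiscLayout",
    "build_disc",
    "rotate_layout",
    "nn_distance_profile",
    "write_layout",
    "read_layout",
]


@dataclass(frozen=True)
class DiscSpec:
    """Parameters of the spiral placement search.

    Parameters
    ----------
    arms:
        Number of spiral arms (the disc's angular resolution).
    per_arm:
        Neurons per arm including the shared central neuron, so the disc
        has ``arms * (per_arm - 1) + 1`` neurons in total.
    trials:
        Candidate angular offsets scored per ring.
    seed:
        Seed for the candidate-offset RNG; the layout is a pure function
        of the spec.
    """

    arms: int
    per_arm: int
    trials: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arms < 1:
            raise InvalidParameterError(f"arms must be >= 1, got {self.arms}")
        if self.per_arm < 2:
            raise InvalidParameterError(f"per_arm must be >= 2, got {self.per_arm}")
        if self.trials < 1:
            raise InvalidParameterError(f"trials must be >= 1, got {self.trials}")

    @property
    def n_neurons(self) -> int:
        return self.arms * (self.per_arm - 1) + 1


@dataclass(frozen=True)
class DiscLayout:
    """A built disc: ring radii, per-ring spiral offsets and positions.

    ``positions`` is an ``(n_neurons, 2)`` array of unit-disc Cartesian
    coordinates; row 0 is the central neuron, then rings in order, each
    ring's ``arms`` neurons ordered by arm index.  ``ring_index`` /
    ``arm_index`` give the (n, phi) labels of each row.
    """

    spec: DiscSpec
    ring_radius: np.ndarray  # (per_arm,), ring_radius[0] == 0, [-1] == 1
    ring_offset: np.ndarray  # (per_arm - 1,), beta_n for n = 1..per_arm-1
    positions: np.ndarray = field(repr=False)  # (n_neurons, 2)
    ring_index: np.ndarray = field(repr=False)  # (n_neurons,)
    arm_index: np.ndarray = field(repr=False)  # (n_neurons,), -1 for center

    @property
    def cumulative_offset(self) -> np.ndarray:
        """Cumulative spiral angle added up to each ring (n = 1..N-1)."""
        return np.cumsum(self.ring_offset)

    def position(self, n: int, phi: int) -> np.ndarray:
        """Cartesian coordinates of neuron (ring ``n``, arm ``phi``)."""
        if n == 0:
            return self.positions[0]
        return self.positions[1 + (n - 1) * self.spec.arms + phi]


def _ring_radii(per_arm: int) -> np.ndarray:
    n = np.arange(per_arm, dtype=float)
    return np.sqrt(n) / np.sqrt(per_arm - 1)


def _ring_positions(radius: float, arms: int, angle0: float) -> np.ndarray:
    phi = np.arange(arms)
    ang = angle0 + 2.0 * np.pi * phi / arms
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang)])


def build_disc(spec: DiscSpec) -> DiscLayout:
    """Place neurons on the disc with the randomized max-min-distance search.

    For each ring ``n`` (in order, outward), ``spec.trials`` candidate
    offsets are drawn uniformly from ``[0, 2*pi/arms)``; each candidate is
    scored by the minimum Euclidean distance from any of its ring's neurons
    to any already-placed neuron, and the highest-scoring candidate (first
    encountered on ties) becomes the ring's offset ``beta_n``.  Offsets are
    cumulative: arm ``phi`` at ring ``n`` lies at angle
    ``2*pi*phi/arms + sum(beta_1..beta_n)``.

    Two exact shortcuts keep the search fast at full size.  The candidate
    ring and the placed set are both invariant under rotation by
    ``2*pi/arms``, so the min distance over all candidate neurons equals
    the min distance from a single candidate neuron.  And any placed neuron
    radially farther from the candidate ring than an upper bound on the
    achievable min distance (the worst-case gap to the previous ring) can
    never be the minimizer, so inner rings are pruned.  Both leave the
    selected offsets bit-identical to the naive all-pairs search.
    """
    rng = np.random.default_rng(spec.seed)
    arms, per_arm = spec.arms, spec.per_arm
    radii = _ring_radii(per_arm)
    sector = 2.0 * np.pi / arms

    placed = [np.zeros((1, 2))]  # center
    placed_r = [np.zeros(1)]
    betas = np.empty(per_arm - 1)
    cum = 0.0

    for n in range(1, per_arm):
        r_n = radii[n]
        deltas = rng.uniform(0.0, sector, size=spec.trials)

        pts = np.concatenate(placed)
        rad = np.concatenate(placed_r)
        # Upper bound on any candidate's min distance: the worst-case gap
        # to the nearest previous-ring neuron (angular offset <= pi/arms).
        r_p = radii[n - 1]
        ub = (
            np.sqrt(r_n**2 + r_p**2 - 2 * r_n * r_p * np.cos(np.pi / arms))
            if n > 1
            else r_n
        )
        keep = rad >= r_n - ub - 1e-12
        pts = pts[keep]

        ang = cum + deltas  # single candidate neuron per trial (arm 0)
        cand = np.column_stack([r_n * np.cos(ang), r_n * np.sin(ang)])
        d2 = ((cand[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        # squared scores rounded so mathematical ties (e.g. every ring-1
        # candidate is exactly r_1 from the center) are exact ties, broken
        # by the first-encountered candidate
        scores = np.round(d2.min(axis=1), 12)
        best = int(np.argmax(scores))

        betas[n - 1] = deltas[best]
        cum += deltas[best]
        ring = _ring_positions(r_n, arms, cum)
        placed.append(ring)
        placed_r.append(np.full(arms, r_n))

    positions = np.concatenate(placed)
    ring_index = np.concatenate(
        [np.zeros(1, dtype=int)]
        + [np.full(arms, n, dtype=int) for n in range(1, per_arm)]
    )
    arm_index = np.concatenate(
        [np.full(1, -1, dtype=int)]
        + [np.arange(arms, dtype=int) for _ in range(1, per_arm)]
    )
    return DiscLayout(
        spec=spec,
        ring_radius=radii,
        ring_offset=betas,
        positions=positions,
        ring_index=ring_index,
        arm_index=arm_index,
    )


def rotate_layout(layout: DiscLayout, angle: float) -> DiscLayout:
    """Rotate every neuron position by ``angle`` (CCW, radians).

    Ring and arm labels are unchanged, so per-ring statistics (and hence
    the emitted temporal pattern) are those of the rotated disc.  Rotating
    by an exact multiple of ``2*pi/arms`` maps each ring's position set
    onto itself.  Used to model continuous rotation of the scene in front
    of the sensor: sampling a fixed image with a disc rotated by ``-angle``
    is exactly sampling the image rotated by ``+angle``.
    """
    import dataclasses

    c, s = np.cos(angle), np.sin(angle)
    rot = np.array([[c, -s], [s, c]])
    return dataclasses.replace(layout, positions=layout.positions @ rot.T)


def nn_distance_profile(
    layout: DiscLayout, n_bands: int
) -> list[tuple[float, float]]:
    """Mean nearest-neighbor distance per radial band.

    Bands partition (0, 1] into ``n_bands`` equal-*area* annuli (edges at
    ``sqrt(k / n_bands)``), so each band covers the same disc area and the
    per-band means are directly comparable; the central neuron belongs to
    the innermost band.  For each band the mean distance from its neurons
    to their nearest neighbor anywhere on the disc is returned as
    ``(band mid-radius, mean distance)``; empty bands report ``nan``.
    A flat profile is the signature of uniform density.
    """
    from scipy.spatial import cKDTree

    if layout.spec.per_arm < 2:
        raise InvalidParameterError("layout must have at least 2 rings")
    if n_bands < 1:
        raise InvalidParameterError("n_bands must be >= 1")

    pts = layout.positions
    tree = cKDTree(pts)
    # k=2: the first neighbor is the point itself.
    dists, _ = tree.query(pts, k=2)
    nn = dists[:, 1]
    r = np.hypot(pts[:, 0], pts[:, 1])

    edges = np.sqrt(np.linspace(0.0, 1.0, n_bands + 1))
    out: list[tuple[float, float]] = []
    for i in range(n_bands):
        lo, hi = edges[i], edges[i + 1]
        mask = (r > lo) & (r <= hi) if i > 0 else (r <= hi)
        mid = 0.5 * (lo + hi)
        out.append((mid, float(nn[mask].mean()) if mask.any() else float("nan")))
    return out


def write_layout(layout: DiscLayout, path: str | Path) -> None:
    """Write a layout as CSV (n, phi, x, y) plus a JSON sidecar.

    The sidecar (same stem, ``.json``) stores the spec and the offset
    sequence so the layout round-trips losslessly.
    """
    path = Path(path)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["n", "phi", "x", "y"])
        for (n, phi, (x, y)) in zip(
            layout.ring_index, layout.arm_index, layout.positions
        ):
            w.writerow([int(n), int(phi), repr(float(x)), repr(float(y))])
    header = {
        "arms": layout.spec.arms,
        "per_arm": layout.spec.per_arm,
        "trials": layout.spec.trials,
        "seed": layout.spec.seed,
        "ring_offset": [float(b) for b in layout.ring_offset],
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1))


def read_layout(path: str | Path) -> DiscLayout:
    """Rebuild a layout from its CSV + JSON sidecar (exact round trip)."""
    path = Path(path)
    side = path.with_suffix(".json")
    if not side.exists():
        raise ParseError(f"missing JSON sidecar {side}")
    header = json.loads(side.read_text())
    spec = DiscSpec(
        arms=header["arms"],
        per_arm=header["per_arm"],
        trials=header["trials"],
        seed=header["seed"],
    )
    betas = np.asarray(header["ring_offset"], dtype=float)
    rows = []
    with open(path) as fh:
        reader = csv.reader(fh)
        head = next(reader, None)
        if head != ["n", "phi", "x", "y"]:
            raise ParseError(f"{path}: expected header n,phi,x,y, got {head}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 fields")
            try:
                rows.append((int(row[0]), int(row[1]), float(row[2]), float(row[3])))
            except ValueError as exc:
                raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    if len(rows) != spec.n_neurons:
        raise ParseError(
            f"{path}: expected {spec.n_neurons} neurons, found {len(rows)}"
        )
    ring_index = np.array([r[0] for r in rows], dtype=int)
    arm_index = np.array([r[1] for r in rows], dtype=int)
    positions = np.array([[r[2], r[3]] for r in rows], dtype=float)
    return DiscLayout(
        spec=spec,
        ring_radius=_ring_radii(spec.per_arm),
        ring_offset=betas,
        positions=positions,
        ring_index=ring_index,
        arm_index=arm_index,
    )
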