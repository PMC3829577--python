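# Methods

## Model

The network is a disc of binary relay neurons on Φ spiral arms with N
neurons per arm; ring `n = 0` is a single central neuron shared by all
arms.  Neurons have no leak, refractoriness, or weights: each simply
re-emits at `t + Δt` what it received at `t`, one ring inward along its
arm.  `Δt` is a dimensionless unit step (= 1); physical time scaling is a
presentation concern.  An activation placed on ring `n` therefore exits
through the summing neuron at step `n + 1`, and the central sample exits
at step 1, so the emitted pattern is

    TP(1) = center,   TP(t) = Σ_φ ring_{t-1},   t = 2..N,

with `Σ_t TP(t) = m` (the initial activation count) by construction.
The arms terminate at ring 1 into the summing neuron and the central
neuron feeds it directly; each initial activation is counted exactly
once.  This conservation is what the shutter logic relies on: the
inhibitory neuron's trace `Inh(t) = m − Σ_{s≤t} TP(s)` is the activity
still on the disc, monotonically falling from `m` to 0 by step N.

### Disc geometry

Ring `n` sits at radius `√n / √(N−1)`.  On a disc, area grows with r², so
square-root radial spacing with a fixed number of neurons per ring gives
approximately uniform areal density — the property that makes a rescaled
object produce a time-and-magnitude-rescaled pattern rather than a
different one (a log-polar layout would instead give scale invariance at
the cost of permanently non-uniform resolution and hopeless translation
behavior).

Each ring's angular offset β_n is chosen by a randomized max–min search:
`trials` candidate offsets are drawn uniformly from one arm sector
`[0, 2π/Φ)` (a larger range is redundant by arm symmetry), each scored by
the minimum distance from the candidate ring's neurons to all already
placed neurons, best candidate wins, offsets accumulate (which is what
bends the arms into spirals).  Numerical choices: scores are squared
distances rounded to 1e−12 so that mathematically exact ties (every
ring-1 candidate is equidistant from the lone center neuron) break to the
first-encountered candidate deterministically; the search is accelerated
by two provably exact shortcuts (single-candidate-point scoring via arm
symmetry, and radial pruning of placed neurons that cannot be the
minimizer), and the test suite checks bit-equality against a naive
all-pairs reference.

Density validation uses equal-area annuli: neuron counts per annulus
(uniformity) and mean nearest-neighbor distance per annulus (the
`nn_distance_profile`).  Equal-area rather than equal-width bands weight
every neuron evenly; the innermost rings are genuinely over-dense (Φ
neurons on a tiny circumference), which an equal-width innermost band
would exaggerate.

### Feature front ends

- **DoG high-pass** — `G(σ_c) − G(σ_s)` with reflective boundaries;
  defaults σ_c = 1 px, σ_s = 2 px for 200×200 images.  Isotropic, hence
  trivially rotation-compatible.
- **Radial Gabor** — at pixel p (center-relative, +y up) the Gabor kernel
  orientation is `θ(p) = α + atan2(y, x)`, computed exactly by per-pixel
  kernel evaluation (row-chunked to bound memory).  This makes the
  response map rotation-equivariant about the center; the package also
  ships the Cartesian (fixed-θ) filter, which fails equivariance, as the
  negative control.  Defaults (wavelength 8 px, envelope σ 3 px, aspect
  0.5, phase 0) are engineering choices; nothing downstream depends on
  them structurally.
- Feature maps are rectified (absolute value) before projection because
  disc neurons are binary and respond to response magnitude.

### Projection and thresholds

The unit disc is inscribed in the (square) feature map; each neuron
samples its nearest pixel (bilinear available behind a flag) and fires iff
the sample exceeds a threshold.  `project_frame`'s default threshold is
0.0 — any positive response — but the characterization pipeline uses
1e−3 on |DoG| maps: a strict zero threshold would fire neurons on float
round-off (~1e−16) in the interior of large constant regions, which is
numerically meaningless, while 1e−3 sits far below any real edge response
on [0, 1] images.

### Shutter modes

`stream_run` admits frames from a (map, arrival step) stream either
periodically every N steps (worst-case drain time) or gated on
`Inh = 0` exactly.  While the disc is busy the latest pending frame wins
and earlier unserved frames are dropped, modeling a continuously
refreshing sensor; an admitted empty frame occupies the disc for one
step.  Queueing policy is a package choice; only the admission condition
is structural.

### Multi-disc fan-out

`build_channels` crosses radial-Gabor orientations with disc densities;
each lower-density disc is built by re-running the placement search at
`per_arm = round(density · N)` (round half up) with a derived seed, so
every disc independently satisfies the uniformity guarantee, rather than
subsampling the full disc.  Channels share the activation threshold and
have no cross-channel state; sparser discs drain earlier, giving a coarse
early preview of the full pattern.

## Time-warp normalization and similarity

`normalize_tp` resamples the pattern's support (first through last
nonzero step) linearly to a fixed length (default 200) and divides by
`m`, emulating how a time-warp-invariant memory would use the inhibitory
neuron's initial level as a size cue.  Alignment-by-support is what lets
patterns from differently sized objects be compared; magnitude division
does not affect cosine or rank similarity but keeps stored values on a
common scale.  Similarity metrics are cosine similarity and Spearman rank
correlation (mean ranks for ties; the tie-handling is cross-checked in
the tests against a hand-rolled rank computation).

## Invariance sweeps

For each image and transform magnitude the pipeline is: transform →
|DoG| → project (threshold 1e−3) → ripple → normalize both patterns →
cosine and Spearman versus the untransformed pattern; tables hold
per-grid-point arithmetic means over images, with pairs excluded (and
counted) when a transformed pattern is empty or constant.

Transform application:

- **Translation** — integer-pixel raster shift (exact, no resampling
  error), zero-filled at the border.
- **Scale** — nearest-neighbor raster rescaling about the center; the
  information loss of nearest-neighbor downscaling is itself part of what
  the sweep measures.
- **Rotation** — applied at the *sampling stage* by default: the fixed
  feature map is sampled with the disc rotated by −θ, which models a
  scene rotating continuously in front of the sensor and involves exactly
  one resampling.  Rotating the raster first and then sampling it stacks
  two nearest-neighbor resamplings; the aliasing of the first decorrelates
  monotonically with angle and buries the disc's arm periodicity (we
  measured its autocorrelation structure directly), so the raster route is
  kept only as an option (`rotation_mode="raster"`).  At every multiple of
  `2π/Φ` the rotated neuron set coincides with itself and the similarity
  returns to exactly 1.

`estimate_period` reports the lag of the strongest positive-lag peak of
the mean-cosine curve's autocorrelation (grid must be uniform and cover
at least two periods; peaks need ≥5% of the zero-lag value in prominence).
The strongest peak is used rather than mean peak spacing because the
within-period curve shape is near-symmetric about the half sector, which
plants genuine secondary peaks at half-period lags.

## Synthetic image set

All experiments run on procedurally generated, centered 200×200 grayscale
images, in six kinds in equal proportion: letters, digits, 2–4-letter
words (from an embedded stroke-vector font, so rendering is identical on
every platform), geometric shapes (circle / polygon / star / rectangle,
filled or outline), radial-harmonic blobs with carved-out interior
features (stand-ins for face-like images), and fish-like silhouettes
(ellipse body, triangle tail, fin, eye hole).  Glyph heights span
45–80% of the frame, blob radii 45–70% of the half-side, silhouette
lengths 55–85%; every image is re-centered on its intensity centroid
(within 2 px) and its foreground is kept between 10% and 80% of the
inscribed disc's area by a deterministic corrective loop (stroke
widening / scale reduction).  Everything derives from a single seed.

What the generator does **not** emulate: photographic texture, shading,
and interior detail of real faces and fish.  Its |DoG| maps are thin
contours, so patterns from blobs and shapes concentrate in few rings and
are *more* fragile under translation in rank-correlation terms than
dense-texture photographs would be, while cosine similarity (dominated by
the large pattern values) is somewhat less affected.  Passing sweeps on
this set therefore demonstrate the transform's structural properties —
conservation, arm periodicity, time-warp alignment, translation
sensitivity — not pixel-exact agreement with measurements on photographic
sets.

## Problem sizes

The full characterization disc is Φ = 200 arms × N = 200 per arm (39801
neurons, 1000 placement trials per ring, ~3 s to build).  The test suite
runs the headline checks at that scale with 30–100 images per sweep; the
reproduction script uses 100 images, the rotation-periodicity check 30
images × 64 angles over four arm sectors.  Unit tests use small discs
(Φ, N ≤ 32), where brute-force oracles are exact and fast.

## Known limitations

- Translation sensitivity figures depend on the image set's object-size
  and texture statistics (see above); rank-correlation drops on this
  synthetic set run higher than on photographic material.
- The gated shutter admits at `Inh = 0` exactly; a low-activity threshold
  variant is not implemented.
- Sub-threshold (gray) feature values are binarized by a fixed threshold;
  no graded or probabilistic activation.
- No downstream memory/recognition network, no salience/centering stage,
  and no 3D extension: inputs must arrive centered.
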