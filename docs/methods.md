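# Methods

## Model and conventions

All descriptors operate on grayscale video volumes stored as float arrays
indexed `[y, x, t]` (0-based; `t` last). The core operator is the local
binary pattern: bit `p` of a pixel's code is 1 iff the intensity of neighbor
`p` is **greater than or equal to** the center intensity, and bit `p` is
weighted `2**p`. Neighbor `p` of `P` sits at angle `2*pi*p/P`
counter-clockwise from the positive x-axis, so for the `P=4, R=1`
configuration used throughout, the bit order is east, north, west, south
(east least significant). The threshold direction matters only as a
convention: flipping it complements every bit, which permutes histogram bins
without changing their information content; the direction above is the
standard one and all oracle tests assume it.

Non-integer sampling positions (general `P`, per-axis radii) are resolved by
bilinear interpolation. At `P=4` with unit radii the neighbors fall exactly
on grid pixels, so no interpolation error enters the main configuration.

Border pixels whose neighborhood does not fit inside the image are excluded
from all histograms; no padded intensities are fabricated. The alternative
(edge replication) exists only in the complexity instrumentation, where the
point is to count comparisons over the idealized full volume.

Block partitioning divides the *coded interior* into `rows x cols`
contiguous rectangles with edge `i` at `floor(i * extent / n)`; trailing
blocks absorb remainders. The same rule is used for 2-D histograms and for
the spatial partition of volume descriptors, where it applies to (y, x) only
— every frame of a voxel's block contributes to that block's segments.
Each block segment is L1-normalized independently (per block, per plane),
so every segment sums to one; whole-vector normalization would let large
blocks dominate small ones.

## Descriptors

**LBP-TOP.** Each voxel in the common codable set
(`y,x,t` at least the per-axis margin from every face) is coded on its XY,
XT and YT planes. On the space-time planes the two axes carry different
radii (e.g. `R_x=1, R_t=3`), so the four neighbors sit at `(+-R_x, 0)` and
`(0, +-R_t)` in plane coordinates — elliptical rather than circular
sampling, the only reading consistent with per-axis radii and integer
sampling. Output layout is block-major: per spatial block the XY, XT, YT
segments in that order.

**LBP-SIP.** The six unique intersection-line neighbors, grouped XY+2: a
4-bit code over the four spatial neighbors (same bit order as core LBP) and
a 2-bit temporal code with the past frame (`t-R_t`) as bit 0 and the future
frame (`t+R_t`) as bit 1. The spatial sub-histogram is mathematically
identical to per-frame `P=4` LBP pooled over interior frames, which the test
suite checks as an oracle identity. The temporal radius must be integral
(temporal neighbors are whole frames).

**LBP-MOP.** The three mean plane images are computed as arithmetic means in
floating point and are *not* re-quantized to integers before coding —
re-quantization would destroy exactly the subtle between-frame differences
the method targets. Orientation: `xt_mean` has x as rows and t as columns,
`yt_mean` has y as rows and t as columns; a "3 x 2" grid on these planes
means 3 blocks along the spatial axis by 2 along the temporal axis, matching
the short temporal extent of length-normalized clips. A `plane_filter` hook
lets denoising run on the three mean images instead of on every frame; both
orders are supported because usage differs between protocols and the
averaging order is otherwise unspecified.

## Complexity instrumentation

Every descriptor tallies actual neighbor-vs-center comparisons into
`meta["comparisons"]`. With `full_volume=True` the input is edge-replicated
so every voxel is coded and the tally equals the closed forms
`12*w*h*l` (TOP), `6*w*h*l` (SIP) and `4*(w*h + w*l + h*l)` (MOP) exposed by
`comparison_count`; tests assert the tally/formula agreement and the exact
2:1 TOP:SIP ratio. These are operation counts, not wall-clock timings.

## Preprocessing

* **Wiener filter** — the classical local-adaptive estimator
  `mu + max(0, v - nv)/max(v, nv) * (x - mu)` with local mean `mu` and
  variance `v` over a sliding window and noise power `nv` estimated as the
  mean local variance when not given. Default window 3x3 (the common
  adaptive default; the protocol leaves it open), exposed in config. Local
  statistics use reflective borders so constant images pass through exactly;
  zero-padded moving averages would distort the frame edge.
* **Gaussian pyramid** — separable 5-tap binomial kernel `[1,4,6,4,1]/16`
  with mirror-symmetric borders, factor-2 decimation by even-index sampling
  (level k+1 keeps `ceil(n/2)` samples per axis), default 4 levels; every
  level is bilinearly resized to a common target (protocol value 163x134)
  so block grids stay comparable across levels, and "all levels" mode
  concatenates the per-level histograms.
* **Temporal resampling** — per-voxel linear interpolation to a fixed frame
  count at uniform positions over `[0, l-1]`, endpoints exact. This is a
  deliberately plain length normalizer: it preserves the one property the
  descriptors need (fixed `l`) and cannot overshoot intensity bounds.
  Model-based temporal interpolation is out of scope.

## Evaluation harness

SVM via scikit-learn's `SVC` behind the module interface: kernels linear,
RBF and polynomial (degree 6 for the classical protocol), `C = 1`,
`gamma = 1/n_features`, one-vs-one multi-class — the defaults of the era's
SVM implementations, all exposed. Histogram features are used as-is (already
in [0, 1]); a standardization switch defaults off. Folds are generated
deterministically by sorted sample id; LOSO subject-disjointness and exact
test-set tiling are asserted structurally in tests. Accuracy is pooled over
all test predictions, not macro-averaged over folds. Folds whose training
data lacks a second class are skipped with a warning and reported.
Because the classical protocols never published their SVM hyperparameters,
absolute accuracies on any real corpus are not bit-reproducible; the harness
therefore targets internal validity (determinism, leak-freedom, sane
behavior on controlled synthetic data) rather than matching printed tables.

## Synthetic data

The generator emulates the statistical skeleton of a micro-expression
corpus: a band-limited per-subject texture (mean 128, sd 20 in 8-bit units)
acting as the identity confound; a class signal that is a small Gaussian
windowed traveling wave (sd h/5, jittered center) whose carrier orientation
and temporal angular frequency depend on the class; additive Gaussian sensor
noise; and quantization to whole 8-bit intensities, which also makes PNG
round-trips voxel-exact. Defaults: 16 subjects x 3 videos, 3 classes,
48x48x10 volumes (the classical length-normalized clip count), motion
amplitude 6 and noise sd 2 — an amplitude a few quantization steps above the
noise floor, i.e. motion visible to local ordering but invisible as a mean
shift. With `spatial_class_cue=False` all classes share one carrier
orientation and differ only in temporal frequency, which isolates the class
signal in the temporal half of SIP's code — used to check that the
descriptor/harness pair attributes signal to the right segments.

What the generator does **not** emulate: faces or facial geometry,
registration error, illumination flicker, head motion, class imbalance, or
temporal onset/offset dynamics. Passing end-to-end tests therefore
demonstrates that the descriptors and harness recover controlled
spatio-temporal structure under a subject confound — not any particular
recognition rate on real faces.

Everything is keyed through `numpy.random.SeedSequence` on
`(seed, subject, class, index)`, so corpora are deterministic at every
granularity.

## Problem sizes and numerical choices

Oracle-equivalence tests compare the vectorized descriptors against naive
triple-loop references on 12x12x9 volumes (the scale where exhaustive loops
are instant); end-to-end recovery runs the default 48-video corpus with SIP
5x5-block features under LOSO, finishing in seconds. Ties in the threshold
(`neighbor == center`) code as 1 by definition, which is why tests use
integer-valued intensities and exact means — equality cases are then decided
identically in both the vectorized and reference paths. Segment
normalization tolerates empty segments (left as zeros) only in the
full-coverage instrumentation path; in normal operation an empty block
raises a `DegenerateBlockError` naming the block (and plane, for MOP) so
misconfigured grids fail loudly.

## Known limitations

* Real-data accuracies cannot be validated here (restricted corpora,
  unpublished hyperparameters); the complexity claims and structural
  identities are validated exactly instead.
* Uniform, rotation-invariant and other LBP variants are out of scope, as
  are volume LBP (VLBP), face detection/alignment, and model-based temporal
  interpolation.
* The Wiener window size and the mean-plane averaging order for denoised
  pipelines are conventions, not published values; both are configurable.
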