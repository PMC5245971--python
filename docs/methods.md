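# Methods

## The question being simulated

fMRI recovers similarity structure between stimuli even though each
voxel sums the activity of an enormous neural population and each
sample sums seconds of spiking. The simulations here treat a candidate
neural code as a function `f` from stimulus vectors to representation
vectors and ask how much of the stimulus similarity structure survives
the map. The operational measure is *functional smoothness*: over a set
of stimulus pairs, compute the Pearson similarity of each input pair
and of each encoded pair, then correlate the two lists (again Pearson).
A statistic of 1 means encoded similarity is a perfect affine image of
input similarity; 0 means the code scrambles it entirely.

## Stimulus model

Each replication draws a prototype of `dim = 100` independent N(0, 1)
activations and 19 distortions, where level *i* adds fresh N(0,
(0.05 i)²) noise to the prototype. Every item — prototype and
distortions — is re-normalized to mean 0 and population s.d. 1, so
noise level manipulates only similarity, not scale. Expected input
similarity at level *i* is `1/√(1 + (0.05 i)²)`, falling from ≈0.999 to
≈0.725 across the 19 levels; the Monte-Carlo tests verify this closed
form. The noise is *fresh* per level (each distortion conditionally
independent given the prototype). The recurrence "previous s.d. plus
0.05" describes the s.d. schedule, not noise accumulated onto the
previous distortion; a cumulative random-walk variant is available via
`generate_distortions(..., cumulative=True)` for sensitivity checks.

Pair set for the statistic: the 19 (prototype, distortion) pairs per
replication. Self-pairs are degenerate (similarity 1 by construction on
both sides) and are rejected. A `n_prototypes` option generates several
prototype families per network for users who want a denser pair set;
the default is one, matching the base protocol.

## Coding schemes

Models 1–11, in order of complexity: identity (vector space), tanh gain
control, matrix multiplication `Wx`, perceptron `tanh(Wx)`, and 2–8
layer stacks `tanh(W_k · y_{k-1})`. All weight matrices are square
`dim × dim` with independent N(0, 1) entries and **no bias terms**
(the minimal model; nothing in the design requires biases). Within a
replication, one 8-layer stack is initialized and every depth-k model
uses its first k layers, so model differences are not confounded with
weight draws. Only the final layer is "scanned".

With z-scored inputs and N(0, 1) weights the pre-activation s.d. is
√dim = 10, so tanh operates deep in saturation: final-layer entries at
depth 8 are close to ±1 (verified in tests), which is precisely why
similar inputs can land in nearly orthogonal corners of the hypercube
and smoothness degrades with depth.

Factorial design coding represents a ±1 factor setting as its full row
of the two-level full factorial design matrix (intercept, main effects,
all interactions; `2^n × 2^n`, Yates row order with the first factor
varying fastest, columns ordered by interaction order then
lexicographically). All distinct rows and columns are orthogonal in
exact integer arithmetic, so the normalized design `Q = M/√(2^n)`
satisfies `QQᵀ = QᵀQ = I`. The statement is proven by direct
verification, not simulation; the proof concerns dot-product
similarity (Pearson on rows including the constant intercept column
differs, and the similarity-matrix tooling reports both views). The
encoder deliberately accepts only discrete ±1 factor vectors; a
sign-binarization helper is provided as a labelled extension for
pushing continuous stimuli through it.

Hash coding serializes each element to its shortest round-trip decimal
string, hashes the UTF-8 bytes with SHA-1, and maps the 20 digest bytes
to reals in [−1, 1] via `b/127.5 − 1`, concatenating per element
(output length 20·dim). Any canonical serialization would do — the
analysis relies only on digests being pseudo-random — and this one is
deterministic across platforms.

## Aggregation of the smoothness statistic

Two modes are implemented and always reported side by side:

- **pooled** (default): one Pearson correlation over all
  (prototype, distortion) pairs of all replications (1,900 pairs under
  the defaults). This is the literal reading of computing the statistic
  "using all item pairs", and is the headline number.
- **per_network_mean**: one statistic per replication (19 pairs), then
  the mean and s.d. across replications.

The two differ by ≲0.02 at all depths under the default conditions.
Under the defaults (seeded), pooled smoothness runs ≈0.91 at depth 1
down to ≈0.26–0.29 at depth 8, with seed-to-seed s.d. of ≈0.015 at
depth 8.

Representations that saturate to exact constants have undefined Pearson
similarity; such pairs are excluded with a logged count
(`n_excluded_pairs`) rather than imputed, because imputing any value
would bias the proportionality statistic. Under the default conditions
no exclusions occur.

## Hash-coding null bands

The hash demo tests two nulls. The similarity curve: each level's mean
similarity over replications is compared against an analytic band for
the mean of independent Pearson correlations between uncorrelated
length-m vectors (s.d. ≈ 1/√(m−1)), Bonferroni-corrected across the 19
levels so the band is simultaneous — the claim is "every level inside",
and a per-level band would be rejected under its own null by
construction. The smoothness statistic: compared against a
1,000-permutation null built by shuffling the output-similarity list
against the input list, using the 2.5th–97.5th percentile band.

## Voxel summation

Voxels are non-overlapping pixel blocks (0-based, row-major, half-open
ranges); a voxel's value is the exact block sum, so total activity is
conserved and any information loss is purely a sampling limit.
Inhomogeneity is the population s.d. across voxels: zero exactly in the
blind regime. Fields whose dimensions do not divide the voxel size are
rejected by default (`edge="truncate"` drops trailing partials
explicitly). For a periodic field of period p, inhomogeneity is 0
whenever the voxel width is a multiple of p and positive when the voxel
undersamples the pattern (width < p) — the discrete analogue of a
Nyquist limit, exercised by a parameter sweep in the tests. No
haemodynamic point-spread or response-function convolution is modelled;
the demonstrations isolate the summation argument.

## Numerical choices

- Pearson similarity raises on constant vectors instead of returning 0,
  and returns exactly 1.0 when the centered inputs are bit-identical
  (so "identity encoder ⇒ statistic = 1.0" holds without 1-ulp
  rounding artifacts). Intermediate moments use the sample convention;
  ρ itself is convention-independent.
- z-normalization uses the population s.d. (divide by n) so "σ = 1"
  holds literally per item; configurable via `ddof`.
- Orthogonal-map invariance: Pearson centers vectors, so only
  orthogonal maps that fix the all-ones direction preserve it exactly;
  the invariance test rotates within the mean-zero subspace (scaled),
  for which the statistic equals 1 to 1e-9.
- Reproducibility: every experiment derives per-replication generators
  from `SeedSequence([seed, replication, stream])`, so results are
  bit-identical given (config, seed) and independent of evaluation
  order. Reports embed config, seed, and package version, and contain
  no timestamps, so re-runs are byte-identical.

## What the synthetic generator does and does not emulate

The generator reproduces the statistical structure the simulations
assume — graded, isotropic similarity around a prototype in a
featureless 100-dimensional space. It does not emulate natural-image
statistics, category manifolds, measurement noise, or haemodynamics.
Passing tests therefore show which codes can or cannot preserve graded
similarity structure under an idealized summing measurement; they do
not quantify what any particular scanner would recover from any
particular brain region.

## Problem sizes

Default experiments (100 networks × 20 stimuli × depth 8, dim 100) run
in about a second on one CPU; unit tests use scaled-down replicas
(dim 20–30, 3–10 networks) where the full protocol is not the point,
and the full protocol where it is.

## Known limitations

- Depth-8 smoothness under the default conditions concentrates around
  0.26–0.29 (pooled), at the upper edge of the historically reported
  range; the exact value is sensitive to aggregation mode and to
  unmodelled measurement steps (e.g. any within-voxel summation of
  units before correlating), which this package deliberately does not
  add to the default protocol.
- Training is out of scope: all networks are random, and conclusions
  about trained deep networks enter only through the external
  activation-matrix interface.
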