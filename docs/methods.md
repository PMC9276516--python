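# Methods

## Model and procedure

The package segments a single 2-D gray-level image into `c` tissue
classes by fuzzy C-means (FCM) clustering of pixel intensities,
optionally regularized by spatial neighborhood information.

1. **Normalization.** Input images are min-max normalized to [0, 1];
   the parameters are recorded so gray values can be mapped back. A
   constant image normalizes to all zeros (logged as a warning).
2. **Filtering.** A 3×3 median filter (rank-based, range-preserving)
   removes impulse noise before clustering. It can be disabled.
3. **Initialization.** Initial centers come from a global-best particle
   swarm minimizing the FCM objective itself (memberships filled in by
   the closed-form optimal update for each candidate center vector), or
   alternatively from `c` distinct data values drawn with the run seed,
   or k-means++.
4. **Alternate optimization.** Membership and center updates alternate
   until the max-absolute change in the membership matrix falls below
   `ε` or `T` sweeps are reached. Both updates are exact coordinate
   minimizers of the objective, so the recorded objective trace is
   non-increasing; the implementation asserts this within 1e-9.
5. **Outputs.** Hard labels (argmax membership, ties to the lowest
   index), centers sorted ascending so label 0/1/2 always means
   darkest → brightest tissue (CSF < GM < WM for T1-like contrast), the
   membership-weighted reconstruction, and the SB / W_RE metrics when a
   reference labeling exists.

### Spatial regularization

The correlation weight between a pixel and each neighbor in its
(2r+1)×(2r+1) window (center excluded, mirror padding) is a Gaussian
kernel on their gray difference, `w_kr = exp(−(x_k − x_r)²/σ_g²)`. The
squared distance entering the objective becomes the convex blend
`D̃² = (1−β)·own + β·weighted-neighborhood-mean`. This keeps both
closed-form updates intact: memberships use `D̃`, and the center update
is the same weighted-mean formula applied to the blended intensities
`x̃_k = (1−β)x_k + β·Σ_r w_kr x_r / Σ_r w_kr`. We chose blended rather
than raw intensities in the center step because that choice makes the
center update the *exact* minimizer of the blended objective — descent
is then guaranteed at every half-step, and at β = 0 the formula reduces
verbatim to the classical update. The effect on fitted centers is tiny
(the blend is intensity-preserving within homogeneous regions) but the
monotonicity guarantee is unconditional.

### Degenerate cases

* A cluster whose total membership mass reaches zero raises an error
  rather than being silently re-seeded; callers may retry with a new
  seed, keeping every run reproducible.
* A pixel at zero distance from one or more centers gets all its
  membership, split uniformly over the coincident centers (the same
  rule absorbs floating-point overflow of the inverse-distance powers).
* Correlation weights are strictly positive, so a zero neighborhood
  total can only arise from underflow; such pixels fall back to their
  plain distance with a warning.

## Parameters

| Parameter | Meaning | Default | Why |
|---|---|---|---|
| `c` | tissue classes | 3 | CSF / GM / WM |
| `m` | fuzzifier (>1), partition softness | 2.0 | standard choice; the method's reference setting |
| `T` | max sweeps | 100 | ample: fits converge in < 10 sweeps on phantoms |
| `ε` | stop tolerance on max-abs ΔU | 1e-4 | reference setting; well below label-changing scale |
| `radius` | neighborhood radius (pixels) | 1 (3×3) | smallest window that regularizes; larger blurs thin structures |
| `σ_g` | gray-difference scale | image std | self-scaling: differences ≫ one tissue contrast get near-zero weight |
| `β` | spatial mixing weight | 0.5 (0.6 in the evaluation protocol) | balanced fidelity/smoothing; 0 disables regularization |
| PSO | swarm 20, 50 iterations, ω=0.72, c1=c2=1.49, clamp 20% of range | — | canonical stable settings for global-best PSO |

All randomness (initial centers, swarm state, phantom noise) flows from
integer seeds; equal seeds give bit-identical results, including output
files.

## Synthetic phantoms

Phantoms stand in for patient MR slices: a geometric ground-truth label
map, per-class mean intensities (default 0.2/0.5/0.8, T1-like
contrast), an optional smooth multiplicative bias field (product of
slow sinusoids, peak amplitude configurable, default off), and seeded
additive Gaussian noise, clipped to [0, 1] (noise tails are slightly
truncated at the bounds). The `slice-like` geometry is a head ellipse
with CSF rim and central ventricle whose GM/WM interior boundary is
carved by thresholded smoothed noise — convoluted, cortical-style, and
class-imbalanced. What phantoms do **not** emulate: Rician noise
statistics, partial-volume voxels, k-space artifacts, skull/scalp
signal, or 3-D continuity. Passing the phantom suite therefore shows
the algorithmic claims (noise robustness, exact reductions, metric
behavior) — it does not certify clinical-grade accuracy on real MRI.

The evaluation protocol used by the test suite and the acceptance
script is: ten phantoms (seeds varied), 128×128, class means
0.2/0.5/0.8, at noise σ = 0.08 and σ = 0.04; pipeline = median filter,
PSO init, spatial FCM with β = 0.6, radius 1, m = 2, T = 100, ε = 1e-4;
score = mean SB over the ten runs. These sizes keep a full run in
seconds while leaving per-seed noise on SB well under a percentage
point.

## Numerical and design choices

* Convergence is measured in the max-absolute-entry norm of ΔU — the
  strictest elementwise criterion, and the one that directly bounds
  label changes.
* Cluster-label correspondence for SB uses optimal assignment over the
  c×c contingency table (Hungarian); greedy matching is order-dependent
  and was rejected.
* W_RE is the mean squared error between image and reconstruction; a
  ratio form would be undefined at zero-intensity pixels.
* The reconstruction weights are the memberships raised to `m`, which
  makes the reconstruction exact for crisp partitions.
* Median filtering of a noiseless phantom reassigns single-pixel-wide
  boundary structures, so with the default filter the pipeline scores
  ~0.996 rather than exactly 1.0 on noiseless truth; with the filter
  disabled, the clustering path alone is an exact fixed point there.
* The multithreshold baseline (multi-level Otsu) and crisp k-means are
  deliberately spatial-context-free comparison arms; level-set methods
  and wall-clock comparisons are out of scope (the latter are
  hardware-dependent).

## Known limitations

* Scalar (single-channel) features only; no multispectral fusion.
* Volumes are processed slice-wise; no 3-D neighborhoods.
* No bias-field *correction* — the spatial term mitigates but does not
  remove smooth inhomogeneity; a strong bias field shifts class means
  locally and will degrade accuracy.
* FCM converges to a local minimum; PSO initialization reduces, but
  cannot eliminate, sensitivity to starting centers.
* The number of classes `c` must be supplied; no validity-index model
  selection is included.
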