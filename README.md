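# fcmseg

Fuzzy C-means (FCM) tissue segmentation for brain MR slices, with
gray-difference neighborhood regularization, particle-swarm-optimized
initial cluster centers, and the SB / reconstruction-error evaluation
metrics. Written for image-analysis practitioners who need a
reproducible, testable gray-level tissue classifier (CSF / gray matter /
white matter) and a synthetic-phantom harness to validate it without
patient data.

## The method

Each pixel intensity `x_k` receives a graded membership `u_ik ∈ [0, 1]`
in every tissue class `i`, with `Σ_i u_ik = 1`. Classical FCM minimizes

    J(U, V) = Σ_i Σ_k  u_ik^m  d_ik²,      d_ik = |v_i − x_k|,  m > 1,

by alternating two closed-form updates until the membership matrix
stops changing (max-abs change < ε) or `T` sweeps are reached:

    v_i  = Σ_k u_ik^m x_k / Σ_k u_ik^m
    u_ik = 1 / Σ_j (d_ik / d_jk)^(2/(m−1))

Pixels coinciding exactly with one or more centers receive all their
membership mass, split uniformly over the coincident centers.

Intensity alone is fragile under noise, so the spatial variant couples
each pixel to its neighborhood through gray-difference correlation
weights `w_kr = exp(−(x_k − x_r)²/σ_g²)` and replaces `d_ik²` with the
effective squared distance

    D̃²_ik = (1−β) d_ik² + β · Σ_r w_kr d_ir² / Σ_r w_kr,   β ∈ [0, 1],

a convex blend of the pixel's own term and its correlation-weighted
neighborhood term. Neighbors of similar gray value (same tissue) pull
strongly; neighbors across an edge barely pull, so boundaries survive
while isolated noise flips are suppressed. `β = 0` recovers classical
FCM exactly.

Initial centers come from a small global-best particle swarm minimizing
the FCM objective itself; evaluation uses SB classification accuracy
(fraction of pixels correct after optimal cluster-label matching) and
the reconstruction error rate `W_RE` (mean squared difference between
the image and its membership-weighted reconstruction from the centers).

## Worked example

```python
import numpy as np
from fcmseg import (FCMConfig, PhantomSpec, RunConfig,
                    generate_phantom, segment_image)

ph = generate_phantom(PhantomSpec(shape=(128, 128), class_sigma=0.08, seed=0))
cfg = RunConfig(fcm=FCMConfig(c=3, seed=0, init="pso"), beta=0.6)
result, labels, recon, report = segment_image(ph.image, cfg, truth=ph.truth)

print("centers:", np.round(result.centers, 4))
print("iterations:", report.n_iter, "converged:", report.converged)
print("SB accuracy:", round(report.sb, 4))
print("W_RE:", round(report.w_re, 6))
```

prints

```
centers: [0.2032 0.5096 0.785 ]
iterations: 3 converged: True
SB accuracy: 0.9941
W_RE: 0.001164
```

The phantom is a 128×128 three-tissue slice (true class means 0.2 /
0.5 / 0.8) with Gaussian noise σ = 0.08. The fitted centers land within
~0.01 of the generative means, 99.4% of pixels are assigned to the
correct tissue after optimal label matching, and the fuzzy
reconstruction deviates from the (filtered) image by a mean squared
error of about 1.2 × 10⁻³.

The same pipeline is available from the shell:

```bash
fcmseg phantom -o ph --sigma 0.08 --seed 0
fcmseg segment ph/image.png -o out --truth ph/truth.png --seed 0 --beta 0.6
fcmseg evaluate out/labels.png ph/truth.png
```

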