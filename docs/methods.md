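# Methods

This note documents the models, algorithms and design decisions behind
`platevol`: what each component assumes, which knobs matter, and what the
synthetic experiments do and do not demonstrate.

## 1. Reference-class formulation

Volume estimation is cast as ordinal classification followed by expectation
decoding. A `ReferenceScheme(N, Vmin, Vmax)` divides [Vmin, Vmax] mL into N
equal intervals; class *i* covers the half-open interval
`[Vmin + (i−1)·u, Vmin + i·u)` with unit `u = (Vmax − Vmin)/N`, the top
class closed at Vmax. The half-open convention is a package decision: it
guarantees every in-range volume exactly one class. Volumes outside the
range are rejected at generation time and raise at labeling time.

The reference volume of class *i* is its midpoint, `i/N − 1/(2N)` in
normalized form. The estimator is the inner product V̂ = Σ p(i)·V(i); in
normalized form V̂ = Vmin + (Vmax − Vmin)·Σ p(i)·(i/N − 1/(2N)). The two
forms are algebraically identical when V(i) are the midpoints (tested to
1e−12), and the estimate is always confined to [midpoint(1), midpoint(N)]
— expectation decoding cannot extrapolate past the edge midpoints. The
*hard* baseline takes the argmax class midpoint, with ties broken toward
the lower class index. No clipping or post-hoc calibration is applied.

Plate transfer: volumes of geometrically similar scenes scale with the cube
of the plate radius, so a scheme trained at radius r_t transfers to radius
r_new = s·r_t by multiplying Vmin and Vmax by s³. Rescaling composes
multiplicatively (s then t equals s·t). Manifests recorded under different
volume ranges can be pooled for training when their N match, because equal
*normalized* volumes imply equal classes; mixing different N is undefined
and refused.

## 2. Shape simulator

Each food is a star-shaped mound: a radial field r(θ, φ) on a regular grid
(azimuth θ cyclic over [0°, 360°), polar φ over (0°, 90°], default 64×32),
drawn i.i.d. from N(r̂, σ) and clipped below at 0.05·r̂ so the surface stays
valid. Smoothing is a separable 5×5 binomial mask applied twice — θ wraps,
φ edge-replicates; unit-sum non-negative masks preserve constants and never
increase the field's variance. Both the mask and the pass count are
config-exposed; the defaults were chosen once by inspecting rendered
surfaces for "smooth but visibly irregular" shapes.

Meshing places the grid rings at φ = 90°/n_phi … 90° (the last ring exactly
in the plate plane z = 0), adds a single apex vertex at the circular mean
radius of the innermost ring and a base-disk centre vertex, and closes the
solid with an apex fan and a flat base disk: exactly `n_theta·n_phi + 2`
vertices, watertight by construction. The φ ladder deliberately excludes
0°: a ring of near-coincident on-axis vertices would be degenerate, and a
dedicated apex vertex keeps the triangulation clean. Volume is the signed
tetrahedron sum over faces (divergence theorem); it matches `trimesh`'s
independent implementation to machine precision, converges to the
hemisphere closed form (2/3)πr³ for constant fields (error < 0.25 % at
128×64, < 0.1 % measured), and agrees with a voxel-counting oracle —
bilinear interpolation of the radial field on a 256³ lattice, sharing no
code with the tetrahedron sum — to well under 1 % on random smoothed
shapes (≈ 0.25 % typical; the residual is the chord-vs-arc difference
between the triangulated surface and the interpolated field).

Dataset generation is rejection sampling into per-class quotas: a target
volume is drawn uniformly over the class interval, converted to r̂ through
the hemisphere inverse r̂ = (3V/2π)^⅓, the shape is sampled, smoothed,
meshed and measured, and accepted only if its *exact* mesh volume falls in
the interval. Uniform-in-volume targeting keeps the within-class volume
distribution flat; targeting the radius uniformly instead would pile
density toward the low end of each class (dV ∝ r² dr) and bias expectation
decoding upward. An attempt budget (60× the quota) turns unreachable
configurations into an explicit error. Classes are balanced by default
(configurable), and train/test counts follow the requested per-class split
(the canonical 2:1). Lengths are in cm so mesh volumes are mL directly.

## 3. Rendering

Scenes are rasterized by a small z-buffer renderer (numba-compiled triangle
fill): perspective camera at 45° elevation and 4 plate-radii distance
(both configurable), framed so the plate diameter spans 95 % of the image
width — rendered images are therefore already plate-normalized; one
directional light with flat Lambertian shading (ambient 0.35); back-face
culling against the camera. The plate is a filled disk at z = 0 (the food's
downward base disk is culled, avoiding z-fighting). Food albedo comes from
seeded multi-octave value noise mapped between two randomly drawn
food-toned colors, and the background is a value-noise colormap: procedural
textures give per-sample appearance variability without any external image
assets, at the cost of photorealism (no specularity, shadows, or real food
texture). Identical inputs and seed produce bit-identical images. Renders
where food + plate cover less than 45 % of the frame are rejected as
framing bugs; a plate-filling food covers ≥ 50 % of the frame by itself.

`crop_and_resize` implements plate-anchored normalization for external
images: a square crop of side `2·r_px·(1+margin)` (default margin 5 %)
around the plate circle, bilinearly resampled, fixing the plate radius at
the same pixel fraction of every input. The same scene rendered with plate
pixel radii r and 2r collapses to near-identical crops (mean absolute
pixel difference ≈ 0.005, tested < 0.02).

## 4. Classification network

Five blocks of inverted-residual layers (1×1 expand → BN → ReLU6 →
depthwise 3×3 → BN → ReLU6 → 1×1 linear project → BN, identity skip when
stride 1 and widths match): a stride-2 3×3 stem to 32 channels plus one
residual (expand 96, project 16); then 3, 3, 4, 3 residuals projecting to
32, 64, 96, 160 with expansion widths 192, 384, 576, 960, each block
leading with its stride-2 layer; block 5 ends with a standard 3×3
convolution to 1024 features; global average pooling and a linear head to N
with a softmax. Output strides are 2, 4, 8, 16, 32. A width multiplier
scales every channel count, rounded to multiples of 8 (minimum 8).

The layers are NumPy with explicit backward passes (im2col for the 3×3
stem/head convolutions, broadcasted matmul for 1×1, shift-and-add for
depthwise, the standard batch-norm backward). Every backward pass is
checked against float64 central differences in the test suite. He
initialization, inputs scaled to [−1, 1], no weight decay.

Training policy: SGD, initial learning rate 0.01
divided by 10 every 5000 steps, one-hot cross-entropy, random horizontal
mirror as the only augmentation (the estimator must see the whole food, so
crops/rotations are off the table; mirroring changes pixels, never
labels). Heavy-ball momentum 0.9 is a package default — the convention of
the architecture family — and can be set to 0 for textbook SGD. All
randomness flows from one top-level seed through labelled substreams
("sim", "init", "train", …; SHA-256 of `seed:label`), so runs are
reproducible end to end.

Two presets are used throughout: the full-scale configuration (224 px
input, width 1.0, batch 128, 15 000 steps) and a **desk preset** (64 px,
width 0.25, batch 16, 900 steps) whose problem sizes were chosen so the
complete generate→train→evaluate pipeline runs in minutes on a single CPU
core. The desk preset is the package's own scaled-down study condition, not
a statement about the full configuration's results.

## 5. Evaluation protocol

top1 is exact-class accuracy; top3 counts predictions within one class of
the truth, with edge-class neighborhoods clipped to the valid range (truth
1 accepts {1, 2}; truth N accepts {N−1, N}). RVE = |Vp − Vt|/Vt and mRVE
is its mean over the test split; reports carry soft and hard mRVE from the
same prediction pass, per-class and overall, serialized as JSON plus a CSV
table (percent, one decimal). The error-distribution summary histograms the
signed errors (default 40 mL bins) and flags the estimator as unbiased when
|mean| ≤ 3 standard errors.

Two analytic anchors follow directly from the RVE definition on the
15-class 400–3400 mL ladder: a fixed 100 mL error is 16.7–25 % relative
error within class 1 (600 and 400 mL boundaries) but only 2.9–3.1 % within
class 15 (3400 and 3200 mL) — large classes are harder to classify yet
cheaper in relative error.

## 6. What the synthetic experiments show — and what they do not

The desk-scale end-to-end run (5 classes over 200–1700 mL, 100 train / 50
test per class, 3 training seeds) verifies the method's *mechanics*: the
classifier recovers the ladder (top3 ≥ 0.8; ≈ 1.0 measured), expectation
decoding beats both the always-guess-the-centre baseline (≈ 12 % vs ≈ 70 %
mRVE) and the hard argmax baseline on average over seeds, and the pooled
signed errors centre on zero within three standard errors.

The simulator emulates smooth convex-ish mounds on clean, centred, fully
visible circular plates with procedural textures. Real food photographs add
concave and multi-component foods, occlusion, clutter, specular plates,
unknown camera geometry, and plate detection itself — none of which these
tests exercise. Passing them validates the estimation machinery, not
real-world accuracy.

## 7. Numerical and degenerate-input choices

- Gaussian radii clipped at 0.05·r̂; grids smaller than 8×4 rejected.
- Mesh construction raises (signalling a resample) if the solid is not
  watertight or has non-positive volume.
- Probability vectors must be non-negative and sum to 1 within 1e−6.
- Batch norm uses eps 1e−5, running-stat momentum 0.9; evaluation always
  uses running statistics.
- argmax ties in the hard baseline resolve to the lower class.
- Empty splits, out-of-range labels, non-positive radii/scales and
  mismatched vector lengths raise `ValueError` rather than being coerced.
- `NetworkConfig.input_size` must be a multiple of 32 (five stride-2
  stages).
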