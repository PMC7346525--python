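# Methods

This note documents the models and numerical choices behind `rcseg`,
what the synthetic fixtures do and do not emulate, and the known
limitations.

## Pre-segmentation

The distance map is the per-pixel Euclidean RGB distance between a
plant-containing image and the empty-chamber reference, on the internal
[0, 1] color scale (range [0, √3]). Distances are clustered by 1-D
Lloyd k-means with `N_pre = 25` centroids initialized equidistantly over
`[min, max]`; for samples of ≥ 10⁵ pixels the update runs on a 1024-bin
histogram of the distances instead of the raw values (the two paths
agree to well under the convergence tolerance; the exact path is used
for everything smaller). Convergence: maximum relative centroid move
< 1e-4 or 100 iterations. Empty clusters are dropped afterwards and
labels re-indexed against the surviving ascending centroids.

Cluster selection uses a standardized color difference. For cluster *k*
(the same pixel positions in both images) and channel *c*:

    z_{k,c} = |mean_c(image, P_k) − mean_c(ref, P_k)| / max(sd_c(ref, P_k), 1/255)
    z_k     = max_c z_{k,c}

A cluster is plant-candidate when `z_k > tsh` with `tsh = 5`. Choices
made here: the *reference-only* standard deviation is used (the
reference is the noise model of the empty chamber; a pooled variant
would dilute a genuine shift with plant-color variance), the floor 1/255
matches 8-bit quantization and guards exactly constant references, and
the max over channels detects a change in any single channel. Selection
is strict (`>`), so raising `tsh` can only shrink the mask.

On high-contrast FLU frames this pre-segmentation is nearly ideal; on
VIS frames it intentionally over-selects (shadows and clutter have
nonzero reference distance) and only serves to expose comparable shapes
to the registration step.

## Co-registration

The FLU-to-VIS transform is a similarity (scale, rotation, translation
about a center in the FLU frame): chamber geometry differences are rigid
plus magnification, and the smallest adequate family is the most stable
to estimate from binary masks. The objective is the Dice coefficient
between the transformed FLU pre-segmentation and the VIS
pre-segmentation — raw intensities are not comparable across modalities,
which is why pre-segmented shapes are registered at all.

Initialization: translation from the centroid difference, scale from the
ratio of root-mean-squared mask radii, rotation 0. Refinement: a hill
climb over (scale, rotation, dx, dy), coarse-to-fine on a factor-2
pyramid down to a minimum level dimension of 64, evaluating ±step moves
per parameter, accepting only improvements > 1e-4 Dice, halving steps
otherwise, at most 50 accepted moves per level; final step resolution
0.25 px / 0.05° / 0.002 scale. Mask warping is inverse nearest-neighbour
mapping (keeps masks binary; out-of-frame pre-images are background).

On clean masks this recovers random misalignments (scale 0.8–1.25,
rotation ±10°, shifts ±30 px) with ≈ 0.1 px median mapping error. On
realistic VIS pre-segmentations that contain the plant's shadow, the
Dice optimum genuinely inflates the scale by up to ~10% to cover the
shadow; the resulting extra support is exactly the "marginal background"
the classification stage removes, so no shadow-specific correction is
attempted. Non-uniform (deformable) leaf motion is deliberately not
modelled.

## Color features and region reduction

Each RGB pixel is lifted to (H, S, V, L, a, b, C, M, Y, K). HSV and CIE
Lab (D65/2°) come from scikit-image; CMYK is the naive formula
`K = 1 − max(R,G,B)`, `C = (1−R−K)/(1−K)` etc., with C=M=Y=0 at pure
black. Every channel is rescaled to [0, 1] (`L/100`, `(a+128)/255`,
`(b+128)/255`) so that no space dominates k-means or PCA by unit scale.
Hue keeps its circular discontinuity — a plain channel concatenation is
used rather than a sin/cos encoding, accepting the wrap-around as part
of the representation.

The Eigen-color basis is a full mean-centered PCA with a deterministic
sign convention (largest-magnitude loading positive). Pixel k-means
(k-means++ init, 5 restarts, fixed seed) runs in the Eigen-color
projection of the masked pixels; the reported AC-KMR descriptors are the
region means in the *raw* multi-color space, which is also the
classifiers' training representation. The effective cluster count is
capped by the number of distinct feature vectors, so uniform regions
collapse cleanly. Stage defaults for the region count follow color
richness: 10 (juvenile), 20 (mid), 30 (adult); segmentation always
reuses the count stored in the model.

For the FLU+VIS modality (20-D features) each VIS pixel inside the
transferred mask is paired with the FLU pixel found by
inverse-transform nearest-neighbour lookup; lookups outside the FLU
frame receive the mean FLU reference color.

## Ensemble classification

The eight members and their realizations: naive Bayes (Gaussian), linear
discriminant analysis, logistic regression, Gaussian-process regression
(constant × RBF + white-noise kernel, hyperparameters by marginal
likelihood), ordinary linear regression, linear-kernel SVC, linear-kernel
SVR, and a one-hidden-layer (10 units, logistic activation, lbfgs,
≤ 500 iterations, fixed seed) neural net. Features are min-max
normalized with statistics stored in the model (constant features map to
0 with a logged warning). Regression-type members produce FE clipped to
[0, 1] and thresholded at exactly 0.5 with ties → plant. Combination:
fusion = OR; median = plant iff ≥ 4 of 8 votes (the 4–4 tie value 0.5
resolves to plant, symmetric with the FE rule). Median is the default;
every tie rule in the package (FE, median vote, region truth majority,
object-filter vote) resolves the same way, toward plant. A member whose
fit fails on degenerate data is replaced by a majority-class stub with a
warning rather than aborting the whole ensemble.

The small-object filter reuses the same eight-member machinery on five
per-component features (size, R/B, R/G, G/B with denominators clamped at
1/255, and vicinity = minimum distance-transform value to the largest
component). Components are 8-connected so thin diagonal leaf tips stay
attached. The largest component is always kept; with no trained filter
the fallback is permissive (keep everything). Object sizes are absolute
pixel counts (no normalization by image area); models store the frame
size in their metadata, so a retrained filter is expected when the
resolution changes materially.

## Evaluation

Accuracy is computed over regions, not pixels: one misclassified region
counts once regardless of area, which is deliberately more sensitive to
classification failures than mask-level Dice (also reported for
context). Region ground truth derives from pixel truth by majority
(> 50% plant, exact ties → plant). The scenario grid trains one ensemble
per (archetype, stage combination) on pooled training tables and
evaluates every member on the training table ("0") and the held-out
stage samples I, II, III. All seeds are explicit arguments and stored in
records and model bundles; identical configuration and seeds reproduce
byte-identical masks and model metadata.

## Synthetic fixtures

The generator renders parametric silhouettes (polar-lobed rosettes in
top view, Bezier grass blades and stem-plus-ellipse broadleaf plants in
side view) at three stage sizes (40/75/110 px nominal in a 512×512 VIS
frame; the FLU frame is 400×400 to echo the unequal camera resolutions).
VIS composition: light-gray background (0.78) with a ±0.08 linear
illumination gradient in a random direction, a blurred (σ = 5) shadow of
the silhouette offset by (10, 14) px at opacity 0.25, stage palettes
shifting from light juvenile green (0.55, 0.80, 0.45) to dark/yellowish
adult tones, and Gaussian sensor noise (sd 0.01). Clutter: fluorescing
moss-colored specks placed ≥ 40 px from the plant (these survive the FLU
mask and are the artefact filter's targets), non-fluorescing soil
specks, and detached green leaf tips 4–15 px from the silhouette that
must be kept. The FLU frame is rendered by sampling the VIS-frame
content through the recorded misalignment transform (default: the frame
size ratio ±4% scale, ±3° rotation, frame offset ±8 px translation), so
the "motion artefact" is known exactly.

What the fixtures do *not* emulate: specular reflections, overlapping
plants, leaves overgrowing the frame, non-rigid leaf motion between
chambers, sensor-specific noise spectra, and the color diversity of real
soil. Passing tests therefore demonstrate the pipeline's mechanics and
its behavior under the modelled difficulty, not performance on any real
platform; on these synthetic conditions the color classes are separable
enough that matched-model accuracies sit near the top of the ≥ 0.90
band asserted in the tests.

## Problem sizes

The default study is 3 archetypes × 3 stages × 10 pairs (half train,
half test), chosen as a desk-scale stand-in for the thousands of images
of a real screening campaign while keeping every color class and
developmental stage represented; the full test suite and the acceptance
script each complete in a few minutes on one CPU. The cross-stage
comparison uses 4 pairs per stage over 5 seeds, enough to make the
juvenile-vs-adult palette gap the dominant effect.

## Known limitations

- The similarity family cannot express per-leaf motion; residual local
  misalignment is absorbed by classification, not corrected.
- Hue's wrap-around can split reddish hues across the 0/1 boundary.
- Gaussian-process regression scales cubically with training-table rows;
  region tables (tens of rows per image) keep this cheap, but pixel-level
  training would not be viable.
- The original MATLAB models' hyperparameters are not published; the
  scikit-learn realizations above are declared substitutes, and absolute
  member rankings need not transfer.
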