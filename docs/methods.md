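# Methods

`sinomar` implements a two-stage learned artifact-reduction pipeline for
sparse-view CT scans of resected specimens containing a metal needle marker,
together with the simulation chain that produces its paired training data and
the metrics used to evaluate it.  This note records the model, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Geometry and projector

All computation is per-slice 2-D parallel-beam.  Conventions: image pixel
(0, 0) top-left with the isocenter at the grid center; x grows with column
index and y upward; projection angles counter-clockwise from +x, views
ordered by increasing angle; detector coordinate s = 0 at the detector
center, bin k at (k − (n_bins−1)/2)·bin_spacing; sinograms indexed
(bin, view).  The reference desk-scale geometry is a 128×128 grid, 180
detector bins and 360 views at 1° (a full turn); the full-resolution
512-bin × 360-view scale is configurable but not the test default.

The forward projector samples each ray at half-pixel steps and interpolates
the attenuation map bilinearly (a Joseph-style scheme); it is exactly linear
in the image.  Its exact adjoint (bilinear splatting) is also provided, so
that iterative reconstruction has a true transpose pair — verified by a
dot-product identity test.  The detector is required to cover the inscribed
field-of-view circle and all simulated objects are constrained to lie inside
that circle, so no projection is truncated.  Against the closed-form chord
sinogram of a uniform disk, the per-bin error at the reference geometry is
below 2 % of the sinogram peak and shrinks with grid refinement; the largest
deviations sit at the disk's tangent bins, where the pixel-basis
representation of a sharp edge limits any projector.

## Reconstruction

FBP filters each projection in the frequency domain (zero-padded to ≥ 4× the
detector length) and backprojects with linear detector interpolation,
averaging the two conjugate half-turns of a 360° scan.  Filters: ram-lak
(|f|) and shepp-logan (|f|·sinc(f/2f_N)), both zero at DC and above
cutoff·f_Nyquist; the default is shepp-logan at relative cutoff 1.0.  At an
exact half-bin detector coordinate the interpolation weight resolves toward
the lower bin index.  Negative reconstructed values are retained — the
metrics operate on raw values.

The iterative comparison baseline is penalized weighted least squares:
½‖Px − y‖² + β·Σ ψ_δ(neighbor differences) with the Huber potential ψ_δ,
identity weighting, minimized by gradient descent with a backtracking
(guaranteed-monotone) step using the exact adjoint; initialization is the
FBP image.  β (smoothness) and δ (edge preservation) are the two exposed
knobs; the comparison preset is β = 150, δ = 10⁻⁵, 100 iterations.  The
potential and optimizer are this package's choice — only the knobs and the
penalized-likelihood family are fixed by the method being reproduced; the
baseline is a comparison point, not the contribution.

## Metal workflow

Metal is segmented in the image domain by inclusive thresholding
(pixel ≥ threshold).  The default threshold is the midpoint between the
strongest soft tissue and the metal attenuation, which is exact on synthetic
phantoms; on measured data it is a config value.  The segmented metal-only
image is forward-projected and every sinogram bin with a positive metal line
integral forms the metal trace; the trace is dilated by one detector bin by
default to absorb partial-volume bins, since threshold segmentation of a
rasterized wire is never pixel-exact.  Trace removal only flags bins invalid
(values are kept but masked); reinsertion writes the segmented metal values
back verbatim after denoising.  The pipeline thresholds the initial FBP of
the input sinogram (the workflow ambiguity of *which* reconstruction is
thresholded is resolved this way and recorded here).

## Sinogram completion

A sparse scan (default ×4 decimation, 360 → 90 views) is up-sampled back to
the dense view grid with inserted views flagged invalid; the metal trace is
flagged invalid as well.  Linear interpolation then fills every invalid
entry: whole missing views along the angular direction with 360° wrap-around
(physically correct periodicity for a full scan), and metal-track gaps
inside measured views along the detector direction.  Interpolation is exact
to machine precision for sinograms affine in view index between retained
views (away from the wrap seam), which the tests pin down.

The trained sinogram network then refines *only the originally-invalid
entries*; measured bins are restored bit-identically after synthesis.  This
write-back rule is a deliberate strengthening chosen for data fidelity.

### Network input

The sinogram network receives six channels: (0) the primary
linear-interpolation fill, (1) an alternative fill interpolated purely along
the angular direction, (2) the inserted-view mask, (3) the metal-trace mask,
(4, 5) the normalized length of the invalid run each entry sits in, along
the detector and the angular axis.  Three facts motivate this.  First, the
two kinds of missing data have error scales two orders of magnitude apart
(trace bins carry most of the completion error), and a
translation-equivariant CNN cannot infer from values alone which bins are
interpolated — the masks tell it.  Second, neither classical fill dominates:
detector-direction filling wins when the wire sits near the rotation center
(a bin is then blocked over long view ranges), angular filling wins for
off-center wires; which is better is object-dependent, so the network is
given both estimates.  Third, the reliability of each fill is governed by
the gap length it bridges, which is global information a patch-local network
cannot recover — the gap maps make the blending decision patch-local.
Channels 0 and 1 share the intensity normalization; the mask and gap
channels pass through unscaled.  The global residual passes channel 0
through, so an untrained (zero-weight) network reproduces the linear
interpolation exactly.

### Consistency-guarded synthesis

At small training scales a learned completion improves most scans but can
corrupt an occasional one.  The measured projections themselves provide a
ground-truth-free check: reconstruct the completed sinogram with FBP,
forward-project the reconstruction, and measure the RMS mismatch at the
*measured* bins.  A completion that corrupts the object raises this
mismatch, because reconstruction mixes every view into every ray.  The
pipeline therefore accepts the network's synthesis only when it lowers this
reprojection inconsistency by at least 2 % (relative) compared to the
linear-interpolation initialization, and otherwise keeps the
interpolation.  The margin was fixed on development phantoms; the guard can
be disabled in the pipeline configuration.  Inference tiles the sinogram
with stride patch/4 — the heavy overlap averages out uncorrelated
prediction noise.

One caveat the guard cannot remove: reprojection consistency tracks
*reconstruction* quality, and because FBP redistributes the large
trace-bin errors across the image, a synthesis that improves the
reconstruction (and its SSIM against the reference) can still raise the
raw sinogram-domain RMSE on some objects.  At desk scale the two rankings
occasionally diverge; the guard sides with image quality, which is the
pipeline's actual aim.

## Network architectures

Both networks are encoder–decoder CNNs with two structural traits: 2×2
strided-convolution down-sampling in place of max-pooling (halving the
spatial size per stage while keeping detail in learned weights), and a
global additive skip from the input's value channel to the single output
channel, so the networks learn residual corrections and the zero-weight
network is the identity.  The sinogram U-Net uses concatenative
encoder→decoder skips; the image ResU-Net replaces concatenation with
*additive* cross-stage connections and places a residual block
(conv–ReLU–conv + skip, ReLU) in every stage.  Unspecified details are fixed
as: 3×3 convolution kernels (2×2 for the strided down-sampling), ReLU
activations, no normalization layers, nearest-neighbor 2× up-sampling
followed by a 3×3 convolution in the decoder.  The final convolution is
initialized at 5 % of the He scale so the network starts near the identity
while gradients still reach the interior layers from the first step (an
exactly-zero final layer would block all upstream gradient flow).

Depth and width are capacity knobs: the package defaults are depth 3 with 16
base channels, and the desk-scale training presets use depth 2 with 8 base
channels, ~10⁴ parameters per network.  The networks are implemented
directly on numpy arrays with hand-written backpropagation (im2col
convolutions; analytic gradients verified against central differences in the
test suite) in float32; inference on float64 data round-trips through
float32, which bounds pipeline reproducibility at ~10⁻⁶ relative rather
than bit-exact for learned stages (non-learned stages are bit-reproducible).

## Training

Patches are sampled at aligned positions from (input, target) pairs with
probability proportional to an equal mixture of uniform coverage and local
|input − target| energy (artifact emphasis, computed exactly with an
integral image).  The loss is the per-batch RMSE minimized by Adam.  The
reference-scale settings — 64×64 patches, 180 000/18 000 patches, 100
epochs, learning rate 10⁻⁵ for the sinogram network; 48×48, 458 640/80 000,
1300 epochs, 10⁻³ for the image network — are preserved as presets but are
cluster-scale; the desk presets train in minutes on one CPU.  Desk-scale
patch sizes are smaller (the sinogram patch must still span the widest metal
trace plus measured context, which sets its lower bound).

Validation is by held-out *phantoms*, not held-out patches of the training
phantoms: with fewer than ~20 training objects, patch-level validation
shares object identity with training and systematically misses overfitting.
For the sinogram stage, early stopping additionally evaluates the actual
task error — full-sinogram completion RMSE on the validation phantoms —
rather than the patch loss, whose implicit region weighting differs from
the task's.  The best-validation weights are kept.  Intensities are scaled
to [0, 1] using the value-channel min/max of the training set; the scaling
is stored with the model; mask channels pass through unscaled.

Training wires are laid out on a stratified (radius x eccentricity) grid
rather than sampled randomly: random placement under-represents the corners
of the wire parameter space (wide wires near the rotation center are the
hardest traces to synthesize), and with a few dozen training objects that
coverage gap dominates generalization.  Held-out test phantoms keep the
random wire sampler — the stratification is experimental design for
training coverage, not a change of the evaluation distribution.

The image network trains on pairs (FBP of the network-synthesized sinogram,
FBP of the ground-truth sinogram), so its input carries exactly the residual
artifacts the first stage leaves and its target carries the reconstruction
filter's own characteristics, as a measured reference image would.

## Artifact simulation

Synthetic specimens stand in for clinical scans that are not available:
piecewise-constant ellipse phantoms with an adipose-like outline (attenuation
0.2 in arbitrary units) containing 3–6 fibroglandular-like ellipses (≈0.4)
and 1–3 darker pockets (≈0.12), all inside the field-of-view circle.  The
metal wire mimics a needle marker: by default a disk cross-section of radius
2–4 px at attenuation 50 — two orders of magnitude above tissue, making
threshold segmentation unambiguous — placed within 30 % of the field-of-view
radius of the center.  Texture noise is available but off by default:
unstructured random texture has angular frequency content that is not
recoverable from 90 views by *any* method, which would contaminate the
completion comparison; real tissue structure is predominantly edge-like and
is represented by the ellipse boundaries.  Projection noise (Gaussian on the
line integrals) is likewise available and off by default; the simulation
deliberately excludes beam hardening and scatter.

One simulated case bundles: ground-truth image, dense metal-free sinogram,
dense metal-embedded sinogram, ×4-decimated sparse sinogram, ground-truth
metal mask and trace, and the FBP of the sparse metal sinogram (the artifact
image).  Datasets are HDF5 files with a JSON manifest of every spec and
seed; regeneration with the same seed is byte-identical.

## Evaluation

RMSE, PSNR (peak = max over both images, not a bit-depth constant; +inf for
identical images), global single-window SSIM, and CNR between a
fibroglandular-like target ROI and an adipose-like reference ROI.  SSIM is
computed from whole-ROI means/variances/covariance; the printed-formula
("literal") stabilizer reading, with k₁ = 0.001 and k₂ = 0.03 added directly,
is the default, and the conventional scaled reading cᵢ = (kᵢL)² is available
as an option.  With tissue attenuations of order 0.3, the literal k₂
dominates the variance terms and compresses SSIM toward 1; comparisons
between methods remain ordinal, which is how they are used here.  Line
profiles are bilinear samples along a segment.

## Problem sizes used

The test suite and the acceptance script run one canonical experiment at
the reference desk-scale geometry (128×128, 180 bins, 360 views): 32
training phantoms (a quarter held out for validation), 2 held-out test
phantoms, 2400 training patches of 24×24 for the sinogram network trained
24 epochs, and 1200 patches for the image network trained 12 epochs.  These
sizes were chosen so the whole experiment — simulation, both trainings and
the six-method comparison — runs in roughly ten minutes on one CPU.

## What the synthetic experiments show — and what they do not

Passing tests show that every deterministic stage obeys its contract
(projector oracles, interpolation exactness, metal round trips, metric
formulas, architecture identities), and that at desk scale the guarded
learned completion is at least as accurate as linear interpolation on the
held-out set (pooled over its phantoms), with the end-to-end ranking naive
sparse FBP < interpolated FBP ≤ full pipeline.  Per-phantom superiority of
the raw (unguarded) network is *not* guaranteed at this scale — whether the
network beats interpolation on an individual scan depends on the wire
geometry drawn, which is why the consistency guard exists.  The tests also
do not show clinical-scale performance: the phantoms
lack tissue texture, scatter, beam hardening and detector effects, the
networks are orders of magnitude smaller than the reference configuration,
and the quantitative SSIM/CNR/PSNR values on synthetic phantoms are not
comparable to values reported on clinical specimens.

## Known limitations

* 2-D parallel-beam geometry; cone-beam weighting and magnification are out
  of scope by design.
* The PWLS baseline's potential/optimizer are choices, not reproductions.
* Learned-stage outputs are float32-deterministic, not float64-bit-exact.
* Training determinism holds for fixed seeds in single-threaded execution.
* The SSIM literal-stabilizer default is scale-sensitive (see above).
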