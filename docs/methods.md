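# Methods

This note documents the models, the numerical choices and the limits of the
synthetic validation, in the order data flows through the package.

## Forward model (`ocmstroke.forward`)

The generator is a discrete-scatterer Fourier-domain OCT model, not a wave
simulation.  An A-scan spectrum is

    I(k_j) = E(k_j) · [ 1 + Σ_m 2 a_m cos( 2 z_m k_j + φ_m + φ_d(k_j) + ψ_r ) ] + n_j

with `E` a Gaussian source envelope (width 0.35 of the sampled span around
the 795-nm central wavenumber), `z_m` the scatterer's air-equivalent optical
depth (`z_offset + n_tissue · z_geometric`, refractive index 1.35 by
default), `φ_d` a polynomial dispersion phase in the normalized band
coordinate, `ψ_r` a global per-repeat bulk-motion phase, and `n_j` additive
Gaussian noise standing in for shot noise.  The uniform wavenumber grid has
`δk = π / (2 Z_air)`, so the FFT depth pitch is `Z_air / (N/2)` —
2.07 µm in air at the full 2048-pixel protocol, 8.28 µm at the 512-pixel
desk scale.  A quadratic, monotone, endpoint-preserving warp of the grid
emulates an uncalibrated spectrometer for the k-linearization tests.
Scatterer depths beyond the unambiguous range raise instead of aliasing.

The extended-focus optics are abstracted to a depth-independent lateral
response: one scatterer set per lateral column, no cross-column coupling.
This is a deliberate simplification — the instrument class being modelled
maintains near-uniform sensitivity over ~800 µm of depth, which is exactly
the regime where a depth-independent response is a fair abstraction.

**Scatterer population.** Per column: 24 static tissue scatterers at uniform
random depths below the surface with Rayleigh-distributed amplitudes scaled
by the local field reflectivity; one deterministic bright surface scatterer
(3× base amplitude — the pia/dura specular return that anchors surface
detection and tilt fitting); one scatterer per vessel voxel (2.5× base).
Static scatterers are sampled once per scene and reused bit-identically
across repeats and frames; their summed fringe phasor is cached, so a frame
only recomputes the vessel contribution.

**Flow and perfusion.** A vessel's flow class sets the axial random-walk
step of its scatterers between repeats (pial 2.0, arteriole 1.0, capillary
0.5 µm — all far beyond the λ/4 decorrelation scale, so every class fully
decorrelates).  The perfusion factor `f ∈ [0, 1]` of a vessel at a given
stage is the probability that a vessel scatterer is *mobile* during that
acquisition.  This choice, rather than scaling the displacement itself, is
what makes the integrated motion signal linear in `f`: decorrelation
saturates with displacement (halving an already-decorrelating step barely
changes the contrast), whereas reducing the number of moving scatterers —
physically, reduced red-blood-cell flux through a partly occluded bed —
scales the expected signal exactly proportionally.  The displacement scale
still follows the flow class, so the two notions stay separate.

**Numerical synthesis.** On a uniform grid the fringe of one scatterer is a
geometric sequence along k, so spectra are built by recursive complex
multiplication (single precision, k-major layout; relative error ~1e-5
after 512 steps, far below speckle and noise) and segment-summed per column.
Non-uniform grids fall back to the full complex exponential.  All
randomness derives from `numpy` `default_rng([seed, stream, frame])`
sequences; identical seeds give bit-identical outputs.

**Noise level.**  No noise floor is reported for the instrument, so the
spectral noise sigma is a free parameter.  The study default (0.004 with
base scatterer amplitude 0.004) gives vessel-voxel amplitude SNR well above
20 dB; the bulk-phase acceptance check instead *calibrates* sigma to exactly
20 dB image-domain amplitude SNR (mean static-voxel magnitude over the
noise-floor sigma), since that is the quantity the estimator sees.

## Scenes and time courses (`ocmstroke.scene`)

The canonical 64 × 64 × 256-voxel cortical phantom (17.2 µm lateral,
2.5 µm axial pitch, 640 µm of tissue) contains two large pial vessels
(25 µm radius), six small pial branches (8 µm) in the 0–160 µm meningeal
band, eight vertical penetrating arterioles (6 µm) spanning 160–320 µm, and
twenty capillaries (3 µm) below 320 µm.  Cylinders are rasterized
area-preservingly: per cross-section, the voxels best covered by the disc
are kept, as many as the disc area spans in voxel units, so voxel counts
track analytic cylinder volumes (within ~10% even for sub-voxel radii) and
thin capillaries remain connected single-voxel lines.

A stroke time course is four contiguous stages (baseline, dye, occlusion,
recovery) with per-vessel perfusion factors; baseline factors are pinned to
1.  The scenarios used by the tests and the acceptance script are: full
occlusion of all bands at `f ∈ {0.1, 0.2, 0.5}` (the deep-band plateau then
reads back `f`), and a superficial-only reperfusion (band 1 → 1.0,
band 2 → 0.5, band 3 → 0.05) mirroring recanalized pial arteries over a
still-ischemic capillary bed.

## Reconstruction (`ocmstroke.recon`)

Cubic-spline resampling onto the uniform grid (linear available); exact
pass-through when the resample map is the identity.  Dispersion is removed
by multiplying the spectrum with `exp(−iφ(k))`; compensating a real
spectrum also doubles the chirp of the mirror image, which is why the
single-scatterer fidelity checks are done away from DC and the mirror.  The
spectral window is Hann by default and configurable, because it changes
FWHM-based measurements; FFTs are orthonormal so the windowless stage is
exactly energy-preserving.  Cropping uses half-open intervals, 0-based, with
Z = 0 at the shallowest retained pixel; nested crops compose to the
intersection.  Optional tilt correction fits a least-squares plane through
the brightest-interface depth of every A-scan and rolls each column by the
integer plane offset.

Structural imaging is the magnitude of the complex mean over the repeat set
(coherent average — flow voxels average down, static voxels keep their
single-repeat magnitude); an incoherent mean-of-magnitudes variant exists
behind a flag for comparison.

## Angiography (`ocmstroke.angio`)

The bulk-phase estimator is `ψ_i = arg Σ_mask A_i conj(A_0)`, with a
quality score (mean resultant length).  Estimates below 1e-12 rad are
snapped to zero: they are indistinguishable from floating-point phase noise
and snapping preserves the exact cancellation of identical static repeats.
The default static-area heuristic keeps voxels above a structural quantile
whose *amplitude-normalized* preliminary motion value is below the median —
normalization matters because under a pure bulk phase the raw motion value
of a static voxel is proportional to its brightness, which would otherwise
anti-select exactly the voxels that carry phase information.  A
scene-derived truth mask is injectable everywhere, and B-scans whose
supplied mask is nearly empty (a plane filled by vasculature) fall back to
the data-driven mask with a log notice.

The motion image averages the N−1 *consecutive* pairwise complex
differences and takes the magnitude.  Note that this average telescopes:
`⟨A_{i+1} − A_i⟩ = (A_N − A_1)/(N−1)` after per-repeat phase correction, so
the statistic depends only on the first and last corrected repeats.  The
implementation follows the stated form (and its brute-force per-voxel
reference implementation is kept as a test oracle); the all-pairs variant,
which does not telescope, is available behind a flag.  An optional
trans-vessel phase scrambling adds per-repeat phase jitter to static
scatterers lying below mobile vessel scatterers, reproducing the bright
axial shadows seen beneath strongly flowing vessels; it is off by default.

## Flow quantification (`ocmstroke.flow`)

Surface detection: axial Gaussian smoothing + lateral median filter, first
crossing of an adaptive threshold (5th percentile + 0.25 of the bright
range), neighbours-median fill for undetectable columns (logged).  Depth
bands are half-open intervals in tissue microns measured from the detected
surface — 0–160, 160–320, 320–640 µm by default — and partition the
quantified range exactly.

The background-rejection threshold defaults to mean + 5·SD of the motion
signal over a declared static region.  Five (rather than a conventional
three) sigma is a deliberate choice driven by integration: the motion
statistic of noise voxels is Rayleigh-tailed and a study volume has ~4×10⁵
static voxels, so a 3-sigma cut passes ~0.6% of them and the integrated
false-positive mass rivals the true capillary signal, biasing normalized
flow ratios upward by tens of percent; at 5 sigma the residual mass is
below ~1% of the vessel signal.  The multiplier is config-exposed.

Integration sums thresholded raw intensities (not binarized voxels) per
band after zeroing the en face columns under the large-vessel mask
(quantile threshold + minimum-component-area filter on the baseline
superficial en face map).  Normalization divides by the baseline-stage
mean.  Cross-session normalization multiplies the follow-up volume by the
static-region noise-level ratio and by a smoothed per-depth structural
gain (clamped to [0.2, 5], clamping logged); identical sessions map to the
identity.  The limited-flow area is the fraction of baseline-positive ROI
pixels below threshold.  Reperfusion classes use follow-up:baseline ratio
cut points c_none = 0.2 and c_full = 0.8 — the category boundaries are not
quantified in the source experiments, so these defaults are configuration,
not constants baked into outputs.

## Serial sections and infarct (`ocmstroke.sections`, `ocmstroke.infarct`)

The section generator renders coronal slices of a lesioned hemisphere at
20 µm/px: an elliptical tissue disc with slowly varying 3-D-correlated
texture (so neighbouring sections share anatomical structure, as real
stained sections do), plus a bright lesion — by default two partially
separated, connected ellipsoid lobes sized so the rasterized lesion
reproduces the reference infarct morphology: 1.1 × 2.4 × 1.4 mm extents and
~1.4 mm³ (1.1% of a 127.3 mm³ hemisphere; the hemisphere volume default is
chosen so those two numbers are consistent, and is configurable).  Each
section is displaced by a known rigid offset (middle section kept clean as
the reference frame when offsets are drawn randomly) and degraded by noise;
ground-truth transforms and the clean label volume are returned for
recovery testing.  Lesion cross-sections are evaluated at mid-slab
(Cavalieri), giving sub-percent volume error for lesions much thicker than
one slice.

Preprocessing follows the stated order — 8-bit rescale, inversion to
negative, percentile contrast stretch (1st–99th, a stand-in for a manual
adjustment, config-exposed), area-average downsampling to 20 µm/px, and a
2 × 2 median filter with the *lower*-median convention (an even window has
no unique median).  Pair registration maximizes normalized
cross-correlation over a coarse (1°) then fine (0.1°) rotation grid within
±15°, with the translation taken from the sub-pixel Fourier correlation
peak at each candidate angle and a final quadratic refinement of the
rotation; sub-pixel shifts inside the scoring loop are essential, since
with integer shifts the NCC-versus-angle curve is quantization-jittered and
rotation recovery degrades several-fold.  Alignment proceeds from the
middle section (lower middle for even counts) outward, each section
registered to its already-aligned inner neighbour.  Segmentation is a
stack-wide Otsu threshold with largest-connected-component keeping;
user-supplied masks pass through verbatim and replace the automatic step
(the counterpart of a manual outline).  Metrics: volume = voxel count ×
pixel² × thickness; AP length = occupied sections × thickness; ML/DV =
bounding-box spans × pixel size; percent of hemisphere from the configured
hemisphere volume.  Atlas registration is out of scope; label volumes are
written as NIfTI so external atlas tools can consume them.

## Pipeline and problem sizes

The orchestrated pipeline (`ocmstroke.pipeline`, YAML-configured, unknown
keys rejected, seed mandatory for stochastic stages) streams
simulate → reconstruct → angio per frame and quantifies at the end,
recording SHA-256 checksums of every output in a manifest; identical
config + seed reproduce identical checksums.

Analyses in the tests and the acceptance script run at a desk scale chosen
as the package's own working point: a 64 × 64 lateral grid with 512
spectral pixels (the full 300 × 300 × 6 × 2048 protocol is
config-reachable), stroke series of 7–10 volumes with 3 baseline frames,
and 9- or 29-section stacks.  One simulated volume takes ~2 s and the whole
acceptance script ~1 minute on a single CPU.

## What the synthetic validation does and does not show

Passing recovery tests demonstrate that the implemented chain is
self-consistent and unbiased under the generator's assumptions: discrete
scatterers, global-phase-only bulk motion, fully decorrelating flow,
depth-independent sensitivity, additive Gaussian noise, rigid section
misalignment.  Real data violate several of these — sub-pixel axial bulk
motion and tissue deformation, multiple scattering and depth-dependent
signal roll-off, hematocrit- and angle-dependent decorrelation, section
tears and nonrigid distortion — so quantitative behaviour on real
acquisitions is not certified by these tests; the fraction-mobile perfusion
model in particular makes signal-vs-flow linearity an assumption rather
than a result.  Velocity in physical units, oxygenation, and Doppler
analysis are out of scope.
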