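# Methods

This note documents the models, defaults and numerical choices behind
`mmkidney`, and what the phantom-based validation does and does not show.

## Data model and conventions

Arrays are indexed `(z, y, x)` (volumes), `(y, x)` (planes) or
`(y, x, ν)` (hyperspectral stacks), 0-based, y increasing downward. All
micron/pixel conversions go through `pixel_size_um` (in-plane) and
`z_spacing_um` (axial). Wavenumber axes are strictly increasing, in cm⁻¹,
and must be supplied explicitly (sidecar YAML/CSV or OME metadata);
plane order alone is never trusted. Channels are assumed co-registered,
as acquired on a single multimodal platform; stitching, vignetting
correction and cross-modality registration are out of scope.

Orientation angles are fiber-axis angles in degrees in [0, 180), measured
from the +x (column) axis toward +y rows; 0° is horizontal, 90° vertical.

## Penalized reference matching (PRM)

Each pixel spectrum is scored against a lipid-subtype reference by cosine
similarity inside the C-H stretching window (2700–3100 cm⁻¹), evaluated
on an offset grid δ ∈ {−10, …, +10} cm⁻¹ (step 1) with the reference
linearly interpolated onto the stack axis (edge values extended). Each
offset carries a penalty w(δ) with w(0)=1, non-increasing in |δ|:

* `gaussian` (default): w(δ) = exp(−δ²/2σ²), σ = 10 cm⁻¹;
* `linear`: w(δ) = max(1 − |δ|/scale, 10⁻⁶);
* `none`: w ≡ 1.

The per-pixel score is the **max** over offsets of penalized similarity —
a well-aligned match is never diluted by averaging over misaligned
offsets. A smooth monotone penalty is the minimal assumption for
down-weighting calibration shifts; the exact form is a configuration
surface, and with offsets {0} and penalty `none` the score reduces
exactly to plain cosine similarity. No baseline subtraction is applied by
default (SRS backgrounds are low); zero-intensity pixels are masked, not
NaN. Simplex normalization divides each subtype score by the per-pixel
sum across subtypes; top-percentile spectrum extraction selects pixels at
or above the (100−p)-th score percentile per subtype, including all ties
(with a 10⁻¹² slack so float-identical scores stay together).

Note that the max-over-offsets rule means a pixel whose spectrum is a
slightly shifted copy of a *smooth* reference can legitimately score its
unshifted cosine (e.g. 0.998) rather than the penalized perfect match
w(δ)·1; the two coincide only for references narrow enough that small
shifts decorrelate them. Tests therefore validate against a brute-force
exhaustive-offset oracle rather than a closed-form value.

## Ratiometric biomarkers

ORR = FAD/(NADH+FAD) and saturation = unsat/(sat+unsat) are computed on
raw intensities. The denominator guard defaults to ε = 10⁻⁶ × the peak
summed intensity; pixels below it are **masked, not clamped**, which
keeps the [0,1] range and the complement identity ORR(a,b)+ORR(b,a)=1
honest. Axial profiles project valid, non-background pixels onto a
user-supplied axis (the cortical–medullary axis is anatomical and cannot
be inferred), bin at 10 µm, drop empty bins, and rescale so the
trapezoidal AUC is 1 — making profiles comparable across overall
intensity scales. Background defaults to pixels below an Otsu threshold
of the summed channels. Group comparison uses Welch's two-sided t-test on
per-region (per-glomerulus) means; the degenerate all-identical case is
reported as t=0, p=1.

## Stimulated Raman histology

Channels are percentile-stretched (1–99 %), mapped through two-endpoint
linear LUTs (protein → eosin pink (1.00, 0.55, 0.60), lipid → faint
near-white tint; both start at white so the multiply blend leaves empty
tissue white) and blended (`multiply` default; `screen` and clipped sum
available). The blend is adjusted in L\*a\*b\* (D65, sRGB companding):
nuclei — segmented as the top percentile of the lipid:(protein+ε) ratio,
de-speckled, closed, hole-filled — are tinted toward hematoxylin purple,
darkened by ΔL\*=25 and shifted Δb\*=−10; background (stretched
protein+lipid < 0.05) is lifted 70 % of the way to white. The PAS variant
adds p = log(1+k·protein)/log(1+k) (k=5) to a\* (gain 18) and subtracts
from b\* (gain 12), emulating the reddish periodic-acid-Schiff product on
glycoprotein-rich structures; k=0 reduces exactly to the H&E render.
None of the published workflows fix these color constants; all are
configuration, and the tests assert the *semantic* invariants (RGB in
range, nuclei darker than tissue, chroma monotone in protein, histogram
matching idempotent and rank-preserving) rather than specific colors.

## Glomerular stereology

The renal corpuscle (outer mask) includes Bowman's space and the parietal
epithelium; the mesangium/tuft is the protein-rich interior. Because a
protein image of a corpuscle has three intensity populations (background,
Bowman's space, tuft), the rapid open/close segmentation optionally uses
the lowest threshold of a 3-class multi-Otsu for the outer mask
(`classes=3`) and plain Otsu otherwise; tracking derives both thresholds
once per volume (lower → corpuscle, upper → mesangium) so polar planes
containing only Bowman's space are not misread as tuft. The SHG route
follows the morphological chain (disk top-hat, median, dilation to a
gradient wireframe, inversion, erosion + reconstruction, regional-maxima
seeds, open/close, constrained growth via watershed to the wireframe with
mutual exclusion) and then filters by area (3 000–80 000 µm² default) and
solidity (≥0.7); regions touching the image border are dropped as
background pockets or clipped objects.

Tracking links a corpuscle across z by requiring the previous plane's
centroid to fall inside the next plane's region (ties → largest overlap).
The maximal cross-section is the tracked area maximum; the vanishing
plane is the first plane, moving away from it, with area below 1 % of the
maximum ("vanishing point" is otherwise undefined); when both directions
vanish inside the volume the longer extent is used (one hemisphere).
Thickness = |z(max) − z(vanish)| × z-spacing. The radius is the mean
centroid-to-boundary distance at the maximal cross-section; if that
section sits at the first or last plane of the volume, no interior
maximum exists and the radius falls back to 100 µm (half the nominal
~200 µm corpuscle diameter). Retention is **inclusive**: thickness ≥
0.9 × radius (only those *below* are discarded). Vv(Mes/Glom):

* `3d_hemisphere`: Σ_z mesangium / Σ_z corpuscle over the analyzed
  planes, retained and unclipped glomeruli only;
* `2d_max_plane`: pixel ratio at the maximal cross-section;
* `2d_single_plane`: pixel ratio at one stated plane.

Direct voxel summation replaces any surface meshing — volume ratios need
no mesh. Connectivity is 8 in 2-D, 26 in 3-D; nuclei are counted as
26-connected components assigned to the region containing their centroid.

## Collagen morphometry

Background subtraction: a heavy Gaussian blur (σ=50 px), recentered to
preserve the mean, is subtracted (removing slow illumination gradients
without distorting fiber amplitudes — a multiplicative flatfield division
was measured to distort ribbon intensities by >15 % on additive
gradients), followed by a disk top-hat; output is clipped at 0.

Thickness: Euclidean distance transform of the binarized image (Otsu on
the background-subtracted SHG by default), padded with background so
border-crossing fibers take no spurious along-border distances; each
8-connected plateau of regional maxima yields one sample at its centroid
(avoiding double counts along ridge lines) with thickness twice the
distance value. Even-width straight ribbons are recovered exactly; odd
widths carry a documented +1 px center-pixel bias; rotated ribbons are
within ±1 px.

Orientation/anisotropy: per 80 µm bin, the mean is subtracted and the bin
replaced by the periodic component of Moisan's periodic-plus-smooth
decomposition (the smooth part solves a discrete Poisson problem driven
by the boundary discrepancies; subtracting it removes the cross-shaped
DFT edge artifact). The power spectrum (DC excluded, bins below 1 % of
peak power zeroed — residual sinc leakage otherwise biases orientation
~4° toward the frequency axes) feeds an inertia tensor over centered
frequency coordinates; the fiber axis is the dominant eigenvector rotated
90°, and anisotropy = 1 − λmin/λmax ∈ [0, 1]. Flat bins report anisotropy
0 with orientation flagged NaN. Bins tile from the origin; partial edge
bins are kept when ≥50 % inside. The edge-artifact suppression is
quantified on the high-frequency half of the frequency axes (|f| > 0.25
of the sampling rate): the decomposition moves boundary-jump energy into
smooth low-frequency content, so near-DC axis bins grow while the long
artifact arms drop by an order of magnitude; measuring all axis bins
would mask the effect.

Spatial context: Voronoi labels assign each thickness sample to its
nearest glomerulus center (ties → lowest seed id); distances are
Euclidean, in µm. Bins above a configurable anisotropy quantile (default
0.9) can be flagged "highly oriented" and excluded, discounting medullary
collagen from glomerulus-centric statistics. Sample count is conserved:
table rows = samples − excluded.

## Phantom generators: what they emulate, and what they do not

All randomness flows from the single integer seed in `PhantomSpec`
through one `numpy.random.default_rng`; identical spec+seed reproduce
phantoms bit-exactly. Noise is additive Gaussian clipped at zero — the
simplest model exposing the SNR behavior of cosine scoring; shot noise,
PSF blur, depth attenuation and anatomical realism (capillary networks,
Bowman's capsule layers) are deliberately absent. Published SRS/TPF noise
characteristics are not available, so phantom noise defaults (σ=0.02
relative on volumes, 0.05 in the noisy spectral tests) are chosen, not
inferred.

* **Reference library**: each subtype owns a distinct primary C-H band
  (cycled over 2850/2880/2940/3011 cm⁻¹, ±4 cm⁻¹ jitter) plus 1–4 weaker
  secondary peaks; draws with pairwise cosine ≥ 0.9 are rejected,
  mirroring the separability of measured lipid-class references
  (triglycerides, ceramide, cholesterol and its esters differ in their
  dominant CH₂/CH₃/=C-H character).
* **Spectral mixtures**: standardized Gaussian-blurred random fields
  pushed through a softmax (temperature 0.3) give smooth compositional
  domains in which one subtype clearly dominates, separated by gradual
  transition zones; abundances sum to 1 on tissue, background is
  zero-signal + noise. Pixels in transition zones have no decisive
  dominant component, so argmax-recovery statistics are reported on
  pixels with ≥60 % dominance.
* **Corpuscle volumes**: a sphere (voxel membership by center-inside) at
  protein level 0.3 (Bowman's space) containing a concentric tuft at 1.0
  sized so its voxel count is the requested fraction of the corpuscle's;
  ground-truth Vv is the voxel-exact ratio and the residual voxelization
  error is reported. `clip_fraction` cuts that fraction of the z-extent
  off at the first plane. A concentric tuft concentrates mesangium at the
  equator — exactly the geometry in which polar 2-D sections
  underestimate Vv and the maximal cross-section overestimates it
  (ratio (r_t/R)² = f^(2/3) at the equator vs f in 3-D), so the phantom
  reproduces the qualitative estimator ordering without claiming
  anatomical realism. Nuclei are non-touching small spheres placed
  rejection-sampled inside the tuft and outside the corpuscle.
* **Fiber fields**: straight ribbons (pixel center within width/2 of the
  axis; even widths anchored on half-pixel offsets so axis-aligned
  ribbons cover exactly w rows/columns). **Redox maps**: FAD = ORR·I,
  NADH = (1−ORR)·I, exactly invertible at zero noise.

Passing tests on these phantoms demonstrates algorithmic correctness
(geometry, estimator consistency, exact ratiometric inversion, Fourier
orientation recovery) — not robustness to optical aberrations, staining
variability, or anatomical heterogeneity of real biopsies.

## Problem sizes and runtime

The validation suite uses 100 µm-radius spheres at 2 µm voxels
(~5×10⁵ corpuscle voxels) for stereology, 50-phantom Monte-Carlo
populations for estimator variance, 64×64×201 hyperspectral mixtures for
PRM, 80×80 bins for orientation analysis, and 76³ volumes with 140 nuclei
for counting — sizes at which every ground-truth comparison is exact or
voxel-limited while the whole suite and the acceptance script each run in
well under a minute on one CPU.

## Known limitations

* The corpuscle segmentation assumes the three-population intensity
  structure (background / Bowman's space / tuft); real biopsies with
  bright tubulointerstitium adjacent to the capsule need the SHG route or
  manual seeds.
* The hemisphere rule's 100 µm fallback radius is a population prior; it
  is wrong for atrophic or hypertrophic glomeruli.
* PRM scores are relative: simplex-normalized similarities are not
  absolute concentrations, and subtypes with highly correlated reference
  spectra (cosine ≳ 0.9) are not reliably separable at the pixel level.
* The PAS chroma mapping and all SRH color constants emulate stain
  semantics; they are not calibrated to any scanner's color profile.
* Orientation analysis reports one dominant axis per bin; crossing fiber
  populations lower anisotropy instead of yielding two axes.
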