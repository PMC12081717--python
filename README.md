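# mmkidney

Label-free multimodal kidney image analysis: penalized reference matching
(PRM) of hyperspectral stimulated Raman scattering (SRS) spectra to lipid
subtypes, ratiometric redox and lipid-saturation biomarkers, stimulated
Raman histology (SRH) pseudo-staining, 3-D glomerular stereology, and
second-harmonic-generation (SHG) collagen fiber morphometry.

## Who this is for

Groups analyzing co-registered label-free microscopy of kidney tissue —
SRS bands in the C-H stretching region (2850 cm⁻¹ lipid CH₂, 2880 cm⁻¹
saturated lipid, 2940 cm⁻¹ protein CH₃, 3011 cm⁻¹ unsaturated =C-H),
two-photon autofluorescence (NADH, flavins), and SHG collagen — who need
reproducible, scriptable versions of the standard analyses:

* **PRM lipid subtyping** — every pixel spectrum I(ν) is scored against a
  reference spectrum r(ν) by penalized, offset-tolerant cosine similarity

  s = max_δ cos(I(ν), r(ν−δ)) · w(δ),  w(δ) = exp(−δ²/2σ²),

  scores are simplex-normalized across subtypes, and relative scores read
  as relative concentrations.
* **Ratiometrics** — normalized optical redox ratio
  ORR = FAD/(NADH+FAD) and lipid saturation = unsat/(sat+unsat), with
  background-excluding, AUC-normalized axial profiles and per-region
  Welch t statistics.
* **SRH** — lipid:protein-ratio nuclei segmentation, LUT blending of the
  protein/lipid channels into H&E-like RGB, a PAS-style L\*a\*b\* chroma
  variant, and histogram specification.
* **Glomerular stereology** — morphological segmentation of the renal
  corpuscle, z-tracking, the hemisphere inclusion rule (discard glomeruli
  with axial thickness < 0.9 × radius; radius defaults to 100 µm when the
  maximal cross-section is terminal), and Vv(Mes/Glom) — the fraction of
  corpuscle volume occupied by tuft — by three estimators (3-D
  hemisphere, 2-D max plane, 2-D single plane), plus 3-D nuclei counts.
* **Collagen morphometry** — distance-transform fiber thickness, per-bin
  DFT orientation/anisotropy with periodic-plus-smooth decomposition
  against FFT edge artifacts, Voronoi partition around glomerulus
  centers, and thickness-vs-distance densities.

Because patient tissue is not available at pixel level, the package ships
a first-class phantom generator (`mmkidney.phantoms`) producing spectral
mixtures, spherical corpuscle volumes, fiber fields and redox maps with
exact ground truth; every analysis stage is validated against it.

## Worked example

Compare the three Vv(Mes/Glom) estimators on a synthetic population of
eight 60 µm glomeruli with a true tuft fraction of 0.6, sectioned at
uniform-random planes:

```python
from mmkidney.pipeline import estimator_report

table, records = estimator_report(8, vv_true=0.6, seed=3, radius_um=60)
print(table.round(4))
```

```
      2d_single_plane  2d_max_plane  3d_hemisphere
mean           0.5234        0.7118         0.6093
sd             0.2584        0.0023         0.0018
se             0.0914        0.0008         0.0006
n              8.0000        8.0000         8.0000
```

The 3-D hemisphere estimator recovers the true fraction (0.6093 vs a
voxel-exact truth of ≈0.607) with the smallest spread; random single
planes scatter widely (SD 0.26) because polar sections miss the tuft; and
the maximal cross-section overestimates (0.71 = 0.6^(2/3)) because a
central tuft fills more of the equatorial disk than of the sphere.

Scoring a noisy spectral-mixture phantom against a three-subtype
reference library and averaging the simplex-normalized similarity over
tissue:

```python
import numpy as np
from mmkidney import phantoms, prm

axis = np.linspace(2700, 3100, 201)
refs = phantoms.make_reference_library(3, axis, seed=7)
spec = phantoms.PhantomSpec(kind="spectral_mixture", shape=(64, 64),
                            noise_sigma=0.05, seed=5)
stack, truth = phantoms.make_spectral_mixture_phantom(refs, spec)
maps = prm.simplex_normalize([prm.prm_score(stack, r) for r in refs])
for m in maps:
    print(m.subtype, round(float(m.scores[truth.tissue_mask].mean()), 4))
```

```
TAG 0.3856
ceramide 0.2821
cholesterol 0.3323
```

These per-subtype mean scores track the generating abundance fields; the
per-pixel argmax recovers the dominant subtype at >99 % of decisively
mixed tissue pixels at zero noise.

A `mmkidney` command-line tool exposes the same stages
(`mmkidney phantom`, `mmkidney run config.yaml`, `mmkidney prm score`,
`mmkidney ratios orr|profile`, `mmkidney srh render`,
`mmkidney glom segment|vv`, `mmkidney collagen thickness|anisotropy`).

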