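"""Synthetic phantoms with exact ground truth.

Patient kidney tissue is not available at pixel level, so every analysis
stage in this package is validated against phantoms that emulate the
relevant physics at known ground truth:

* noisy non-negative mixtures of a small lipid reference-spectrum library
  over the 2700-3100 cm^-1 C-H stretching window (hyperspectral SRS);
* spherical renal-corpuscle volumes with a concentric tuft, a low-intensity
  Bowman's space shell, and non-touching nuclei at known counts;
* straight collagen ribbons of known width and orientation (SHG);
* NADH/FAD channel pairs generated from a known optical-redox-ratio map.

All randomness flows from the single integer seed in :class:`PhantomSpec`
through one ``numpy.random.default_rng`` generator, so identical spec +
seed reproduce phantoms bit-exactly. Noise is additive Gaussian clipped at
zero; intensities are always non-negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .datatypes import HyperspectralStack, MultimodalVolume, ReferenceSpectrum, common_axis
from .exceptions import GeometryError, InvalidAxisError

_SUBTYPE_NAMES = (
    "TAG",
    "ceramide",
    "cholesterol",
    "cholesteryl_ester",
    "sphingomyelin",
    "phosphatidylcholine",
)

#: major C-H stretching band centers (cm^-1): CH2 symmetric (lipid), CH2
#: asymmetric (saturated lipid), CH3 (protein), =C-H (unsaturated lipid)
CH_BAND_CENTERS = (2850.0, 2880.0, 2940.0, 3011.0)


@dataclass
class PhantomSpec:
    """Geometry, sampling and noise description of one phantom."""

    kind: str
    shape: Tuple[int, ...]
    pixel_size_um: float = 1.0
    z_spacing_um: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    _KINDS = ("spectral_mixture", "glomerulus_volume", "fiber_field", "redox_map")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        self.shape = tuple(int(s) for s in self.shape)
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be strictly positive in all dimensions")
        if self.pixel_size_um <= 0 or self.z_spacing_um <= 0:
            raise ValueError("pixel sizes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Known truth accompanying a phantom; fields populated per phantom kind."""

    abundance_maps: Optional[Dict[str, np.ndarray]] = None
    tissue_mask: Optional[np.ndarray] = None
    clean_stack: Optional[np.ndarray] = None
    vv_true: Optional[float] = None
    voxelization_error: Optional[float] = None
    corpuscle_mask: Optional[np.ndarray] = None
    tuft_mask: Optional[np.ndarray] = None
    expected_retained: Optional[bool] = None
    center_um: Optional[Tuple[float, float, float]] = None
    radius_um: Optional[float] = None
    fiber_widths_px: List[float] = field(default_factory=list)
    fiber_orientations_deg: List[float] = field(default_factory=list)
    fiber_masks: List[np.ndarray] = field(default_factory=list)
    orr_map: Optional[np.ndarray] = None
    nuclei_count_by_region: Optional[Dict[str, int]] = None


# ---------------------------------------------------------------------------
# reference spectra
# ---------------------------------------------------------------------------

def make_reference_library(
    n_subtypes: int, wavenumber_axis: np.ndarray, seed: int = 0
) -> List[ReferenceSpectrum]:
    """Generate synthetic lipid-subtype reference spectra.

    Each spectrum is a sum of 2-5 Gaussian peaks: a dominant peak at one
    of the four C-H band positions (2850, 2880, 2940, 3011 cm^-1, cycled
    across subtypes so each subtype owns a distinct primary band, the way
    real lipid classes differ in their dominant CH2/CH3/=C-H character)
    plus weaker secondary peaks at the other bands, all with center
    jitter, max-normalized to 1 and mutually distinct (pairwise cosine
    < 0.99). These stand in for spontaneous-Raman reference spectra of
    pure lipid subtypes (TAG, ceramide, cholesterol, cholesteryl ester,
    ...).
    """
    axis = np.asarray(wavenumber_axis, dtype=float)
    if axis.ndim != 1 or not np.all(np.diff(axis) > 0):
        raise InvalidAxisError("wavenumber axis must be 1-D and strictly increasing")
    if axis[0] > 2700.0 or axis[-1] < 3100.0:
        raise InvalidAxisError("axis must cover the C-H window [2700, 3100] cm^-1")
    if n_subtypes < 2:
        raise ValueError("need at least 2 subtypes for reference matching")

    rng = np.random.default_rng(seed)
    refs: List[ReferenceSpectrum] = []
    spectra: List[np.ndarray] = []
    attempts = 0
    while len(refs) < n_subtypes:
        attempts += 1
        if attempts > 100 * n_subtypes:  # pragma: no cover - defensive
            raise RuntimeError("could not draw a distinct reference library")
        primary = CH_BAND_CENTERS[len(refs) % len(CH_BAND_CENTERS)]
        n_minor = int(rng.integers(1, 5))
        others = [c for c in CH_BAND_CENTERS if c != primary]
        centers = np.concatenate(
            [[primary], rng.choice(others, size=n_minor, replace=True)]
        )
        centers = centers + rng.normal(0.0, 4.0, size=n_minor + 1)
        widths = rng.uniform(10.0, 25.0, size=n_minor + 1)
        amps = np.concatenate([[1.0], rng.uniform(0.1, 0.45, size=n_minor)])
        y = np.zeros_like(axis)
        for c, w, a in zip(centers, widths, amps):
            y += a * np.exp(-0.5 * ((axis - c) / w) ** 2)
        y /= y.max()
        # reject draws that resemble an existing subtype; 0.9 keeps the
        # library about as separable as measured lipid-class references
        if any(_cosine(y, other) >= 0.9 for other in spectra):
            continue
        idx = len(refs)
        name = (
            _SUBTYPE_NAMES[idx]
            if idx < len(_SUBTYPE_NAMES)
            else f"subtype_{idx}"
        )
        refs.append(ReferenceSpectrum(name=name, wavenumbers=axis.copy(), intensities=y))
        spectra.append(y)
    return refs


def _cosine(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# spectral mixture phantom
# ---------------------------------------------------------------------------

def make_spectral_mixture_phantom(
    refs: Sequence[ReferenceSpectrum],
    spec: PhantomSpec,
    abundance_maps: Optional[np.ndarray] = None,
    tissue_mask: Optional[np.ndarray] = None,
    temperature: float = 0.3,
) -> Tuple[HyperspectralStack, GroundTruth]:
    """Hyperspectral phantom: per-pixel noisy non-negative mixture of references.

    Each tissue pixel's spectrum is ``sum_k a_k(y, x) * ref_k`` with
    ``a_k >= 0`` and ``sum_k a_k = 1``, plus additive Gaussian noise clipped
    at zero. Background pixels carry zero signal plus noise. By default the
    abundance maps come from standardized Gaussian-blurred random fields
    pushed through a softmax at the given ``temperature``: smooth patches
    in which one subtype clearly dominates, separated by gradual
    transition zones (tissue-like compositional domains rather than
    uniform blends; smaller temperature means sharper domains). Pass
    ``abundance_maps`` of shape ``(n_refs, y, x)`` to override.
    """
    if len(refs) < 2:
        raise ValueError("need at least 2 references")
    axis = common_axis(list(refs))
    ny, nx = spec.shape[-2], spec.shape[-1]
    rng = spec.rng()

    if tissue_mask is None:
        yy, xx = np.mgrid[0:ny, 0:nx]
        cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
        tissue_mask = ((yy - cy) ** 2 + (xx - cx) ** 2) <= (0.45 * min(ny, nx)) ** 2
    tissue_mask = np.asarray(tissue_mask, dtype=bool)

    if abundance_maps is None:
        fields = rng.standard_normal((len(refs), ny, nx))
        fields = np.stack(
            [ndimage.gaussian_filter(f, sigma=min(ny, nx) / 10.0) for f in fields]
        )
        fields = (fields - fields.mean(axis=(1, 2), keepdims=True)) / fields.std(
            axis=(1, 2), keepdims=True
        )
        fields = np.exp(fields / temperature)
        abundance_maps = fields / fields.sum(axis=0, keepdims=True)
    else:
        abundance_maps = np.asarray(abundance_maps, dtype=float)
        if abundance_maps.shape != (len(refs), ny, nx):
            raise ValueError("abundance_maps must have shape (n_refs, y, x)")
    abundance_maps = np.where(tissue_mask[None], abundance_maps, 0.0)

    ref_matrix = np.stack([r.intensities for r in refs])  # (k, n)
    clean = np.einsum("kyx,kn->yxn", abundance_maps, ref_matrix)
    noisy = clean + rng.normal(0.0, spec.noise_sigma, size=clean.shape) if spec.noise_sigma > 0 else clean.copy()
    noisy = np.clip(noisy, 0.0, None)

    stack = HyperspectralStack(
        data=noisy, wavenumbers=axis.copy(), pixel_size_um=spec.pixel_size_um
    )
    truth = GroundTruth(
        abundance_maps={r.name: abundance_maps[k] for k, r in enumerate(refs)},
        tissue_mask=tissue_mask,
        clean_stack=clean,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# glomerulus volume phantom
# ---------------------------------------------------------------------------

#: protein-channel intensity levels: the tuft (mesangial cells + matrix,
#: endothelium, podocytes) is protein-rich; Bowman's space is nearly empty.
TUFT_INTENSITY = 1.0
BOWMAN_INTENSITY = 0.3
NUCLEUS_INTENSITY = 1.0


def make_glomerulus_volume_phantom(
    spec: PhantomSpec,
    radius_um: float = 100.0,
    mes_fraction: float = 0.6,
    clip_fraction: float = 0.0,
    n_glomerular_nuclei: int = 0,
    n_cortical_nuclei: int = 0,
    nucleus_radius_px: float = 2.0,
) -> Tuple[MultimodalVolume, GroundTruth]:
    """Spherical renal-corpuscle phantom with a concentric tuft.

    The corpuscle is a sphere of ``radius_um``; the tuft is a concentric
    sphere sized so its voxel count is ``mes_fraction`` of the corpuscle's
    (the residual voxelization error is reported in the ground truth, whose
    ``vv_true`` is the voxel-exact ratio). ``clip_fraction`` cuts that
    fraction of the sphere's z-extent off at the first plane, emulating a
    glomerulus only partially contained in the imaging volume. A voxel
    belongs to a sphere iff its center lies inside.

    Optional nuclei are non-touching small spheres placed inside the tuft
    (glomerular) and outside the corpuscle (cortical) at known counts.
    """
    if not (0.0 < mes_fraction <= 1.0):
        raise ValueError("mes_fraction must be in (0, 1]")
    if not (0.0 <= clip_fraction < 1.0):
        raise ValueError("clip_fraction must be in [0, 1)")
    if len(spec.shape) != 3:
        raise ValueError("glomerulus phantom requires a 3-D shape (z, y, x)")
    nz, ny, nx = spec.shape
    dz, dp = spec.z_spacing_um, spec.pixel_size_um
    rng = spec.rng()

    R = float(radius_um)
    cy_um, cx_um = (ny - 1) / 2.0 * dp, (nx - 1) / 2.0 * dp
    if 2 * R > min((ny - 1) * dp, (nx - 1) * dp):
        raise GeometryError("sphere diameter exceeds in-plane extent")
    # z center: clip_fraction of the sphere's z-extent (diameter) lies below
    # the first plane.
    cz_um = R * (1.0 - 2.0 * clip_fraction) if clip_fraction > 0 else (nz - 1) / 2.0 * dz
    if cz_um + R > (nz - 1) * dz + 1e-9:
        raise GeometryError("sphere extends beyond the last z-plane")
    if clip_fraction == 0 and cz_um - R < -1e-9:
        raise GeometryError("full sphere does not fit along z")

    zc = np.arange(nz) * dz
    yc = np.arange(ny) * dp
    xc = np.arange(nx) * dp
    d2 = (
        (zc - cz_um)[:, None, None] ** 2
        + (yc - cy_um)[None, :, None] ** 2
        + (xc - cx_um)[None, None, :] ** 2
    )
    corpuscle = d2 <= R ** 2
    r_tuft = R * mes_fraction ** (1.0 / 3.0)
    tuft = d2 <= r_tuft ** 2

    n_corp = int(corpuscle.sum())
    if n_corp == 0:
        raise GeometryError("corpuscle contains no voxel centers")
    vv_true = float(tuft.sum()) / n_corp

    protein = np.zeros(spec.shape)
    protein[corpuscle] = BOWMAN_INTENSITY
    protein[tuft] = TUFT_INTENSITY

    nuclei = np.zeros(spec.shape)
    counts = {"glomerulus": 0, "cortex": 0}
    centers: List[np.ndarray] = []
    r_n = nucleus_radius_px

    def _place(n_wanted: int, inside_tuft: bool, key: str) -> None:
        tries = 0
        while counts[key] < n_wanted:
            tries += 1
            if tries > 20000:
                raise GeometryError(f"could not place {n_wanted} {key} nuclei")
            p = np.array(
                [
                    rng.uniform(r_n * dz, (nz - 1 - r_n) * dz),
                    rng.uniform(r_n * dp, (ny - 1 - r_n) * dp),
                    rng.uniform(r_n * dp, (nx - 1 - r_n) * dp),
                ]
            )
            d_center = math.sqrt(
                (p[0] - cz_um) ** 2 + (p[1] - cy_um) ** 2 + (p[2] - cx_um) ** 2
            )
            margin = (r_n + 1.5) * max(dz, dp)
            if inside_tuft and d_center > r_tuft - margin:
                continue
            if not inside_tuft and d_center < R + margin:
                continue
            if any(np.linalg.norm(p - q) < 2.0 * margin for q in centers):
                continue
            dd2 = (
                (zc - p[0])[:, None, None] ** 2
                + (yc - p[1])[None, :, None] ** 2
                + (xc - p[2])[None, None, :] ** 2
            )
            nuclei[dd2 <= (r_n * dp) ** 2] = NUCLEUS_INTENSITY
            centers.append(p)
            counts[key] += 1

    if n_glomerular_nuclei:
        _place(n_glomerular_nuclei, True, "glomerulus")
    if n_cortical_nuclei:
        _place(n_cortical_nuclei, False, "cortex")

    if spec.noise_sigma > 0:
        protein = np.clip(
            protein + rng.normal(0.0, spec.noise_sigma, protein.shape), 0.0, None
        )

    # retention expectation under the hemisphere rule: thickness is the
    # z-extent from the max-area plane to the vanishing plane; when the
    # equator is cut off, the max area sits at the first plane and the
    # radius falls back to the 100 um default.
    if clip_fraction < 0.5:
        thickness_um = R
        radius_for_rule = R
    else:
        thickness_um = 2.0 * R * (1.0 - clip_fraction)
        radius_for_rule = 100.0
    expected_retained = thickness_um >= 0.9 * radius_for_rule

    volume = MultimodalVolume(
        channels={"protein_2940": protein, "nuclei": nuclei},
        z_spacing_um=dz,
        pixel_size_um=dp,
    )
    truth = GroundTruth(
        vv_true=vv_true,
        voxelization_error=abs(vv_true - mes_fraction),
        corpuscle_mask=corpuscle,
        tuft_mask=tuft,
        expected_retained=bool(expected_retained),
        center_um=(float(cz_um), float(cy_um), float(cx_um)),
        radius_um=R,
        nuclei_count_by_region=counts,
    )
    return volume, truth


# ---------------------------------------------------------------------------
# fiber phantom
# ---------------------------------------------------------------------------

def make_fiber_phantom(
    spec: PhantomSpec,
    widths_px: Sequence[float],
    orientations_deg: Sequence[float],
    anchors: Optional[Sequence[Tuple[float, float]]] = None,
    lengths_px: Optional[Sequence[float]] = None,
) -> Tuple[np.ndarray, GroundTruth]:
    """SHG phantom: straight ribbons of stated width and orientation.

    Orientation is the fiber-axis angle in degrees, in [0, 180), measured
    from the +x (column) axis toward +y rows mod 180 (so 0 is horizontal,
    90 vertical). A pixel is foreground when its center lies within
    ``width/2`` of the ribbon axis; even widths are anchored on half-pixel
    offsets so an axis-aligned ribbon of width w covers exactly w rows or
    columns. Overlapping fibers are allowed.
    """
    if len(widths_px) != len(orientations_deg):
        raise ValueError("widths and orientations must have equal length")
    for w in widths_px:
        if w < 1:
            raise ValueError("fiber widths must be >= 1 px")
    for o in orientations_deg:
        if not (0.0 <= o < 180.0):
            raise ValueError("orientations must lie in [0, 180)")
    ny, nx = spec.shape[-2], spec.shape[-1]
    rng = spec.rng()
    n_fib = len(widths_px)

    if anchors is None:
        # integer anchors keep odd axis-aligned widths exact; even widths
        # get a half-pixel offset below
        if n_fib == 1:
            anchors = [(float(ny // 2), float(nx // 2))]
        else:
            anchors = [
                (
                    float(round((i + 1) * ny / (n_fib + 1.0))),
                    float(round((i + 1) * nx / (n_fib + 1.0))),
                )
                for i in range(n_fib)
            ]
    if lengths_px is None:
        lengths_px = [math.hypot(ny, nx) * 2.0] * n_fib  # span the image

    yy, xx = np.mgrid[0:ny, 0:nx].astype(float)
    image = np.zeros((ny, nx))
    masks: List[np.ndarray] = []
    for (ay, ax_), w, theta, L in zip(anchors, widths_px, orientations_deg, lengths_px):
        t = math.radians(theta)
        d = np.array([math.sin(t), math.cos(t)])  # (dy, dx) along the fiber
        n = np.array([-d[1], d[0]])  # unit normal
        ay_, ax2 = ay, ax_
        if int(round(w)) % 2 == 0:
            # half-pixel anchor offset keeps axis-aligned even widths exact
            ay_, ax2 = ay + 0.5 * n[0], ax_ + 0.5 * n[1]
        py, px = yy - ay_, xx - ax2
        dperp = np.abs(py * n[0] + px * n[1])
        dalong = np.abs(py * d[0] + px * d[1])
        mask = (dperp < w / 2.0) & (dalong <= L / 2.0)
        image[mask] = 1.0
        masks.append(mask)

    if spec.noise_sigma > 0:
        image = np.clip(image + rng.normal(0.0, spec.noise_sigma, image.shape), 0.0, None)

    truth = GroundTruth(
        fiber_widths_px=list(widths_px),
        fiber_orientations_deg=list(orientations_deg),
        fiber_masks=masks,
    )
    return image, truth


# ---------------------------------------------------------------------------
# redox phantom
# ---------------------------------------------------------------------------

def make_redox_phantom(
    spec: PhantomSpec,
    orr_map: np.ndarray,
    total_intensity: float = 100.0,
) -> Tuple[np.ndarray, np.ndarray, GroundTruth]:
    """NADH/FAD image pair with a known optical-redox-ratio map.

    ``FAD = orr_map * total_intensity`` and ``NADH = (1 - orr_map) *
    total_intensity``, so ``FAD / (NADH + FAD)`` recovers ``orr_map``
    exactly at zero noise. ``noise_sigma`` is relative to unit signal and
    scales with ``total_intensity``.
    """
    orr = np.asarray(orr_map, dtype=float)
    if orr.min() < 0.0 or orr.max() > 1.0:
        raise ValueError("orr_map values must lie in [0, 1]")
    if total_intensity <= 0:
        raise ValueError("total_intensity must be positive")
    rng = spec.rng()
    fad = orr * total_intensity
    nadh = (1.0 - orr) * total_intensity
    if spec.noise_sigma > 0:
        sig = spec.noise_sigma * total_intensity
        fad = np.clip(fad + rng.normal(0.0, sig, fad.shape), 0.0, None)
        nadh = np.clip(nadh + rng.normal(0.0, sig, nadh.shape), 0.0, None)
    truth = GroundTruth(orr_map=orr.copy())
    return nadh, fad, truth
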