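"""Glomerulus detection, z-tracking, and mesangial volume-fraction estimation.

The renal corpuscle (the "glomerulus" mask) is the outer structure
including Bowman's space and the parietal epithelium; the mesangium (tuft:
mesangial cells and matrix, capillary endothelium, podocytes) is the
protein-rich interior obtained by intersecting the corpuscle mask with a
protein threshold. Vv(Mes/Glom) is the fraction of corpuscle volume
occupied by tuft, estimated three ways:

* ``3d_hemisphere`` - sum of mesangium pixels over the planes between the
  maximal cross-section and the vanishing plane, divided by the matching
  corpuscle sum; glomeruli whose axial thickness is below 90 % of their
  radius (less than a hemisphere in the volume) are discarded;
* ``2d_max_plane`` - the pixel ratio at each glomerulus' largest
  cross-section;
* ``2d_single_plane`` - the pixel ratio at one fixed plane, mimicking a
  traditional 2-D section.

Connectivity is 8 in 2-D and 26 in 3-D throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import median as median_filter
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import (
    closing,
    dilation,
    disk,
    erosion,
    local_maxima,
    opening,
    reconstruction,
    white_tophat,
)
from skimage.segmentation import watershed

from .datatypes import MultimodalVolume

STRUCT_26 = np.ones((3, 3, 3), dtype=bool)
#: fallback radius (um) when no interior maximal cross-section exists
DEFAULT_RADIUS_UM = 100.0
#: retention rule: axial thickness must reach this fraction of the radius
HEMISPHERE_FRACTION = 0.9
#: a plane "vanishes" when its area drops below this fraction of the max
VANISH_AREA_FRACTION = 0.01


@dataclass
class LabeledRegions:
    """Labeled segmentation output; region ids are contiguous 1..n."""

    labels: np.ndarray
    n_regions: int
    provenance: str

    def __post_init__(self) -> None:
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")


@dataclass
class GlomerulusRecord:
    """Per-glomerulus tracking result and Vv estimates."""

    id: int
    plane_areas_px: Dict[int, int]
    mes_areas_px: Dict[int, int]
    centroid_um: Tuple[float, float, float]
    max_plane: int
    vanish_plane: Optional[int]
    thickness_um: float
    radius_um: float
    retained: bool
    clipped: bool
    vv_3d: float
    vv_2d_single: float
    vv_2d_max: float
    n_volume_planes: int
    pixel_size_um: float = 1.0
    max_plane_mask: Optional[np.ndarray] = field(default=None, repr=False)


def _relabel(mask_or_labels: np.ndarray, provenance: str) -> LabeledRegions:
    labels, n = sk_label(mask_or_labels, connectivity=2, return_num=True)
    return LabeledRegions(labels=labels, n_regions=n, provenance=provenance)


def _shape_filter(
    labels: np.ndarray,
    pixel_size_um: float,
    area_range_um2: Tuple[float, float],
    solidity_min: float = 0.0,
    circularity_min: float = 0.0,
) -> np.ndarray:
    out = np.zeros_like(labels)
    next_id = 1
    for prop in regionprops(labels):
        area_um2 = prop.area * pixel_size_um ** 2
        if not (area_range_um2[0] <= area_um2 <= area_range_um2[1]):
            continue
        if solidity_min > 0 and prop.solidity < solidity_min:
            continue
        if circularity_min > 0:
            circ = 4.0 * np.pi * prop.area / max(prop.perimeter, 1e-9) ** 2
            if circ < circularity_min:
                continue
        out[labels == prop.label] = next_id
        next_id += 1
    return out


def segment_glomeruli_shg(
    shg: np.ndarray,
    se_radius_px: int,
    iterate: bool = False,
    median_radius_px: int = 2,
    pixel_size_um: float = 1.0,
    area_range_um2: Tuple[float, float] = (3_000.0, 80_000.0),
    solidity_min: float = 0.7,
    exclude_border: bool = True,
) -> LabeledRegions:
    """Segment glomeruli (SHG-dark, fiber-ringed objects) from a collagen image.

    Pipeline: disk top-hat background subtraction (``se_radius_px`` should
    be at least twice the largest visible fiber diameter); median filter;
    dilation to form the gradient wireframe; inversion; erosion +
    morphological reconstruction; regional-maxima object seeds; binary
    opening/closing of the seeds; then each seed is grown (geodesic
    dilation via watershed on the wireframe) until it reaches the fiber
    wireframe or another object, and finally size/solidity filtered.
    Glomeruli and tubule lumens both survive the morphology; the shape
    filter separates them.
    """
    shg = np.asarray(shg, float)
    if shg.size == 0 or shg.max() == 0:
        return LabeledRegions(np.zeros(shg.shape, dtype=int), 0, "shg_pipeline")
    if se_radius_px < 2:
        warnings.warn("se_radius_px < 2: structuring element may be too small")

    tophat = white_tophat(shg, disk(se_radius_px))
    med = median_filter(tophat, disk(median_radius_px))
    wireframe = dilation(med, disk(2))
    inverted = med.max() - med
    eroded = erosion(inverted, disk(max(se_radius_px // 2, 1)))
    recon = reconstruction(eroded, inverted)

    seeds = local_maxima(recon, connectivity=2)
    seeds = opening(seeds, disk(1))
    seeds = closing(seeds, disk(2))
    if iterate:
        # second pass: merge missed seeds found on the wireframe-augmented
        # reconstruction and re-solidify
        extra = local_maxima(recon + wireframe.max() - wireframe, connectivity=2)
        seeds = closing(seeds | opening(extra, disk(1)), disk(2))
    markers = sk_label(seeds, connectivity=2)
    if markers.max() == 0:
        return LabeledRegions(np.zeros(shg.shape, dtype=int), 0, "shg_pipeline")

    fiber_level = threshold_otsu(med) if np.ptp(med) > 0 else np.inf
    grow_mask = med < fiber_level
    grown = watershed(wireframe, markers=markers, mask=grow_mask)
    if exclude_border:
        # open regions reaching the image edge are background pockets or
        # clipped objects, not fully ringed glomeruli
        edge_labels = np.unique(
            np.concatenate(
                [grown[0, :], grown[-1, :], grown[:, 0], grown[:, -1]]
            )
        )
        grown = np.where(np.isin(grown, edge_labels), 0, grown)
    filtered = _shape_filter(
        grown, pixel_size_um, area_range_um2, solidity_min=solidity_min
    )
    return _relabel(filtered, "shg_pipeline")


def segment_glomeruli_openclose(
    protein: np.ndarray,
    r_open: int = 2,
    r_close: int = 2,
    pixel_size_um: float = 1.0,
    area_range_um2: Tuple[float, float] = (0.0, np.inf),
    circularity_min: float = 0.0,
    classes: int = 2,
) -> LabeledRegions:
    """Rapid glomerulus identification by opening-closing and Otsu.

    Grey opening (disk ``r_open``) then closing (disk ``r_close``), Otsu
    binarization (``classes=3`` switches to the lowest multi-Otsu
    threshold, which keeps the dim Bowman's-space shell in the foreground
    when background, Bowman's space and tuft form three intensity
    populations), hole filling, labeling, and a size/circularity filter.
    ``r_open = r_close = 0`` reduces to plain Otsu components.
    """
    img = np.asarray(protein, float)
    if img.max() == img.min():
        return LabeledRegions(np.zeros(img.shape, dtype=int), 0, "open_close_pipeline")
    if r_open > 0:
        img = opening(img, disk(r_open))
    if r_close > 0:
        img = closing(img, disk(r_close))
    if classes >= 3:
        try:
            thresh = threshold_multiotsu(img, classes=classes)[0]
        except ValueError:
            thresh = threshold_otsu(img)
    else:
        thresh = threshold_otsu(img)
    mask = ndimage.binary_fill_holes(img > thresh)
    labels = sk_label(mask, connectivity=2)
    filtered = _shape_filter(
        labels, pixel_size_um, area_range_um2, circularity_min=circularity_min
    )
    return _relabel(filtered, "open_close_pipeline")


def segment_mesangium(
    glom_mask: np.ndarray,
    protein: np.ndarray,
    method: str = "otsu",
    threshold: Optional[float] = None,
) -> np.ndarray:
    """Mesangium mask: glomerulus mask intersected with a protein threshold.

    Intersecting with the protein image removes the Bowman's-space
    background. ``method='otsu'`` computes the threshold within the
    glomerulus; ``method='fixed'`` uses the supplied ``threshold``.
    """
    glom_mask = np.asarray(glom_mask, bool)
    protein = np.asarray(protein, float)
    if glom_mask.shape != protein.shape:
        raise ValueError("mask and image shapes differ")
    if not glom_mask.any():
        return np.zeros_like(glom_mask)
    if method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        t = threshold
    elif method == "otsu":
        inside = protein[glom_mask]
        if np.ptp(inside) == 0:
            # uniform interior: everything at or above the level is tuft
            return glom_mask & (protein >= inside.min()) if inside.min() > 0 else np.zeros_like(glom_mask)
        t = threshold_otsu(inside)
    else:
        raise ValueError(f"unknown method {method!r}")
    return glom_mask & (protein >= t)


# ---------------------------------------------------------------------------
# z-tracking
# ---------------------------------------------------------------------------

def _corpuscle_plane_mask(
    plane: np.ndarray, t_low: float, r_open: int, r_close: int
) -> np.ndarray:
    mask = plane > t_low
    if r_open > 0:
        mask = opening(mask, disk(r_open))
    if r_close > 0:
        mask = closing(mask, disk(r_close))
    return ndimage.binary_fill_holes(mask)


def volume_thresholds(protein_volume: np.ndarray) -> Tuple[float, float]:
    """Global (corpuscle, mesangium) thresholds from a 3-class multi-Otsu."""
    try:
        t_low, t_high = threshold_multiotsu(protein_volume, classes=3)
    except ValueError:
        t = threshold_otsu(protein_volume)
        t_low = t_high = t
    return float(t_low), float(t_high)


def track_glomerulus(
    volume: MultimodalVolume,
    seed_yx: Tuple[float, float],
    seed_plane: Optional[int] = None,
    glom_id: int = 1,
    r_open: int = 2,
    r_close: int = 2,
    single_plane: Optional[int] = None,
    protein_channel: str = "protein_2940",
) -> GlomerulusRecord:
    """Track one glomerulus through z and compute its Vv estimates.

    Starting from the plane/position seed, the corpuscle region is linked
    across planes (the centroid of plane k must fall inside the region of
    plane k+1; ties resolve by largest overlap). Per-plane corpuscle and
    mesangium areas are recorded between the maximal cross-section and the
    vanishing plane (area below 1 % of the maximum); the glomerular
    thickness is the axial distance between those planes. A region
    touching the x/y image border is flagged clipped. ``single_plane``
    selects the plane used for the traditional 2-D single-plane estimate
    (default: the seed plane).
    """
    protein = volume[protein_channel]
    nz = protein.shape[0]
    if nz < 3:
        raise ValueError("z-tracking needs at least 3 planes")
    t_low, t_high = volume_thresholds(protein)

    if seed_plane is None:
        seed_plane = nz // 2
    seed_plane = int(seed_plane)

    # link the seed region across planes
    masks: List[Optional[np.ndarray]] = [None] * nz
    areas = np.zeros(nz, dtype=int)

    def _region_at(z: int, point_yx: Tuple[float, float], prev_mask) -> Optional[np.ndarray]:
        plane_mask = _corpuscle_plane_mask(protein[z], t_low, r_open, r_close)
        labels = sk_label(plane_mask, connectivity=2)
        if labels.max() == 0:
            return None
        iy, ix = int(round(point_yx[0])), int(round(point_yx[1]))
        lab = 0
        if 0 <= iy < labels.shape[0] and 0 <= ix < labels.shape[1]:
            lab = labels[iy, ix]
        if lab == 0 and prev_mask is not None:
            # centroid fell outside: take the label with the largest overlap
            overlap = np.bincount(labels[prev_mask], minlength=labels.max() + 1)
            overlap[0] = 0
            if overlap.max() == 0:
                return None
            lab = int(overlap.argmax())
        if lab == 0:
            return None
        return labels == lab

    seed_mask = _region_at(seed_plane, seed_yx, None)
    if seed_mask is None:
        raise ValueError("no corpuscle region found at the seed position")
    masks[seed_plane] = seed_mask
    areas[seed_plane] = int(seed_mask.sum())

    for direction in (1, -1):
        prev = seed_mask
        z = seed_plane + direction
        while 0 <= z < nz and prev is not None:
            cy, cx = ndimage.center_of_mass(prev)
            cur = _region_at(z, (cy, cx), prev)
            if cur is None:
                break
            masks[z] = cur
            areas[z] = int(cur.sum())
            prev = cur
            z += direction

    tracked = [z for z in range(nz) if areas[z] > 0]
    max_plane = int(max(tracked, key=lambda z: areas[z]))
    max_area = areas[max_plane]

    def _find_vanish(direction: int) -> Tuple[Optional[int], int]:
        """Return (vanish plane or None, extent in planes) in one direction."""
        z = max_plane + direction
        while 0 <= z < nz:
            if areas[z] < VANISH_AREA_FRACTION * max_area:
                return z, abs(z - max_plane)
            z += direction
        return None, abs((nz - 1 if direction > 0 else 0) - max_plane)

    v_up, ext_up = _find_vanish(+1)
    v_dn, ext_dn = _find_vanish(-1)
    candidates = [(v, e) for v, e in ((v_up, ext_up), (v_dn, ext_dn)) if v is not None]
    if candidates:
        vanish_plane, extent = max(candidates, key=lambda t: t[1])
    else:
        # no vanishing point inside the volume: use the longer extent to a
        # volume boundary
        vanish_plane, extent = (None, max(ext_up, ext_dn))
    thickness_um = extent * volume.z_spacing_um

    lo, hi = sorted((max_plane, vanish_plane if vanish_plane is not None else (
        max_plane + extent if ext_up >= ext_dn else max_plane - extent)))
    analyzed = [z for z in range(lo, hi + 1) if areas[z] > 0]

    mes_areas: Dict[int, int] = {}
    plane_areas: Dict[int, int] = {}
    clipped = False
    for z in analyzed:
        m = masks[z]
        plane_areas[z] = int(areas[z])
        mes = segment_mesangium(m, protein[z], method="fixed", threshold=t_high)
        mes_areas[z] = int(mes.sum())
        if (
            m[0, :].any() or m[-1, :].any() or m[:, 0].any() or m[:, -1].any()
        ):
            clipped = True

    czs = [z * volume.z_spacing_um * areas[z] for z in analyzed]
    cy, cx = ndimage.center_of_mass(masks[max_plane])
    centroid = (
        float(sum(czs) / max(sum(areas[z] for z in analyzed), 1)),
        float(cy * volume.pixel_size_um),
        float(cx * volume.pixel_size_um),
    )

    record = GlomerulusRecord(
        id=glom_id,
        plane_areas_px=plane_areas,
        mes_areas_px=mes_areas,
        centroid_um=centroid,
        max_plane=max_plane,
        vanish_plane=vanish_plane,
        thickness_um=float(thickness_um),
        radius_um=0.0,
        retained=False,
        clipped=clipped,
        vv_3d=float("nan"),
        vv_2d_single=float("nan"),
        vv_2d_max=float("nan"),
        n_volume_planes=nz,
        pixel_size_um=volume.pixel_size_um,
        max_plane_mask=masks[max_plane],
    )
    record.radius_um = estimate_radius(record)
    record.retained = hemisphere_filter(record)

    total_corp = sum(plane_areas.values())
    total_mes = sum(mes_areas.values())
    record.vv_3d = total_mes / total_corp if total_corp else float("nan")
    record.vv_2d_max = (
        mes_areas[max_plane] / plane_areas[max_plane]
        if plane_areas.get(max_plane)
        else float("nan")
    )
    sp = seed_plane if single_plane is None else int(single_plane)
    if areas[sp] > 0:
        mes_sp = segment_mesangium(masks[sp], protein[sp], "fixed", t_high)
        record.vv_2d_single = float(mes_sp.sum()) / areas[sp]
    return record


def estimate_radius(record: GlomerulusRecord) -> float:
    """Mean centroid-to-boundary distance at the maximal cross-section, in um.

    If the largest area occurs at the first or last plane of the volume no
    interior maximum is defined, and the radius falls back to the 100 um
    default.
    """
    if record.max_plane in (0, record.n_volume_planes - 1):
        return DEFAULT_RADIUS_UM
    mask = record.max_plane_mask
    if mask is None or not mask.any():
        return DEFAULT_RADIUS_UM
    return radius_from_mask(mask, record.pixel_size_um)


def radius_from_mask(mask: np.ndarray, pixel_size_um: float = 1.0) -> float:
    """Mean boundary-pixel distance to the mask centroid, in microns."""
    mask = np.asarray(mask, bool)
    boundary = mask & ~ndimage.binary_erosion(mask)
    cy, cx = ndimage.center_of_mass(mask)
    ys, xs = np.nonzero(boundary)
    dists = np.hypot(ys - cy, xs - cx)
    return float(dists.mean() * pixel_size_um)


def hemisphere_filter(record: GlomerulusRecord) -> bool:
    """Retain a glomerulus iff its thickness reaches 90 % of its radius.

    The boundary is inclusive: thickness exactly at 0.9 x radius is
    retained (only those *below* the threshold are discarded).
    """
    return record.thickness_um >= HEMISPHERE_FRACTION * record.radius_um


def vv_mes_glom(
    records: Sequence[GlomerulusRecord], method: str = "3d_hemisphere"
) -> Tuple[pd.Series, pd.Series]:
    """Per-glomerulus Vv(Mes/Glom) values and their group summary.

    ``3d_hemisphere`` uses retained, unclipped records only;
    ``2d_single_plane`` and ``2d_max_plane`` use unclipped records. Returns
    (per-glomerulus values indexed by id, summary with mean/sd/se/n).
    """
    if method == "3d_hemisphere":
        usable = [r for r in records if r.retained and not r.clipped]
        if not usable:
            raise ValueError(
                "no glomeruli passed the hemisphere (thickness >= 0.9 radius) "
                "and edge-clipping filters"
            )
        vals = {r.id: r.vv_3d for r in usable}
    elif method in ("2d_single_plane", "2d_max_plane"):
        usable = [r for r in records if not r.clipped]
        if not usable:
            raise ValueError("all glomeruli were clipped at the image border")
        key = "vv_2d_single" if method == "2d_single_plane" else "vv_2d_max"
        vals = {r.id: getattr(r, key) for r in usable}
    else:
        raise ValueError(f"unknown method {method!r}")
    series = pd.Series(vals, name=method).dropna()
    n = len(series)
    sd = float(series.std(ddof=1)) if n > 1 else 0.0
    summary = pd.Series(
        {
            "mean": float(series.mean()),
            "sd": sd,
            "se": sd / np.sqrt(n) if n else float("nan"),
            "n": n,
        },
        name=method,
    )
    return series, summary


def records_to_frame(records: Sequence[GlomerulusRecord]) -> pd.DataFrame:
    """One row per glomerulus: id, radius, thickness, retained, Vv columns."""
    rows = [
        {
            "id": r.id,
            "radius_um": r.radius_um,
            "thickness_um": r.thickness_um,
            "retained": r.retained,
            "clipped": r.clipped,
            "vv_3d": r.vv_3d,
            "vv_2d_single": r.vv_2d_single,
            "vv_2d_max": r.vv_2d_max,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("id")


def count_nuclei_3d(
    nuclei: np.ndarray, regions: LabeledRegions
) -> Dict[int, int]:
    """Count 26-connected nuclei per region; assignment is by centroid.

    A nucleus straddling a region boundary is counted once, in the region
    containing its centroid (region 0 collects nuclei outside every
    labeled region, e.g. the surrounding tubule cortex).
    """
    nuclei = np.asarray(nuclei) > 0
    if nuclei.shape != regions.labels.shape:
        raise ValueError("nuclei and region shapes differ")
    comp, n = ndimage.label(nuclei, structure=STRUCT_26)
    counts: Dict[int, int] = {int(i): 0 for i in np.unique(regions.labels)}
    if n == 0:
        return counts
    centroids = ndimage.center_of_mass(nuclei, comp, index=range(1, n + 1))
    for cz, cy, cx in centroids:
        region = int(
            regions.labels[int(round(cz)), int(round(cy)), int(round(cx))]
        )
        counts[region] = counts.get(region, 0) + 1
    return counts
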