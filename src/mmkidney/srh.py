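"""Stimulated Raman Histology: pseudo-staining of SRS protein/lipid images.

The protein (2940 cm^-1, CH3) and lipid (2850 cm^-1, CH2) channels are
mapped through two-endpoint linear lookup tables, blended in RGB, and then
adjusted in the device-independent L*a*b* space: nuclei (segmented from
the lipid:protein ratio) are darkened and shifted toward hematoxylin
blue-purple, background is lifted toward white. A PAS-style variant adds a
chroma term where a* minus b* grows logarithmically with the protein
signal, emulating the reddish periodic-acid-Schiff product on
glycoprotein-rich basement membranes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage.color import lab2rgb, rgb2lab
from skimage.exposure import match_histograms
from skimage.morphology import closing, disk, remove_small_objects

RGB = Tuple[float, float, float]

#: default stain endpoints; the pseudo-color semantics (eosin pink for
#: protein, faint near-white for lipid, hematoxylin purple nuclei) are
#: configurable.
EOSIN_PINK: RGB = (1.00, 0.55, 0.60)
LIPID_TINT: RGB = (1.00, 0.97, 0.94)
HEMATOXYLIN: RGB = (0.35, 0.25, 0.55)


def _lut(v: np.ndarray, low: RGB, high: RGB) -> np.ndarray:
    low_a = np.asarray(low, float)
    high_a = np.asarray(high, float)
    return low_a + v[..., None] * (high_a - low_a)


@dataclass(frozen=True)
class LUTPair:
    """Two-endpoint linear LUTs for the protein and lipid channels."""

    protein_low: RGB = (1.0, 1.0, 1.0)
    protein_high: RGB = EOSIN_PINK
    lipid_low: RGB = (1.0, 1.0, 1.0)
    lipid_high: RGB = LIPID_TINT
    blend_mode: str = "multiply"

    def __post_init__(self) -> None:
        for c in (self.protein_low, self.protein_high, self.lipid_low, self.lipid_high):
            if any(not (0.0 <= x <= 1.0) for x in c):
                raise ValueError("LUT endpoints must be RGB in [0, 1]")
        if self.blend_mode not in ("multiply", "screen", "linear_sum_clipped"):
            raise ValueError(f"unknown blend mode {self.blend_mode!r}")

    def blend(self, protein01: np.ndarray, lipid01: np.ndarray) -> np.ndarray:
        a = _lut(protein01, self.protein_low, self.protein_high)
        b = _lut(lipid01, self.lipid_low, self.lipid_high)
        if self.blend_mode == "multiply":
            out = a * b
        elif self.blend_mode == "screen":
            out = 1.0 - (1.0 - a) * (1.0 - b)
        else:
            out = a + b - 1.0
        return np.clip(out, 0.0, 1.0)


@dataclass
class SRHImage:
    """A rendered pseudo-stained RGB image."""

    rgb: np.ndarray
    style: str
    nuclei_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (y, x, 3)")
        if not np.isfinite(self.rgb).all():
            raise ValueError("rgb must be finite")


def percentile_stretch(
    image: np.ndarray, percentiles: Tuple[float, float] = (1.0, 99.0)
) -> np.ndarray:
    """Rescale an image to [0, 1] between the given intensity percentiles."""
    image = np.asarray(image, float)
    lo, hi = np.percentile(image, percentiles)
    if hi <= lo:
        return np.zeros_like(image)
    return np.clip((image - lo) / (hi - lo), 0.0, 1.0)


def segment_nuclei(
    lipid: np.ndarray,
    protein: np.ndarray,
    ratio_percentile: float = 95.0,
    min_area: int = 9,
    close_radius: int = 2,
    eps: Optional[float] = None,
) -> np.ndarray:
    """Segment nuclei by thresholding the highest lipid:protein ratios.

    Nuclei (dense nucleic acid, low protein-CH3 signal) stand out in the
    lipid/(protein + eps) ratio. The top ``100 - ratio_percentile`` percent
    of ratio values are kept, then the mask is de-speckled (area <
    ``min_area`` removed), morphologically closed (disk of
    ``close_radius``) and hole-filled.
    """
    lipid = np.asarray(lipid, float)
    protein = np.asarray(protein, float)
    if lipid.shape != protein.shape:
        raise ValueError("channel shapes differ")
    if eps is None:
        peak = protein.max()
        eps = 1e-3 * peak if peak > 0 else 1e-3
    ratio = lipid / (protein + eps)
    if np.ptp(ratio) < 1e-12:
        warnings.warn("lipid:protein ratio is constant; no nuclei segmented")
        return np.zeros(ratio.shape, dtype=bool)
    thresh = np.percentile(ratio, ratio_percentile)
    mask = ratio > thresh
    mask = remove_small_objects(mask, max_size=min_area - 1)
    if close_radius > 0:
        mask = closing(mask, disk(close_radius))
    mask = ndimage.binary_fill_holes(mask)
    if not mask.any():
        warnings.warn("nuclei segmentation produced an empty mask")
    return mask


@dataclass(frozen=True)
class RenderParams:
    """Tunable constants of the L*a*b* adjustment stage."""

    stretch_percentiles: Tuple[float, float] = (1.0, 99.0)
    delta_l_nuclei: float = 25.0
    delta_b_nuclei: float = 10.0
    background_threshold: float = 0.05
    background_l_gain: float = 0.7
    nuclei_color: RGB = HEMATOXYLIN
    nuclei_color_weight: float = 0.6


def render_he(
    protein: np.ndarray,
    lipid: np.ndarray,
    nuclei_mask: Optional[np.ndarray] = None,
    luts: LUTPair = LUTPair(),
    params: RenderParams = RenderParams(),
) -> SRHImage:
    """Render an H&E-style pseudo-stained image.

    Channels are percentile-stretched to [0, 1], mapped through the LUT
    pair and blended; the blend is converted to L*a*b*, where nuclei have
    L* decreased (and b* slightly decreased, toward hematoxylin), the
    background has L* raised toward white, and the result is converted
    back to RGB and clipped.
    """
    p01 = percentile_stretch(protein, params.stretch_percentiles)
    l01 = percentile_stretch(lipid, params.stretch_percentiles)
    rgb = luts.blend(p01, l01)

    if nuclei_mask is not None and nuclei_mask.any():
        w = params.nuclei_color_weight
        tint = np.asarray(params.nuclei_color, float)
        rgb[nuclei_mask] = (1.0 - w) * rgb[nuclei_mask] + w * tint

    lab = rgb2lab(rgb)
    background = (p01 + l01) < params.background_threshold
    if nuclei_mask is not None:
        lab[..., 0] = np.where(
            nuclei_mask, lab[..., 0] - params.delta_l_nuclei, lab[..., 0]
        )
        lab[..., 2] = np.where(
            nuclei_mask, lab[..., 2] - params.delta_b_nuclei, lab[..., 2]
        )
        background = background & ~nuclei_mask
    lab[..., 0] = np.where(
        background,
        lab[..., 0] + params.background_l_gain * (100.0 - lab[..., 0]),
        lab[..., 0],
    )
    lab[..., 0] = np.clip(lab[..., 0], 0.0, 100.0)
    rgb_out = np.clip(lab2rgb(lab), 0.0, 1.0)
    return SRHImage(rgb=rgb_out, style="HE", nuclei_mask=nuclei_mask)


def render_pas(
    protein: np.ndarray,
    lipid: np.ndarray,
    nuclei_mask: Optional[np.ndarray] = None,
    k: float = 5.0,
    a_gain: float = 18.0,
    b_gain: float = 12.0,
    luts: LUTPair = LUTPair(),
    params: RenderParams = RenderParams(),
) -> SRHImage:
    """Render a PAS-style variant of the H&E pseudo-stain.

    On top of the H&E render, a PAS intensity field
    ``p = log(1 + k * protein01) / log(1 + k)`` shifts chroma redder where
    the protein signal is high: a* increases by ``a_gain * p`` and b*
    decreases by ``b_gain * p``. ``k = 0`` reduces to the H&E render.
    """
    base = render_he(protein, lipid, nuclei_mask, luts=luts, params=params)
    if k == 0:
        return SRHImage(rgb=base.rgb.copy(), style="PAS", nuclei_mask=nuclei_mask)
    if k < 0:
        raise ValueError("k must be non-negative")
    p01 = percentile_stretch(protein, params.stretch_percentiles)
    pas = np.log1p(k * p01) / np.log1p(k)
    lab = rgb2lab(base.rgb)
    lab[..., 1] += a_gain * pas
    lab[..., 2] -= b_gain * pas
    rgb_out = np.clip(lab2rgb(lab), 0.0, 1.0)
    return SRHImage(rgb=rgb_out, style="PAS", nuclei_mask=nuclei_mask)


def histogram_specification(
    rgb: np.ndarray, reference_rgb: np.ndarray
) -> np.ndarray:
    """Per-channel monotone histogram matching of ``rgb`` to a reference.

    Constant channels pass through unchanged with a warning (their
    histogram carries no shape to match).
    """
    rgb = np.asarray(rgb, float)
    ref = np.asarray(reference_rgb, float)
    if rgb.ndim != 3 or rgb.shape[2] != 3 or ref.ndim != 3 or ref.shape[2] != 3:
        raise ValueError("inputs must be (y, x, 3) RGB")
    out = np.empty_like(rgb)
    for c in range(3):
        if np.ptp(rgb[..., c]) == 0 or np.ptp(ref[..., c]) == 0:
            warnings.warn(f"channel {c} is constant; passed through unmatched")
            out[..., c] = rgb[..., c]
        else:
            out[..., c] = match_histograms(rgb[..., c], ref[..., c])
    return np.clip(out, 0.0, 1.0)
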