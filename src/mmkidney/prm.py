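"""Penalized Reference Matching (PRM) of hyperspectral SRS pixels.

Every pixel spectrum I(nu) is scored against a lipid-subtype reference
r(nu) by cosine similarity in the C-H stretching region (2700-3100 cm^-1),
evaluated at a grid of wavenumber offsets delta; each offset carries a
penalty w(delta) <= 1 (w(0) = 1, non-increasing in |delta|) that absorbs
small calibration or lensing shifts without rewarding gross misalignment:

    s = max_delta  cos( I(nu), r(nu - delta) ) * w(delta)

Scores across subtypes are simplex-normalized per pixel, and relative
scores are read as relative concentrations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .datatypes import HyperspectralStack, ReferenceSpectrum

CH_WINDOW = (2700.0, 3100.0)


@dataclass(frozen=True)
class PenaltySpec:
    """Offset penalty w(delta): gaussian (default), linear, or none.

    gaussian: w = exp(-delta^2 / (2 scale^2));
    linear:   w = max(1 - |delta| / scale, floor);
    none:     w = 1.
    Always w(0) = 1, non-increasing in |delta|, and in (0, 1].
    """

    kind: str = "gaussian"
    scale_cm1: float = 10.0
    _FLOOR = 1e-6

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "linear", "none"):
            raise ValueError(f"unknown penalty kind {self.kind!r}")
        if self.kind != "none" and self.scale_cm1 <= 0:
            raise ValueError("penalty scale must be positive")

    def __call__(self, offset_cm1: float) -> float:
        d = abs(float(offset_cm1))
        if self.kind == "none":
            return 1.0
        if self.kind == "gaussian":
            return float(np.exp(-(d ** 2) / (2.0 * self.scale_cm1 ** 2)))
        return max(1.0 - d / self.scale_cm1, self._FLOOR)


@dataclass
class SimilarityMap:
    """Per-pixel similarity of a stack to one reference subtype."""

    scores: np.ndarray
    subtype: str
    offsets_cm1: List[float]
    penalty: PenaltySpec
    valid_mask: np.ndarray
    winning_offset: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.scores.shape != self.valid_mask.shape:
            raise ValueError("scores and mask shapes differ")


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine similarity of two spectra, clipped to [0, 1].

    Spectra are non-negative, so the clip at zero is a numerical guard.
    A zero vector scores 0 (with a warning) rather than NaN.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("spectra must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        warnings.warn("cosine similarity of a zero spectrum is defined as 0")
        return 0.0
    return float(np.clip(np.dot(a, b) / (na * nb), 0.0, 1.0))


def prm_score(
    stack: HyperspectralStack,
    ref: ReferenceSpectrum,
    offsets_cm1: Sequence[float] = tuple(range(-10, 11)),
    penalty: PenaltySpec = PenaltySpec(),
    window: Tuple[float, float] = CH_WINDOW,
) -> SimilarityMap:
    """Score every pixel against one reference at multiple penalized offsets.

    The reference is linearly interpolated onto the stack axis (edge values
    extended) for each offset; the per-pixel score is the max over offsets
    of penalized cosine similarity, restricted to ``window``. The winning
    offset is stored per pixel. An empty offset list falls back to
    delta = 0 only.
    """
    offsets = list(offsets_cm1) if len(list(offsets_cm1)) else [0.0]
    wn = stack.wavenumbers
    sel = (wn >= window[0]) & (wn <= window[1])
    if sel.sum() < 2:
        raise ValueError("scoring window contains fewer than 2 axis samples")
    axis = wn[sel]
    data = stack.data[:, :, sel]
    ny, nx, n = data.shape
    flat = data.reshape(-1, n)
    norms = np.linalg.norm(flat, axis=1)
    valid = norms > 0
    safe = np.where(valid, norms, 1.0)
    unit = flat / safe[:, None]

    best = np.full(flat.shape[0], -np.inf)
    best_off = np.zeros(flat.shape[0])
    for delta in offsets:
        r = ref.resample(axis, shift_cm1=delta)
        rn = np.linalg.norm(r)
        if rn == 0:
            continue
        s = (unit @ (r / rn)) * penalty(delta)
        better = s > best
        best_off[better] = delta
        best[better] = s[better]
    scores = np.clip(np.where(valid, best, 0.0), 0.0, 1.0).reshape(ny, nx)
    return SimilarityMap(
        scores=scores,
        subtype=ref.name,
        offsets_cm1=[float(d) for d in offsets],
        penalty=penalty,
        valid_mask=valid.reshape(ny, nx),
        winning_offset=best_off.reshape(ny, nx),
    )


def simplex_normalize(maps: Sequence[SimilarityMap]) -> List[SimilarityMap]:
    """Divide each subtype score by the per-pixel sum across subtypes.

    Pixels with zero total score are masked. Per-pixel normalized scores
    sum to 1 on unmasked pixels.
    """
    if len(maps) < 2:
        raise ValueError("simplex normalization needs at least 2 subtype maps")
    shape = maps[0].scores.shape
    for m in maps[1:]:
        if m.scores.shape != shape:
            raise ValueError("similarity maps must share shape")
    total = np.sum([m.scores for m in maps], axis=0)
    nonzero = total > 0
    safe = np.where(nonzero, total, 1.0)
    out = []
    for m in maps:
        out.append(
            SimilarityMap(
                scores=np.where(nonzero, m.scores / safe, 0.0),
                subtype=m.subtype,
                offsets_cm1=m.offsets_cm1,
                penalty=m.penalty,
                valid_mask=m.valid_mask & nonzero,
                winning_offset=m.winning_offset,
            )
        )
    return out


def top_percentile_spectra(
    stack: HyperspectralStack,
    smap: SimilarityMap,
    p: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean spectrum (and per-wavenumber std) of the top-p% scoring pixels.

    Selects unmasked pixels with score >= the (100 - p)th percentile; tied
    scores are all included. Returns (mean spectrum, std band, pixel mask).
    """
    if not (0 < p <= 100):
        raise ValueError("p must be in (0, 100]")
    valid = smap.valid_mask
    scores = smap.scores[valid]
    if scores.size == 0:
        raise ValueError("no valid pixels to select from")
    thresh = np.percentile(scores, 100.0 - p)
    # small slack keeps float-identical scores together on one side of
    # the threshold (ties are included by contract)
    mask = valid & (smap.scores >= thresh - 1e-12)
    n_sel = int(mask.sum())
    if n_sel < 10:
        warnings.warn(f"only {n_sel} pixels in the top {p}% selection")
    spectra = stack.data[mask]
    return spectra.mean(axis=0), spectra.std(axis=0), mask


@dataclass
class RatioResult:
    """Ratiometric subtype map with its pixel-value histogram summary."""

    image: np.ndarray
    valid_mask: np.ndarray
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    mean: float


def ratiometric_map(
    numerator: SimilarityMap,
    denominator: SimilarityMap,
    eps: float = 1e-6,
    bins: int = 64,
) -> RatioResult:
    """Per-pixel ratio of two subtype similarity maps, with histogram + mean.

    The ratio is num / (den + eps) on pixels where at least one map exceeds
    eps; pixels where both scores are below eps are masked. Values are
    always finite.
    """
    if numerator.scores.shape != denominator.scores.shape:
        raise ValueError("maps must share shape")
    num, den = numerator.scores, denominator.scores
    valid = (
        numerator.valid_mask
        & denominator.valid_mask
        & ((num >= eps) | (den >= eps))
    )
    ratio = np.where(valid, num / (den + eps), 0.0)
    vals = ratio[valid]
    counts, edges = np.histogram(vals, bins=bins) if vals.size else (
        np.zeros(bins, int),
        np.linspace(0, 1, bins + 1),
    )
    mean = float(vals.mean()) if vals.size else float("nan")
    return RatioResult(
        image=ratio, valid_mask=valid, hist_counts=counts, hist_edges=edges, mean=mean
    )
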